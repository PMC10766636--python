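"""ABC scenario choice and parameter estimation.

Summary statistics (per-population and pairwise), MAD-standardized
rejection sampling, multinomial-logistic scenario posterior probabilities
with delta-method confidence intervals, and Beaumont-style local-linear
parameter posteriors with Epanechnikov weights.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import diversity_stats as dv
from . import sequence_core as sc
from .scenario_simulator import (
    ALL_SCENARIOS,
    POPULATIONS,
    MutationModel,
    draw_priors,
    simulate_raw,
)

PER_POP_STATS = ("S", "n_hap", "H", "mean_pair_diff", "var_pair_diff", "tajima_D")
PER_PAIR_STATS = ("between_mean_diff", "fst")


def summary_names(pops: tuple[str, ...] = POPULATIONS) -> list[str]:
    names = [f"{p}_{s}" for p in pops for s in PER_POP_STATS]
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            names += [f"{pops[i]}_{pops[j]}_{s}" for s in PER_PAIR_STATS]
    return names


@dataclass
class SummaryVector:
    names: list[str]
    values: np.ndarray
    valid: np.ndarray  # False where the statistic was undefined (encoded 0)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)


@dataclass
class RetainedSet:
    indices: np.ndarray
    distances: np.ndarray
    tolerance: float
    stat_columns: list[str]
    dropped_columns: list[str]
    mad: np.ndarray


@dataclass
class AbcScenarioResult:
    pp: dict[int, float]
    ci: dict[int, tuple[float, float]]
    tolerance: float
    n_retained: int
    method: str  # 'mnlogit' or 'rejection'
    flagged: bool = False

    def to_dict(self) -> dict:
        return {
            "pp": {str(k): v for k, v in self.pp.items()},
            "ci": {str(k): list(v) for k, v in self.ci.items()},
            "tolerance": self.tolerance,
            "n_retained": self.n_retained,
            "method": self.method,
            "flagged": self.flagged,
        }


@dataclass
class AbcParamPosterior:
    scenario_id: int
    parameter: str
    sample: np.ndarray
    weights: np.ndarray
    point: float
    hpd: tuple[float, float]
    adjusted: bool
    flagged: bool = False

    def to_dict(self) -> dict:
        return {
            "scenario_id": self.scenario_id,
            "parameter": self.parameter,
            "point": self.point,
            "hpd": list(self.hpd),
            "adjusted": self.adjusted,
            "flagged": self.flagged,
        }


def _pairwise_diff_matrix(codes: np.ndarray) -> np.ndarray:
    """Difference counts for gap-free integer-coded sequences."""
    n, L = codes.shape
    var = ~np.all(codes == codes[0], axis=0)
    sub = codes[:, var]
    matches = np.zeros((n, n), dtype=np.int64)
    for b in range(4):
        xb = (sub == b).astype(np.int64)
        matches += xb @ xb.T
    return sub.shape[1] - matches


def _haplotype_counts(D_pop: np.ndarray) -> np.ndarray:
    """Haplotype class sizes from a within-population difference matrix
    (two rows share a haplotype iff their difference count is 0)."""
    first = (D_pop == 0).argmax(axis=1)
    counts = np.bincount(first)
    return counts[counts > 0]


def _tajima_d_from(k_hat: float, S: int, n: int) -> float:
    if S == 0 or n < 4:
        return 0.0
    c = dv._tajima_constants(n)
    return (k_hat - S / c["a1"]) / math.sqrt(c["e1"] * S + c["e2"] * S * (S - 1))


def summarize_matrix(
    codes: np.ndarray, pop_labels: list[str], pops: tuple[str, ...] = POPULATIONS
) -> SummaryVector:
    """Summary statistics from a gap-free coded matrix (fast ABC path)."""
    labels = np.asarray(pop_labels)
    names = summary_names(pops)
    values = np.zeros(len(names))
    valid = np.ones(len(names), dtype=bool)
    D = _pairwise_diff_matrix(codes)
    idx_of = {}
    pos = 0
    for p in pops:
        idx = np.flatnonzero(labels == p)
        if idx.size == 0:
            raise ValueError(f"empty population: {p}")
        idx_of[p] = idx
        sub = codes[idx]
        S = int(np.sum(~np.all(sub == sub[0], axis=0)))
        Dp = D[np.ix_(idx, idx)]
        counts = _haplotype_counts(Dp)
        n = idx.size
        freqs = counts / n
        H = n / (n - 1) * (1.0 - np.sum(freqs**2)) if n >= 2 else 0.0
        iu = np.triu_indices(n, k=1)
        pair = Dp[iu].astype(float)
        k_hat = float(pair.mean()) if pair.size else 0.0
        k_var = float(pair.var(ddof=0)) if pair.size else 0.0
        d_taj = _tajima_d_from(k_hat, S, n)
        row = {
            "S": float(S),
            "n_hap": float(len(counts)),
            "H": float(H),
            "mean_pair_diff": k_hat,
            "var_pair_diff": k_var,
            "tajima_D": d_taj,
        }
        for s in PER_POP_STATS:
            values[pos] = row[s]
            if s == "tajima_D" and (S == 0 or n < 4):
                valid[pos] = False
            pos += 1
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            ia, ib = idx_of[pops[i]], idx_of[pops[j]]
            between = float(D[np.ix_(ia, ib)].mean())
            wa = D[np.ix_(ia, ia)][np.triu_indices(ia.size, k=1)]
            wb = D[np.ix_(ib, ib)][np.triu_indices(ib.size, k=1)]
            within = 0.5 * (
                (wa.mean() if wa.size else 0.0) + (wb.mean() if wb.size else 0.0)
            )
            fst = 1.0 - within / between if between > 0 else 0.0
            values[pos] = between
            pos += 1
            values[pos] = fst
            if between == 0:
                valid[pos] = False
            pos += 1
    return SummaryVector(names=names, values=values, valid=valid)


def summarize_alignment(
    aln: sc.Alignment, meta: pd.DataFrame, pops: tuple[str, ...] = POPULATIONS
) -> SummaryVector:
    """Summary statistics through the general alignment machinery
    (pairwise deletion; slow path, used for observed data)."""
    order = {s: i for i, s in enumerate(aln.sample_ids)}
    labels = np.empty(aln.n, dtype=object)
    for _, row in meta.iterrows():
        if row["sample_id"] in order:
            labels[order[row["sample_id"]]] = row["population"]
    names = summary_names(pops)
    values = np.zeros(len(names))
    valid = np.ones(len(names), dtype=bool)
    diffs_all = sc.pairwise_differences(aln)
    idx_of: dict[str, np.ndarray] = {}
    pos = 0
    for p in pops:
        idx = np.flatnonzero(labels == p)
        if idx.size == 0:
            raise ValueError(f"empty population: {p}")
        idx_of[p] = idx
        sub = aln.subset([aln.sample_ids[i] for i in idx])
        S = dv.segregating_sites(sub)
        ht = sc.collapse_haplotypes(sub)
        n = idx.size
        H = dv.haplotype_diversity(ht) if n >= 2 else 0.0
        iu = np.triu_indices(n, k=1)
        pair = diffs_all.diffs[np.ix_(idx, idx)][iu].astype(float)
        k_hat = float(pair.mean()) if pair.size else 0.0
        k_var = float(pair.var(ddof=0)) if pair.size else 0.0
        d_taj = _tajima_d_from(k_hat, S, n)
        row = {
            "S": float(S),
            "n_hap": float(ht.k),
            "H": float(H),
            "mean_pair_diff": k_hat,
            "var_pair_diff": k_var,
            "tajima_D": d_taj,
        }
        for s in PER_POP_STATS:
            values[pos] = row[s]
            if s == "tajima_D" and (S == 0 or n < 4):
                valid[pos] = False
            pos += 1
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            ia, ib = idx_of[pops[i]], idx_of[pops[j]]
            between = float(diffs_all.diffs[np.ix_(ia, ib)].mean())
            wa = diffs_all.diffs[np.ix_(ia, ia)][np.triu_indices(ia.size, k=1)]
            wb = diffs_all.diffs[np.ix_(ib, ib)][np.triu_indices(ib.size, k=1)]
            within = 0.5 * (
                (wa.mean() if wa.size else 0.0) + (wb.mean() if wb.size else 0.0)
            )
            fst = 1.0 - within / between if between > 0 else 0.0
            values[pos] = between
            pos += 1
            values[pos] = fst
            if between == 0:
                valid[pos] = False
            pos += 1
    return SummaryVector(names=names, values=values, valid=valid)


# ---------------------------------------------------------------------------
# Reference table


PARAM_COLUMNS = ["Ta", "T1", "T2", "T3"] + [f"N_{p}" for p in POPULATIONS]


def build_reference_table(
    n_per_scenario: int,
    sample_sizes: dict[str, int],
    model: MutationModel | None = None,
    L: int = 1230,
    seed: int | None = None,
    scenarios=ALL_SCENARIOS,
) -> pd.DataFrame:
    """Simulate the ABC reference table: one row per simulation with the
    scenario id, drawn parameters and the summary vector."""
    model = model or MutationModel()
    rng = np.random.default_rng(seed)
    stat_names = summary_names()
    rows = []
    for scn in scenarios:
        for _ in range(n_per_scenario):
            params = draw_priors(scn, rng)
            codes, pops = simulate_raw(scn, params, sample_sizes, model, L, rng)
            sv = summarize_matrix(codes, pops)
            row = {"scenario": scn.scenario_id}
            for c in PARAM_COLUMNS:
                row[c] = params.get(c, np.nan)
            row.update(dict(zip(stat_names, sv.values)))
            rows.append(row)
    return pd.DataFrame(rows)


def abc_reject(
    observed: SummaryVector | np.ndarray,
    table: pd.DataFrame,
    tolerance: float,
) -> RetainedSet:
    """Retain the ceil(tolerance * rows) simulations closest to the observed
    vector under MAD-standardized Euclidean distance.

    Statistics with zero MAD across the table are dropped from the distance
    with a warning.
    """
    if not 0 < tolerance <= 1:
        raise ValueError("tolerance must be in (0, 1]")
    if len(table) == 0:
        raise ValueError("empty reference table")
    stat_cols = [c for c in summary_names() if c in table.columns]
    obs = observed.values if isinstance(observed, SummaryVector) else np.asarray(observed)
    if obs.shape[0] != len(stat_cols):
        raise ValueError("observed vector length does not match table statistics")
    X = table[stat_cols].to_numpy(dtype=float)
    med = np.median(X, axis=0)
    mad = np.median(np.abs(X - med), axis=0)
    keep = mad > 0
    dropped = [c for c, k in zip(stat_cols, keep) if not k]
    if dropped:
        warnings.warn(f"dropping zero-MAD statistics from ABC distance: {dropped}")
    if not keep.any():
        raise ValueError("all statistics degenerate (zero MAD)")
    Z = (X[:, keep] - obs[keep]) / mad[keep]
    dist = np.sqrt(np.sum(Z**2, axis=1))
    n_keep = int(math.ceil(tolerance * len(table)))
    order = np.argsort(dist, kind="stable")[:n_keep]
    return RetainedSet(
        indices=order,
        distances=dist[order],
        tolerance=tolerance,
        stat_columns=[c for c, k in zip(stat_cols, keep) if k],
        dropped_columns=dropped,
        mad=mad[keep],
    )


def scenario_posterior(
    retained: RetainedSet,
    table: pd.DataFrame,
    observed: SummaryVector | np.ndarray,
) -> AbcScenarioResult:
    """Scenario posterior probabilities among retained simulations.

    Multinomial logistic regression of the scenario indicator on the
    (summary - observed) differences, evaluated at zero; confidence
    intervals by the delta method. Falls back to the retained-fraction
    estimator when the regression is degenerate.
    """
    obs = observed.values if isinstance(observed, SummaryVector) else np.asarray(observed)
    sub = table.iloc[retained.indices]
    scen_ids = sorted(table["scenario"].unique())
    y_all = sub["scenario"].to_numpy()
    present = sorted(set(y_all.tolist()))
    n_ret = len(sub)

    def rejection_result(flagged: bool) -> AbcScenarioResult:
        pp, ci = {}, {}
        for s in scen_ids:
            p = float(np.mean(y_all == s))
            se = math.sqrt(max(p * (1 - p), 1e-12) / n_ret)
            pp[int(s)] = p
            ci[int(s)] = (max(0.0, p - 1.96 * se), min(1.0, p + 1.96 * se))
        return AbcScenarioResult(
            pp=pp, ci=ci, tolerance=retained.tolerance,
            n_retained=n_ret, method="rejection", flagged=flagged,
        )

    if len(present) < 2:
        return rejection_result(flagged=True)

    name_to_obs = dict(zip(summary_names(), obs))
    cols = retained.stat_columns
    X = sub[cols].to_numpy(dtype=float) - np.array([name_to_obs[c] for c in cols])
    X = X / retained.mad
    # drop columns constant within the retained set
    keep = X.std(axis=0) > 1e-12
    X = X[:, keep]
    y = np.searchsorted(present, y_all)
    try:
        import statsmodels.api as sm

        Xc = sm.add_constant(X, has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.MNLogit(y, Xc).fit(method="lbfgs", maxiter=500, disp=0)
        params = fit.params  # (k, J-1)
        x0 = np.zeros(Xc.shape[1])
        x0[0] = 1.0
        logits = x0 @ params  # (J-1,)
        expl = np.exp(np.concatenate([[0.0], logits]))
        probs = expl / expl.sum()
        cov = fit.cov_params()
        # delta method: numerical gradient of each prob wrt flattened params
        flat = params.to_numpy().flatten(order="F") if hasattr(params, "to_numpy") else params.flatten(order="F")
        k, jm1 = Xc.shape[1], len(present) - 1

        def probs_of(vec: np.ndarray) -> np.ndarray:
            P = vec.reshape((k, jm1), order="F")
            lg = x0 @ P
            e = np.exp(np.concatenate([[0.0], lg]))
            return e / e.sum()

        eps = 1e-6
        grad = np.zeros((len(present), len(flat)))
        for m in range(len(flat)):
            dvec = flat.copy()
            dvec[m] += eps
            grad[:, m] = (probs_of(dvec) - probs) / eps
        cov_arr = np.asarray(cov)
        var = np.einsum("im,mn,in->i", grad, cov_arr, grad)
        se = np.sqrt(np.clip(var, 0.0, None))
        if not np.all(np.isfinite(se)):
            raise np.linalg.LinAlgError("non-finite covariance")
        pp, ci = {}, {}
        for s in scen_ids:
            if s in present:
                idx = present.index(s)
                p = float(probs[idx])
                lo = max(0.0, p - 1.96 * se[idx])
                hi = min(1.0, p + 1.96 * se[idx])
            else:
                p, lo, hi = 0.0, 0.0, 0.0
            pp[int(s)] = p
            ci[int(s)] = (lo, hi)
        total = sum(pp.values())
        pp = {s: v / total for s, v in pp.items()}
        return AbcScenarioResult(
            pp=pp, ci=ci, tolerance=retained.tolerance,
            n_retained=n_ret, method="mnlogit",
        )
    except Exception:
        return rejection_result(flagged=True)


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q: float) -> float:
    order = np.argsort(x)
    xs, ws = x[order], w[order]
    cw = np.cumsum(ws)
    cw /= cw[-1]
    return float(np.interp(q, cw, xs))


def _weighted_hpd(x: np.ndarray, w: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    order = np.argsort(x)
    xs, ws = x[order], w[order] / w.sum()
    cw = np.concatenate([[0.0], np.cumsum(ws)])
    best = (xs[0], xs[-1])
    best_len = xs[-1] - xs[0]
    j = 0
    for i in range(len(xs)):
        while j < len(xs) and cw[j + 1] - cw[i] < mass:
            j += 1
        if j >= len(xs):
            break
        width = xs[j] - xs[i]
        if width < best_len:
            best_len = width
            best = (xs[i], xs[j])
    return float(best[0]), float(best[1])


def estimate_params(
    retained: RetainedSet,
    table: pd.DataFrame,
    observed: SummaryVector | np.ndarray,
    scenario_id: int,
    parameter: str,
    prior_bounds: tuple[float, float] | None = None,
    min_rows: int = 50,
    ridge_rel: float = 0.1,
) -> AbcParamPosterior:
    """Local-linear regression-adjusted posterior for one parameter.

    Epanechnikov weights on the retained distances; the weighted regression
    is ridge-regularized (``ridge_rel`` scales the penalty relative to the
    design's mean eigenvalue; the intercept is never penalized) to avoid
    over-adjustment when many statistics are weakly informative. Adjusted
    draws are clipped to the prior support. Falls back to the unadjusted
    rejection posterior when the regression is degenerate (flagged).
    """
    obs = observed.values if isinstance(observed, SummaryVector) else np.asarray(observed)
    sub = table.iloc[retained.indices]
    mask = (sub["scenario"] == scenario_id).to_numpy()
    sub = sub[mask]
    dist = retained.distances[mask]
    if len(sub) == 0:
        raise ValueError(f"no retained rows for scenario {scenario_id}")
    flagged = len(sub) < min_rows
    theta = sub[parameter].to_numpy(dtype=float)
    dmax = dist.max()
    if dmax == 0:
        w = np.ones_like(dist)
    else:
        w = 1.0 - (dist / (dmax * (1 + 1e-9))) ** 2
    w = np.clip(w, 1e-12, None)
    w = w / w.sum()

    name_to_obs = dict(zip(summary_names(), obs))
    cols = retained.stat_columns
    X = sub[cols].to_numpy(dtype=float) - np.array([name_to_obs[c] for c in cols])
    X = X / retained.mad
    keep = X.std(axis=0) > 1e-12
    X = X[:, keep]
    adjusted = False
    theta_adj = theta.copy()
    if X.shape[1] > 0 and len(sub) > X.shape[1] + 1:
        Xd = np.column_stack([np.ones(len(sub)), X])
        Wsq = np.sqrt(w)
        A = Xd * Wsq[:, None]
        b = theta * Wsq
        gram = A.T @ A
        lam = ridge_rel * np.trace(gram) / gram.shape[0]
        M = gram + lam * np.eye(gram.shape[0])
        M[0, 0] -= lam  # leave the intercept unpenalized
        try:
            beta = np.linalg.solve(M, A.T @ b)
            theta_adj = theta - X @ beta[1:]
            adjusted = True
        except np.linalg.LinAlgError:
            flagged = True
    else:
        flagged = True
    if prior_bounds is not None:
        theta_adj = np.clip(theta_adj, prior_bounds[0], prior_bounds[1])
    point = _weighted_quantile(theta_adj, w, 0.5)
    hpd = _weighted_hpd(theta_adj, w, 0.95)
    return AbcParamPosterior(
        scenario_id=scenario_id,
        parameter=parameter,
        sample=theta_adj,
        weights=w,
        point=point,
        hpd=hpd,
        adjusted=adjusted,
        flagged=flagged,
    )
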