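"""Diversity statistics and expansion dating.

Nucleotide diversity, haplotype diversity, Tajima's D with a
beta-approximation significance flag, the observed mismatch distribution,
a least-squares sudden-expansion fit (tau, theta0, theta1), and the two
closed-form mutation-rate datings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .sequence_core import MISSING_CODE, Alignment, HaplotypeTable, PairwiseDiffs, pairwise_differences

# Chicken mitochondrial control-region rate (per site per year) and a
# one-year generation interval.
DEFAULT_MU_SITE = 3.13e-7
DEFAULT_SEQ_LENGTH = 1230


@dataclass(frozen=True)
class RateConstants:
    """Per-site yearly mutation rate and sequence length.

    ``mu_seq`` is the per-sequence yearly rate mu_site * L
    (~3.85e-4 for the defaults).
    """

    mu_site: float = DEFAULT_MU_SITE
    seq_length: int = DEFAULT_SEQ_LENGTH
    generation_years: float = 1.0

    def __post_init__(self) -> None:
        if self.mu_site <= 0 or self.seq_length <= 0 or self.generation_years <= 0:
            raise ValueError("rate constants must be positive")

    @property
    def mu_seq(self) -> float:
        return self.mu_site * self.seq_length


@dataclass
class DiversityStats:
    n: int
    S: int
    pi_site: float
    k_hat: float
    H: float
    tajima_D: float | None
    tajima_p_flag: str  # 'ns' | 'p<0.05' | 'p<0.01' | 'undefined'


@dataclass
class MismatchResult:
    observed_freqs: np.ndarray
    expected_freqs: np.ndarray
    tau: float
    theta0: float
    theta1: float
    ssd: float


def nucleotide_diversity(diffs: PairwiseDiffs) -> float:
    """Mean over unordered pairs of (differences / comparable sites)."""
    n = diffs.n
    if n < 2:
        raise ValueError("need at least 2 sequences")
    iu = np.triu_indices(n, k=1)
    return float(np.mean(diffs.diffs[iu] / diffs.comparable[iu]))


def mean_pairwise_differences(diffs: PairwiseDiffs) -> float:
    """k_hat: mean raw pairwise difference count (pairwise deletion)."""
    iu = np.triu_indices(diffs.n, k=1)
    return float(np.mean(diffs.diffs[iu]))


def haplotype_diversity(ht: HaplotypeTable) -> float:
    """H = n/(n-1) * (1 - sum p_i^2)."""
    n = ht.n
    if n < 2:
        raise ValueError("need at least 2 sequences")
    return float(n / (n - 1) * (1.0 - np.sum(ht.freqs**2)))


def segregating_sites(aln: Alignment) -> int:
    """Number of sites with >= 2 distinct non-missing bases."""
    codes = aln.codes()
    S = 0
    for col in codes.T:
        bases = np.unique(col[col != MISSING_CODE])
        if bases.size >= 2:
            S += 1
    return S


def _tajima_constants(n: int) -> dict[str, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def _tajima_p_flag(D: float, n: int, e2: float, a1: float) -> str:
    # Beta-distribution approximation: D rescaled to [Dmin, Dmax] is treated
    # as Beta(alpha, beta) with mean 0 and variance 1 on the original scale.
    sq = math.sqrt(e2)
    dmin = (2.0 / n - 1.0 / a1) / sq
    kmax = n / (2.0 * (n - 1)) if n % 2 == 0 else (n + 1) / (2.0 * n)
    dmax = (kmax - 1.0 / a1) / sq
    alpha = -(1.0 + dmin * dmax) * dmax / (dmax - dmin)
    beta = (1.0 + dmin * dmax) * dmin / (dmax - dmin)
    if alpha <= 0 or beta <= 0:
        return "ns"
    x = (D - dmin) / (dmax - dmin)
    x = min(max(x, 0.0), 1.0)
    cdf = stats.beta.cdf(x, alpha, beta)
    p2 = 2.0 * min(cdf, 1.0 - cdf)
    if p2 < 0.01:
        return "p<0.01"
    if p2 < 0.05:
        return "p<0.05"
    return "ns"


def tajimas_d(aln: Alignment) -> DiversityStats:
    """Tajima's D from k_hat (pairwise deletion) and segregating sites.

    Raises ValueError when S = 0 (statistic undefined).
    """
    n = aln.n
    if n < 4:
        raise ValueError("need at least 4 sequences for Tajima's D")
    S = segregating_sites(aln)
    diffs = pairwise_differences(aln)
    k_hat = mean_pairwise_differences(diffs)
    pi = nucleotide_diversity(diffs)
    from .sequence_core import collapse_haplotypes

    H = haplotype_diversity(collapse_haplotypes(aln))
    if S == 0:
        return DiversityStats(n=n, S=0, pi_site=pi, k_hat=k_hat, H=H,
                              tajima_D=None, tajima_p_flag="undefined")
    c = _tajima_constants(n)
    D = (k_hat - S / c["a1"]) / math.sqrt(c["e1"] * S + c["e2"] * S * (S - 1))
    flag = _tajima_p_flag(D, n, c["e2"], c["a1"])
    return DiversityStats(n=n, S=S, pi_site=pi, k_hat=k_hat, H=H,
                          tajima_D=D, tajima_p_flag=flag)


def mismatch_observed(diffs: PairwiseDiffs) -> np.ndarray:
    """Histogram of pairwise difference counts, normalized to sum 1."""
    iu = np.triu_indices(diffs.n, k=1)
    d = diffs.diffs[iu]
    counts = np.bincount(d)
    return counts / counts.sum()


def expected_mismatch(tau: float, theta0: float, theta1: float, jmax: int) -> np.ndarray:
    """Sudden-expansion expected mismatch distribution F_j(tau, theta0, theta1).

    F_j = Fhat_j(theta1) + exp(-tau (theta1+1)/theta1)
          * sum_{i<=j} tau^i/i! (Fhat_{j-i}(theta0) - Fhat_{j-i}(theta1)),
    where Fhat_j(theta) = theta^j / (1+theta)^(j+1) is the equilibrium
    distribution. Returned vector is renormalized over 0..jmax.
    """
    j = np.arange(jmax + 1)

    def eq(theta: float) -> np.ndarray:
        if theta <= 0:
            out = np.zeros(jmax + 1)
            out[0] = 1.0
            return out
        return np.exp(j * np.log(theta) - (j + 1) * np.log1p(theta))

    f0, f1 = eq(theta0), eq(theta1)
    # decay * tau^i/i! computed in log space to avoid overflow at large tau
    if theta1 <= 0:
        w = np.zeros(jmax + 1)
        if tau <= 0:
            w[0] = 1.0
    elif tau <= 0:
        w = np.zeros(jmax + 1)
        w[0] = 1.0
    else:
        logw = (
            -tau * (theta1 + 1.0) / theta1
            + j * math.log(tau)
            - special.gammaln(j + 1)
        )
        w = np.exp(logw)
    conv = np.convolve(w, f0 - f1)[: jmax + 1]
    F = f1 + conv
    F = np.clip(F, 0.0, None)
    s = F.sum()
    return F / s if s > 0 else F


def fit_sudden_expansion(
    obs: np.ndarray,
    tau_grid: np.ndarray | None = None,
    theta0_grid: np.ndarray | None = None,
    theta1_grid: np.ndarray | None = None,
    theta1_max: float = 1000.0,
    refine: bool = True,
) -> MismatchResult:
    """Least-squares fit of the sudden-expansion mismatch curve.

    Deterministic: coarse grid search over (tau, theta0, theta1) with
    theta0 <= theta1, followed by Nelder-Mead refinement.
    """
    obs = np.asarray(obs, dtype=float)
    if not math.isclose(obs.sum(), 1.0, rel_tol=1e-6):
        raise ValueError("observed mismatch must sum to 1")
    jmax = len(obs) - 1
    if jmax == 0 or obs[0] >= 1.0 - 1e-12:
        exp0 = np.zeros_like(obs)
        exp0[0] = 1.0
        return MismatchResult(obs, exp0, 0.0, 0.0, 0.0, float(np.sum((obs - exp0) ** 2)))

    if tau_grid is None:
        tau_grid = np.linspace(0.0, max(4.0 * jmax, 10.0), 81)
    if theta0_grid is None:
        theta0_grid = np.linspace(0.0, 5.0, 21)
    if theta1_grid is None:
        theta1_grid = np.unique(np.concatenate([
            np.linspace(0.5, 10.0, 16),
            np.geomspace(10.0, theta1_max, 10),
        ]))

    def ssd(tau: float, t0: float, t1: float) -> float:
        return float(np.sum((obs - expected_mismatch(tau, t0, t1, jmax)) ** 2))

    best = (np.inf, 0.0, 0.0, float(theta1_max))
    for tau in tau_grid:
        for t0 in theta0_grid:
            for t1 in theta1_grid:
                if t1 < t0:
                    continue
                val = ssd(tau, t0, t1)
                if val < best[0]:
                    best = (val, float(tau), float(t0), float(t1))

    _, tau, t0, t1 = best
    if refine:
        def objective(x: np.ndarray) -> float:
            tt, a, b = x
            if tt < 0 or a < 0 or b < a or b > theta1_max:
                return 1e6
            return ssd(tt, a, b)

        res = optimize.minimize(
            objective, x0=[tau, t0, t1], method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000},
        )
        if res.fun <= best[0]:
            tau, t0, t1 = (float(v) for v in res.x)
    expected = expected_mismatch(tau, t0, t1, jmax)
    return MismatchResult(
        observed_freqs=obs,
        expected_freqs=expected,
        tau=tau,
        theta0=t0,
        theta1=t1,
        ssd=float(np.sum((obs - expected) ** 2)),
    )


def expansion_time(tau: float, rates: RateConstants) -> float:
    """Years before present of a sudden expansion: t = tau / (2 mu_seq)."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    return tau / (2.0 * rates.mu_seq)


def divergence_time(net_distance_per_site: float, rates: RateConstants) -> float:
    """Years since divergence from a per-site net distance: t = d / (2 mu_site)."""
    if net_distance_per_site < 0:
        raise ValueError("distance must be >= 0")
    return net_distance_per_site / (2.0 * rates.mu_site)
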