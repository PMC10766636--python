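"""Haploid coalescent simulator for three demographic scenarios.

Three populations (Madagascar, EastAfrica, WestAsia) connected by clean
split events; backward in time the daughter's lineages merge into the
ancestor at the split time. Sequence evolution is HKY with a proportion of
invariant sites and discrete-gamma rate heterogeneity, simulated exactly
by uniformization of the substitution process. Time is in years with a
one-year generation interval, so years equal generations.

Scenario topologies:
  1: Madagascar splits from WestAsia at T1; EastAfrica from Madagascar at
     Ta (T1 > Ta).
  2: Madagascar splits from WestAsia at T2; EastAfrica from WestAsia at Ta
     (no order constraint between T2 and Ta).
  3: EastAfrica splits from WestAsia at Ta; Madagascar from EastAfrica at
     T3 (Ta > T3).

Time priors: Ta ~ U(800, 1200); T1 ~ U(800, 2000) with T1 > Ta;
T2 ~ U(700, 2000); T3 ~ U(700, 1200) with Ta > T3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .diversity_stats import DEFAULT_MU_SITE
from .sequence_core import Alignment

POPULATIONS = ("Madagascar", "EastAfrica", "WestAsia")

# effective female population size prior (the one free choice not printed
# anywhere; uniform over a wide plausible range)
DEFAULT_SIZE_PRIOR = (10.0, 1.0e5)


@dataclass(frozen=True)
class SplitEvent:
    daughter: str
    ancestor: str
    time_param: str


@dataclass(frozen=True)
class DemographicScenario:
    scenario_id: int
    events: tuple[SplitEvent, ...]
    time_priors: dict[str, tuple[float, float]]
    # (a, b) pairs meaning "a must exceed b"
    order_constraints: tuple[tuple[str, str], ...] = ()
    size_priors: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {p: DEFAULT_SIZE_PRIOR for p in POPULATIONS}
    )


def scenario(
    scenario_id: int, size_prior: tuple[float, float] | None = None
) -> DemographicScenario:
    """Scenario definition; ``size_prior`` overrides the default effective
    population size prior (applied to every population)."""
    ta = (800.0, 1200.0)
    sizes = {p: (size_prior or DEFAULT_SIZE_PRIOR) for p in POPULATIONS}
    if scenario_id == 1:
        return DemographicScenario(
            1,
            events=(
                SplitEvent("EastAfrica", "Madagascar", "Ta"),
                SplitEvent("Madagascar", "WestAsia", "T1"),
            ),
            time_priors={"Ta": ta, "T1": (800.0, 2000.0)},
            order_constraints=(("T1", "Ta"),),
            size_priors=sizes,
        )
    if scenario_id == 2:
        return DemographicScenario(
            2,
            events=(
                SplitEvent("EastAfrica", "WestAsia", "Ta"),
                SplitEvent("Madagascar", "WestAsia", "T2"),
            ),
            time_priors={"Ta": ta, "T2": (700.0, 2000.0)},
            size_priors=sizes,
        )
    if scenario_id == 3:
        return DemographicScenario(
            3,
            events=(
                SplitEvent("Madagascar", "EastAfrica", "T3"),
                SplitEvent("EastAfrica", "WestAsia", "Ta"),
            ),
            time_priors={"Ta": ta, "T3": (700.0, 1200.0)},
            order_constraints=(("Ta", "T3"),),
            size_priors=sizes,
        )
    raise ValueError("scenario_id must be 1, 2 or 3")


ALL_SCENARIOS = (scenario(1), scenario(2), scenario(3))


@dataclass(frozen=True)
class MutationModel:
    """HKY + invariant sites + discrete gamma."""

    kappa: float = 10.0
    freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    p_inv: float = 0.5
    alpha: float = 0.5
    n_cat: int = 4
    mu_site: float = DEFAULT_MU_SITE

    def __post_init__(self) -> None:
        if abs(sum(self.freqs) - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")
        if self.kappa <= 0 or self.alpha <= 0 or not 0 <= self.p_inv < 1:
            raise ValueError("invalid mutation model parameters")

    def rate_matrix(self) -> np.ndarray:
        """HKY generator normalized to one expected substitution per unit time."""
        pi = np.asarray(self.freqs)
        Q = np.zeros((4, 4))
        transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                Q[i, j] = pi[j] * (self.kappa if (i, j) in transitions else 1.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -np.dot(pi, np.diag(Q))
        return Q / scale

    def gamma_category_rates(self) -> np.ndarray:
        """Mean rates of n_cat equal-probability bins of Gamma(alpha, 1/alpha)."""
        from scipy import stats

        k, a = self.n_cat, self.alpha
        bounds = stats.gamma.ppf(np.linspace(0, 1, k + 1), a, scale=1.0 / a)
        bounds[0], bounds[-1] = 0.0, np.inf
        # E[X; bin] for Gamma(a, scale=1/a): gammainc(a+1, a*b_hi) - gammainc(a+1, a*b_lo)
        upper = np.where(np.isinf(bounds), 1.0, special.gammainc(a + 1, a * bounds))
        rates = k * np.diff(upper)
        return rates / rates.mean() * 1.0


@dataclass
class Genealogy:
    """Coalescent tree: node 0..n-1 are leaves at time 0, times in years."""

    n_leaves: int
    parent: np.ndarray  # parent index per node, -1 for root
    time: np.ndarray  # node times (years before present)
    leaf_populations: list[str]

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    def tmrca(self) -> float:
        return float(self.time.max())

    def total_length(self) -> float:
        keep = self.parent >= 0
        return float(np.sum(self.time[self.parent[keep]] - self.time[keep]))

    def children(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for node, par in enumerate(self.parent):
            if par >= 0:
                out[par].append(node)
        return out


@dataclass
class SimulatedDataset:
    alignment: Alignment
    meta: pd.DataFrame
    truth: dict


def draw_priors(scn: DemographicScenario, rng: np.random.Generator) -> dict[str, float]:
    """One draw from the scenario priors, rejecting order-constraint violations."""
    while True:
        params = {
            name: rng.uniform(lo, hi) for name, (lo, hi) in scn.time_priors.items()
        }
        if all(params[a] > params[b] for a, b in scn.order_constraints):
            break
    for pop, (lo, hi) in scn.size_priors.items():
        params[f"N_{pop}"] = rng.uniform(lo, hi)
    return params


def simulate_genealogy(
    scn: DemographicScenario,
    params: dict[str, float],
    sample_sizes: dict[str, int],
    rng: np.random.Generator,
) -> Genealogy:
    """Haploid coalescent with population splits.

    Within a population of size N each lineage pair coalesces at rate 1/N
    per year; at a split time the daughter's lineages move into the
    ancestor.
    """
    leaf_pops: list[str] = []
    lineages: dict[str, list[int]] = {}
    for pop in POPULATIONS:
        k = int(sample_sizes.get(pop, 0))
        lineages[pop] = []
        for _ in range(k):
            lineages[pop].append(len(leaf_pops))
            leaf_pops.append(pop)
    n = len(leaf_pops)
    if n < 2:
        raise ValueError("need at least 2 sampled lineages")

    parent = list(np.full(n, -1, dtype=int))
    times = list(np.zeros(n))
    splits = sorted(
        ((params[ev.time_param], ev.daughter, ev.ancestor) for ev in scn.events),
        key=lambda e: e[0],
    )
    sizes = {pop: params.get(f"N_{pop}", DEFAULT_SIZE_PRIOR[0]) for pop in POPULATIONS}

    t = 0.0
    split_idx = 0
    total = n
    while total > 1:
        rates = {
            pop: len(lin) * (len(lin) - 1) / (2.0 * sizes[pop])
            for pop, lin in lineages.items()
            if len(lin) >= 2
        }
        total_rate = sum(rates.values())
        dt = rng.exponential(1.0 / total_rate) if total_rate > 0 else np.inf
        if split_idx < len(splits) and t + dt > splits[split_idx][0]:
            t_split, daughter, ancestor = splits[split_idx]
            t = t_split
            lineages[ancestor].extend(lineages[daughter])
            lineages[daughter] = []
            split_idx += 1
            continue
        if total_rate == 0:
            raise RuntimeError("no coalescence possible; scenario misconfigured")
        t += dt
        u = rng.random() * total_rate
        acc = 0.0
        for pop, rate in rates.items():
            acc += rate
            if u <= acc:
                break
        lin = lineages[pop]
        i, j = rng.choice(len(lin), size=2, replace=False)
        a, b = lin[i], lin[j]
        new = len(parent)
        parent.append(-1)
        times.append(t)
        parent[a] = parent[b] = new
        lin_new = [x for x in lin if x not in (a, b)]
        lin_new.append(new)
        lineages[pop] = lin_new
        total -= 1

    return Genealogy(
        n_leaves=n,
        parent=np.array(parent, dtype=int),
        time=np.array(times, dtype=float),
        leaf_populations=leaf_pops,
    )


def _uniformization(model: MutationModel) -> tuple[float, np.ndarray]:
    """Return (Lambda, cumulative transition rows) for the uniformized chain."""
    Q = model.rate_matrix()
    lam = float(np.max(-np.diag(Q)))
    R = np.eye(4) + Q / lam
    return lam, np.cumsum(R, axis=1)


def draw_site_rates(model: MutationModel, L: int, rng: np.random.Generator) -> np.ndarray:
    """Per-site rate multipliers: 0 with probability p_inv, else a discrete
    gamma category multiplier (mean 1 over variable sites)."""
    rates = model.gamma_category_rates()
    cat = rng.integers(0, model.n_cat, size=L)
    mult = rates[cat]
    mult[rng.random(L) < model.p_inv] = 0.0
    return mult


def mutate_sequences(
    tree: Genealogy,
    model: MutationModel,
    L: int,
    rng: np.random.Generator,
    site_multipliers: np.ndarray | None = None,
) -> np.ndarray:
    """Evolve sequences down the genealogy; returns (n_leaves, L) uint8 codes.

    The root sequence is drawn from the stationary frequencies; per branch,
    substitution events are generated by uniformization of the HKY chain at
    per-site rate mu * multiplier, which is exact for the CTMC.
    """
    if L <= 0:
        raise ValueError("L must be positive")
    if site_multipliers is None:
        site_multipliers = draw_site_rates(model, L, rng)
    lam, R_cum = _uniformization(model)
    site_rate = model.mu_site * site_multipliers * lam
    total_rate = float(site_rate.sum())
    if total_rate > 0:
        cum_sites = np.cumsum(site_rate) / total_rate
    children = tree.children()
    seqs: dict[int, np.ndarray] = {}
    root = tree.root
    seqs[root] = rng.choice(4, size=L, p=np.asarray(model.freqs)).astype(np.uint8)
    stack = [root]
    leaf_seqs = np.empty((tree.n_leaves, L), dtype=np.uint8)
    while stack:
        node = stack.pop()
        seq = seqs.pop(node)
        if node < tree.n_leaves:
            leaf_seqs[node] = seq
        for child in children[node]:
            branch = tree.time[node] - tree.time[child]
            cseq = seq.copy()
            if total_rate > 0 and branch > 0:
                n_events = rng.poisson(total_rate * branch)
                if n_events:
                    sites = np.searchsorted(cum_sites, rng.random(n_events))
                    us = rng.random(n_events)
                    for s, u in zip(sites, us):
                        cseq[s] = np.searchsorted(R_cum[cseq[s]], u)
            seqs[child] = cseq
            stack.append(child)
    return leaf_seqs


_DECODE = np.array(list("ACGT"))


def codes_to_alignment(codes: np.ndarray, sample_ids: list[str]) -> Alignment:
    seqs = ["".join(row) for row in _DECODE[codes]]
    return Alignment(sample_ids=sample_ids, seqs=seqs)


def simulate_raw(
    scn: DemographicScenario,
    params: dict[str, float],
    sample_sizes: dict[str, int],
    model: MutationModel,
    L: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[str]]:
    """Fast path: (codes matrix, per-row population labels)."""
    tree = simulate_genealogy(scn, params, sample_sizes, rng)
    codes = mutate_sequences(tree, model, L, rng)
    return codes, tree.leaf_populations


def simulate_dataset(
    scn: DemographicScenario,
    sample_sizes: dict[str, int],
    model: MutationModel | None = None,
    L: int = 1230,
    seed: int | None = None,
    params: dict[str, float] | None = None,
) -> SimulatedDataset:
    """Draw priors (unless given), simulate a genealogy and sequences, and
    package alignment + metadata + truth record."""
    model = model or MutationModel()
    rng = np.random.default_rng(seed)
    if params is None:
        params = draw_priors(scn, rng)
    codes, pops = simulate_raw(scn, params, sample_sizes, model, L, rng)
    ids = []
    counter: dict[str, int] = {}
    for pop in pops:
        counter[pop] = counter.get(pop, 0) + 1
        ids.append(f"{pop}_{counter[pop]:03d}")
    aln = codes_to_alignment(codes, ids)
    meta = pd.DataFrame(
        {
            "sample_id": ids,
            "locality": pops,
            "region": ["Lowland_west"] * len(ids),
            "elevation": [0] * len(ids),
            "population": pops,
        }
    )
    truth = {
        "scenario_id": scn.scenario_id,
        "params": {k: float(v) for k, v in params.items()},
        "sample_sizes": {k: int(v) for k, v in sample_sizes.items()},
        "L": L,
        "seed": seed,
        "model": {
            "kappa": model.kappa,
            "freqs": list(model.freqs),
            "p_inv": model.p_inv,
            "alpha": model.alpha,
            "n_cat": model.n_cat,
            "mu_site": model.mu_site,
        },
    }
    return SimulatedDataset(alignment=aln, meta=meta, truth=truth)
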