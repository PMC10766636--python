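"""Spatial population structure.

Within/between/net population distances, neighbor-joining over net
distances with midpoint rooting, AMOVA variance components from pairwise
difference counts, and a simulated-annealing SAMOVA search for the
K-group partition maximizing the among-group component FCT.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .sequence_core import Alignment, PairwiseDiffs, pairwise_differences


@dataclass
class PopDistanceMatrix:
    labels: list[str]
    within: np.ndarray  # dX, per-site mean pairwise distance within each pop
    between: np.ndarray  # dXY, per-site mean distance between pops
    net: np.ndarray  # dA = dXY - (dX + dY)/2, clamped at 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.net, index=self.labels, columns=self.labels)


@dataclass
class PopTree:
    """A tree over subpopulation labels, branch lengths in substitutions/site."""

    tree: dendropy.Tree
    zero_diameter: bool = False

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def leaf_labels(self) -> list[str]:
        return sorted(lf.taxon.label for lf in self.tree.leaf_node_iter())

    def leaf_distances(self) -> pd.DataFrame:
        pdm = self.tree.phylogenetic_distance_matrix()
        labels = self.leaf_labels()
        taxa = {t.label: t for t in self.tree.taxon_namespace}
        out = np.zeros((len(labels), len(labels)))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    out[i, j] = out[j, i] = pdm.patristic_distance(taxa[a], taxa[b])
        return pd.DataFrame(out, index=labels, columns=labels)


@dataclass
class SamovaResult:
    K: int
    labels: list[str]
    partition: list[list[str]]
    sigma_a: float
    sigma_b: float
    sigma_c: float
    fct: float
    fsc: float
    fst: float
    trace: list[float] = field(default_factory=list)
    n_restarts: int = 0
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "partition": self.partition,
            "sigma_a": self.sigma_a,
            "sigma_b": self.sigma_b,
            "sigma_c": self.sigma_c,
            "FCT": self.fct,
            "FSC": self.fsc,
            "FST": self.fst,
            "n_restarts": self.n_restarts,
            "seed": self.seed,
        }


def _group_indices(aln: Alignment, meta: pd.DataFrame, group_by: str) -> dict[str, np.ndarray]:
    pos = {sid: i for i, sid in enumerate(aln.sample_ids)}
    meta = meta[meta["sample_id"].isin(pos)]
    groups: dict[str, np.ndarray] = {}
    for label, sub in meta.groupby(group_by, sort=True):
        groups[str(label)] = np.array([pos[s] for s in sub["sample_id"]], dtype=int)
    if len(groups) < 1:
        raise ValueError(f"no groups found for column {group_by!r}")
    covered = set().union(*(set(v.tolist()) for v in groups.values()))
    if covered != set(range(aln.n)):
        missing = [aln.sample_ids[i] for i in set(range(aln.n)) - covered]
        raise ValueError(f"samples absent from metadata groups: {missing}")
    return groups


def pop_distances(
    aln: Alignment,
    meta: pd.DataFrame,
    group_by: str = "locality",
    diffs: PairwiseDiffs | None = None,
) -> PopDistanceMatrix:
    """Per-site p-distances within/between groups and clamped net distances.

    Pairwise deletion throughout; a singleton group has within-distance 0;
    negative net distances are reported as 0.
    """
    groups = _group_indices(aln, meta, group_by)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if diffs is None:
        diffs = pairwise_differences(aln)
    P = diffs.per_site()
    labels = sorted(groups)
    m = len(labels)
    within = np.zeros(m)
    for a, lab in enumerate(labels):
        idx = groups[lab]
        if len(idx) > 1:
            sub = P[np.ix_(idx, idx)]
            iu = np.triu_indices(len(idx), k=1)
            within[a] = sub[iu].mean()
    between = np.zeros((m, m))
    net = np.zeros((m, m))
    for a in range(m):
        for b in range(a + 1, m):
            ia, ib = groups[labels[a]], groups[labels[b]]
            dxy = float(P[np.ix_(ia, ib)].mean())
            between[a, b] = between[b, a] = dxy
            da = max(0.0, dxy - 0.5 * (within[a] + within[b]))
            net[a, b] = net[b, a] = da
    return PopDistanceMatrix(labels=labels, within=within, between=between, net=net)


# ---------------------------------------------------------------------------
# Neighbor joining (Saitou & Nei) with negative-branch clamping


def _quote_label(label: str) -> str:
    if any(c in label for c in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _nj_newick(labels: list[str], D: np.ndarray) -> str:
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    D = np.asarray(D, dtype=float).copy()
    if D.shape != (n, n) or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    labels = [_quote_label(lab) for lab in labels]
    if n == 2:
        return f"({labels[0]}:{D[0, 1]:.10g},{labels[1]}:0):0;"
    nodes = [f"{lab}" for lab in labels]  # newick fragments

    def join_pair(i: int, j: int, li: float, lj: float) -> str:
        # clamp a negative branch to 0 and transfer the deficit so the
        # path length through the new node is preserved
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        return f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"

    active = list(range(n))
    while len(active) > 3:
        k = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        ai, aj = np.unravel_index(np.argmin(Q), Q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (k - 2))
        lj = dij - li
        frag = join_pair(i, j, li, lj)
        # distances from the new node u
        du = 0.5 * (D[i, active] + D[j, active] - dij)
        D[i, active] = du
        D[active, i] = du
        D[i, i] = 0.0
        nodes[i] = frag
        active.remove(j)
    a, b, c = active
    # final trifurcation branch lengths
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    la, lb, lc = (max(0.0, v) for v in (la, lb, lc))
    return f"({nodes[a]}:{la:.10g},{nodes[b]}:{lb:.10g},{nodes[c]}:{lc:.10g});"


def nj_tree(d: PopDistanceMatrix | pd.DataFrame) -> PopTree:
    """Neighbor-joining tree from a net-distance matrix."""
    if isinstance(d, PopDistanceMatrix):
        labels, mat = d.labels, d.net
    else:
        labels, mat = [str(x) for x in d.index], d.to_numpy()
    nwk = _nj_newick(labels, mat)
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    return PopTree(tree=tree)


def midpoint_root(t: PopTree) -> PopTree:
    """Root at the midpoint of the longest leaf-to-leaf path."""
    tree = t.tree.clone(depth=1)
    pdm = tree.phylogenetic_distance_matrix()
    diameter = max(
        (pdm.patristic_distance(a, b) for a, b in itertools.combinations(tree.taxon_namespace, 2)),
        default=0.0,
    )
    if diameter == 0.0:
        return PopTree(tree=tree, zero_diameter=True)
    tree.reroot_at_midpoint(update_bipartitions=True)
    return PopTree(tree=tree)


# ---------------------------------------------------------------------------
# AMOVA / SAMOVA


def _pop_cross_sums(diffs: PairwiseDiffs, groups: dict[str, np.ndarray]) -> tuple[list[str], np.ndarray, np.ndarray]:
    """W[p, q] = sum over i in p, j in q of squared distance (= diff count)."""
    labels = sorted(groups)
    m = len(labels)
    W = np.zeros((m, m))
    sizes = np.zeros(m, dtype=int)
    D = diffs.diffs.astype(float)
    for a, la in enumerate(labels):
        sizes[a] = len(groups[la])
        for b, lb in enumerate(labels):
            W[a, b] = D[np.ix_(groups[la], groups[lb])].sum()
    return labels, W, sizes


def _amova_components(
    W: np.ndarray, sizes: np.ndarray, assignment: np.ndarray, K: int
) -> tuple[float, float, float]:
    """Excoffier-Smouse-Quattro nested variance components.

    ``assignment`` maps population index -> group index (0..K-1). Distances
    entering W are squared Euclidean (pairwise difference counts).
    """
    N = sizes.sum()
    P = len(sizes)
    ss_total = W.sum() / (2.0 * N)
    ss_wp = sum(W[p, p] / (2.0 * sizes[p]) for p in range(P))
    ss_groups = 0.0
    n_g = np.zeros(K)
    sum_np2_over_ng = 0.0
    for g in range(K):
        pops = np.flatnonzero(assignment == g)
        ng = sizes[pops].sum()
        n_g[g] = ng
        ss_groups += W[np.ix_(pops, pops)].sum() / (2.0 * ng)
        sum_np2_over_ng += (sizes[pops] ** 2).sum() / ng
    ss_ag = ss_total - ss_groups
    ss_apwg = ss_groups - ss_wp

    df_ag = K - 1
    df_apwg = P - K
    df_wp = N - P
    sigma_c = ss_wp / df_wp if df_wp > 0 else 0.0
    if df_apwg > 0:
        n_prime = (N - sum_np2_over_ng) / df_apwg
        sigma_b = (ss_apwg / df_apwg - sigma_c) / n_prime if n_prime > 0 else 0.0
    else:
        sigma_b = 0.0
    n_dprime = (sum_np2_over_ng - (sizes**2).sum() / N) / df_ag
    n_tprime = (N - (n_g**2).sum() / N) / df_ag
    sigma_a = (ss_ag / df_ag - sigma_c - n_dprime * sigma_b) / n_tprime
    return float(sigma_a), float(sigma_b), float(sigma_c)


def _phi_stats(sa: float, sb: float, sc: float) -> tuple[float, float, float]:
    tot = sa + sb + sc
    if tot == 0:
        return 0.0, 0.0, 0.0
    fct = sa / tot
    fsc = sb / (sb + sc) if (sb + sc) != 0 else 0.0
    fst = (sa + sb) / tot
    return fct, fsc, fst


def amova(
    aln: Alignment,
    meta: pd.DataFrame,
    partition: list[list[str]],
    group_by: str = "locality",
    diffs: PairwiseDiffs | None = None,
) -> SamovaResult:
    """AMOVA Phi-statistics for a fixed partition of subpopulations."""
    groups = _group_indices(aln, meta, group_by)
    labels = sorted(groups)
    flat = [p for block in partition for p in block]
    if sorted(flat) != labels:
        raise ValueError("partition must cover every subpopulation exactly once")
    if diffs is None:
        diffs = pairwise_differences(aln)
    labels, W, sizes = _pop_cross_sums(diffs, groups)
    assignment = np.zeros(len(labels), dtype=int)
    for g, block in enumerate(partition):
        for p in block:
            assignment[labels.index(p)] = g
    sa, sb, sc = _amova_components(W, sizes, assignment, K=len(partition))
    fct, fsc, fst = _phi_stats(sa, sb, sc)
    return SamovaResult(
        K=len(partition), labels=labels,
        partition=[sorted(b) for b in partition],
        sigma_a=sa, sigma_b=sb, sigma_c=sc, fct=fct, fsc=fsc, fst=fst,
    )


def _assignment_to_partition(labels: list[str], assignment: np.ndarray, K: int) -> list[list[str]]:
    blocks = [[] for _ in range(K)]
    for p, g in enumerate(assignment):
        blocks[g].append(labels[p])
    blocks = [sorted(b) for b in blocks if b]
    return sorted(blocks)


def _contiguous(assignment: np.ndarray, K: int, adj: np.ndarray) -> bool:
    for g in range(K):
        pops = np.flatnonzero(assignment == g)
        if len(pops) <= 1:
            continue
        seen = {pops[0]}
        stack = [pops[0]]
        popset = set(pops.tolist())
        while stack:
            cur = stack.pop()
            for nb in np.flatnonzero(adj[cur]):
                if nb in popset and nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if len(seen) != len(pops):
            return False
    return True


def samova(
    aln: Alignment,
    meta: pd.DataFrame,
    K: int,
    group_by: str = "locality",
    n_restarts: int = 20,
    seed: int | None = None,
    t0: float = 1.0,
    cooling: float = 0.95,
    steps_per_temp: int = 100,
    t_min: float = 1e-3,
    adjacency: pd.DataFrame | None = None,
    diffs: PairwiseDiffs | None = None,
) -> SamovaResult:
    """Simulated-annealing search for the K-group partition maximizing FCT.

    Geometric cooling; one move reassigns a single deme to another group.
    ``adjacency`` (optional boolean deme x deme frame) restricts groups to
    geographically contiguous sets. Deterministic given ``seed``.
    """
    groups = _group_indices(aln, meta, group_by)
    labels = sorted(groups)
    P = len(labels)
    if not 2 <= K < P:
        raise ValueError(f"K must satisfy 2 <= K < {P}")
    if diffs is None:
        diffs = pairwise_differences(aln)
    labels, W, sizes = _pop_cross_sums(diffs, groups)
    adj = None
    if adjacency is not None:
        adj = adjacency.loc[labels, labels].to_numpy().astype(bool)

    rng = np.random.default_rng(seed)

    def fct_of(assignment: np.ndarray) -> float:
        if len(np.unique(assignment)) < K:
            return -np.inf
        if adj is not None and not _contiguous(assignment, K, adj):
            return -np.inf
        sa, sb, sc = _amova_components(W, sizes, assignment, K)
        return _phi_stats(sa, sb, sc)[0]

    best_assignment = None
    best_fct = -np.inf
    trace: list[float] = []
    for _ in range(n_restarts):
        while True:
            assignment = rng.integers(0, K, size=P)
            if fct_of(assignment) > -np.inf:
                break
        cur_fct = fct_of(assignment)
        temp = t0
        while temp > t_min:
            for _step in range(steps_per_temp):
                cand = assignment.copy()
                deme = rng.integers(P)
                new_g = rng.integers(K)
                if new_g == cand[deme]:
                    continue
                cand[deme] = new_g
                cand_fct = fct_of(cand)
                if cand_fct == -np.inf:
                    continue
                if cand_fct >= cur_fct or rng.random() < np.exp((cand_fct - cur_fct) / temp):
                    assignment, cur_fct = cand, cand_fct
                    if cur_fct > best_fct:
                        best_fct = cur_fct
                        best_assignment = assignment.copy()
            temp *= cooling
        trace.append(cur_fct)
    assert best_assignment is not None
    sa, sb, sc = _amova_components(W, sizes, best_assignment, K)
    fct, fsc, fst = _phi_stats(sa, sb, sc)
    return SamovaResult(
        K=K, labels=labels,
        partition=_assignment_to_partition(labels, best_assignment, K),
        sigma_a=sa, sigma_b=sb, sigma_c=sc, fct=fct, fsc=fsc, fst=fst,
        trace=trace, n_restarts=n_restarts, seed=seed,
    )


def exhaustive_samova_k2(
    aln: Alignment,
    meta: pd.DataFrame,
    group_by: str = "locality",
    diffs: PairwiseDiffs | None = None,
) -> SamovaResult:
    """Exhaustive maximum-FCT bipartition (oracle-scale, <= ~15 demes)."""
    groups = _group_indices(aln, meta, group_by)
    labels = sorted(groups)
    P = len(labels)
    if P > 16:
        raise ValueError("exhaustive search limited to 16 demes")
    if diffs is None:
        diffs = pairwise_differences(aln)
    labels, W, sizes = _pop_cross_sums(diffs, groups)
    best = (-np.inf, None)
    for mask in range(1, 2 ** (P - 1)):
        assignment = np.array([(mask >> p) & 1 for p in range(P)], dtype=int)
        sa, sb, sc = _amova_components(W, sizes, assignment, 2)
        fct = _phi_stats(sa, sb, sc)[0]
        if fct > best[0]:
            best = (fct, assignment)
    fct, assignment = best
    sa, sb, sc = _amova_components(W, sizes, assignment, 2)
    fct, fsc, fst = _phi_stats(sa, sb, sc)
    return SamovaResult(
        K=2, labels=labels,
        partition=_assignment_to_partition(labels, assignment, 2),
        sigma_a=sa, sigma_b=sb, sigma_c=sc, fct=fct, fsc=fsc, fst=fst,
    )
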