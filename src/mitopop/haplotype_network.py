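"""Median-joining haplotype network construction.

Iterates an epsilon-relaxed minimum spanning network over the current node
set, adds majority-consensus (median) vectors of connected triplets when
they shorten connections, and finally prunes obsolete median vectors so
that every retained median has degree >= 3.

Character weights are uniform; alignment columns containing any
missing/ambiguous symbol in any haplotype are excluded from network
distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequence_core import HaplotypeTable

_MAX_ITER = 50


@dataclass
class NetworkNode:
    node_id: str
    seq: str
    count: int
    is_median: bool
    members: list[str] = field(default_factory=list)


@dataclass
class HaploNetwork:
    nodes: list[NetworkNode]
    edges: list[tuple[str, str, int]]  # (u, v, mutation steps)
    epsilon: int

    def node_table(self, locality_of: dict[str, str] | None = None) -> pd.DataFrame:
        rows = []
        for nd in self.nodes:
            row = {
                "node_id": nd.node_id,
                "count": nd.count,
                "is_median": nd.is_median,
                "members": ",".join(nd.members),
            }
            if locality_of is not None:
                locs: dict[str, int] = {}
                for m in nd.members:
                    loc = locality_of.get(m, "?")
                    locs[loc] = locs.get(loc, 0) + 1
                row["localities"] = ";".join(f"{k}:{v}" for k, v in sorted(locs.items()))
            rows.append(row)
        return pd.DataFrame(rows)

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["u", "v", "steps"])

    def degree(self, node_id: str) -> int:
        return sum(1 for u, v, _ in self.edges if node_id in (u, v))

    def total_weight(self) -> int:
        return sum(w for _, _, w in self.edges)

    def is_connected(self) -> bool:
        if not self.nodes:
            return True
        adj: dict[str, set[str]] = {nd.node_id: set() for nd in self.nodes}
        for u, v, _ in self.edges:
            adj[u].add(v)
            adj[v].add(u)
        seen = {self.nodes[0].node_id}
        stack = [self.nodes[0].node_id]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == len(self.nodes)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def _hamming(a: np.ndarray, b: np.ndarray) -> int:
    return int(np.sum(a != b))


def _distance_matrix(mats: list[np.ndarray]) -> np.ndarray:
    k = len(mats)
    D = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            D[i, j] = D[j, i] = _hamming(mats[i], mats[j])
    return D


def _msn_edges(D: np.ndarray, epsilon: int) -> list[tuple[int, int, int]]:
    """Epsilon-relaxed minimum spanning network.

    An edge of weight w is included iff its endpoints are not connected by
    the subgraph of all edges with weight < w - epsilon.
    """
    k = D.shape[0]
    all_edges = sorted(
        (int(D[i, j]), i, j) for i in range(k) for j in range(i + 1, k)
    )
    out = []
    for w in sorted({e[0] for e in all_edges}):
        uf = _UnionFind(range(k))
        for w2, i, j in all_edges:
            if w2 < w - epsilon:
                uf.union(i, j)
        for w2, i, j in all_edges:
            if w2 == w and uf.find(i) != uf.find(j):
                out.append((i, j, w2))
    return out


def _median_seq(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Site-wise majority consensus; three-way ties keep the first sequence."""
    med = a.copy()
    med[b == c] = b[b == c]
    return med


def build_mj_network(
    ht: HaplotypeTable, epsilon: int = 0, max_iter: int = _MAX_ITER
) -> HaploNetwork:
    """Median-joining network of a haplotype table (Bandelt-style).

    Deterministic: haplotypes are processed in table order, candidate
    medians in lexicographic sequence order.
    """
    if ht.k < 2:
        raise ValueError("need at least 2 haplotypes")
    L = len(ht.seqs[0])
    if any(len(s) != L for s in ht.seqs):
        raise ValueError("unaligned input: haplotype lengths differ")

    # exclude columns with any non-ACGT symbol from network distances
    arr = np.array([list(s) for s in ht.seqs])
    keep = np.all(np.isin(arr, list("ACGT")), axis=0)
    obs_mats = [np.frombuffer(s.encode(), dtype=np.uint8)[keep].copy() for s in ht.seqs]

    median_mats: list[np.ndarray] = []

    def node_mats() -> list[np.ndarray]:
        return obs_mats + median_mats

    def known(seq: np.ndarray) -> bool:
        return any(np.array_equal(seq, m) for m in node_mats())

    for _ in range(max_iter):
        mats = node_mats()
        D = _distance_matrix(mats)
        edges = _msn_edges(D, epsilon)
        adj: dict[int, set[int]] = {i: set() for i in range(len(mats))}
        for i, j, _w in edges:
            adj[i].add(j)
            adj[j].add(i)
        candidates: list[tuple[int, bytes, np.ndarray]] = []
        for v in range(len(mats)):
            nbrs = sorted(adj[v])
            for ai in range(len(nbrs)):
                for bi in range(ai + 1, len(nbrs)):
                    u, w = nbrs[ai], nbrs[bi]
                    med = _median_seq(mats[v], mats[u], mats[w])
                    if known(med):
                        continue
                    lam = (
                        _hamming(med, mats[v])
                        + _hamming(med, mats[u])
                        + _hamming(med, mats[w])
                    )
                    candidates.append((lam, med.tobytes(), med))
        if not candidates:
            break
        lam_min = min(c[0] for c in candidates)
        added = set()
        for lam, key, med in sorted(candidates, key=lambda c: (c[0], c[1])):
            if lam <= lam_min + epsilon and key not in added:
                median_mats.append(med)
                added.add(key)

    # prune obsolete medians: recompute the MSN and drop median vectors of
    # degree <= 2 until stable
    while True:
        mats = node_mats()
        D = _distance_matrix(mats)
        edges = _msn_edges(D, epsilon)
        deg = {i: 0 for i in range(len(mats))}
        for i, j, _w in edges:
            deg[i] += 1
            deg[j] += 1
        n_obs = len(obs_mats)
        drop = [
            i - n_obs
            for i in range(n_obs, len(mats))
            if deg[i] <= 2
        ]
        if not drop:
            break
        for d in sorted(drop, reverse=True):
            median_mats.pop(d)

    mats = node_mats()
    D = _distance_matrix(mats)
    edges = _msn_edges(D, epsilon)

    nodes: list[NetworkNode] = []
    names: list[str] = []
    for i in range(len(mats)):
        if i < len(obs_mats):
            nodes.append(
                NetworkNode(
                    node_id=ht.haplotype_ids[i],
                    seq=ht.seqs[i],
                    count=int(ht.counts[i]),
                    is_median=False,
                    members=list(ht.members[i]),
                )
            )
        else:
            nodes.append(
                NetworkNode(
                    node_id=f"mv{i - len(obs_mats) + 1}",
                    seq=mats[i].tobytes().decode(),
                    count=0,
                    is_median=True,
                )
            )
        names.append(nodes[-1].node_id)
    edge_list = sorted(
        (names[i], names[j], int(w)) for i, j, w in edges
    )
    return HaploNetwork(nodes=nodes, edges=edge_list, epsilon=epsilon)
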