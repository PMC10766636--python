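import itertools

import numpy as np
import pandas as pd
import pytest

from mitopop import sequence_core as sc
from mitopop import spatial_structure as ss

from conftest import random_alignment


def make_meta(aln, localities, region="Lowland_west", elevation=10.0):
    return pd.DataFrame(
        {
            "sample_id": aln.sample_ids,
            "locality": localities,
            "region": [region] * aln.n,
            "elevation": [elevation] * aln.n,
            "population": ["Madagascar"] * aln.n,
        }
    )


def brute_force_amova(diff_matrix, pops, partition_of_pop):
    """Literal sums-of-squares decomposition over all pairs (oracle)."""
    pops = np.asarray(pops)
    groups = np.array([partition_of_pop[p] for p in pops])
    N = len(pops)
    d2 = diff_matrix.astype(float)

    def ss_within(labels):
        total = 0.0
        for lab in np.unique(labels):
            idx = np.flatnonzero(labels == lab)
            total += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
        return total

    ss_total = d2.sum() / (2.0 * N)
    ss_wp = ss_within(pops)
    ss_wg = ss_within(groups)
    ss_ag = ss_total - ss_wg
    ss_apwg = ss_wg - ss_wp

    pop_labels = np.unique(pops)
    group_labels = np.unique(groups)
    P, K = len(pop_labels), len(group_labels)
    sizes = {p: np.sum(pops == p) for p in pop_labels}
    g_sizes = {g: np.sum(groups == g) for g in group_labels}
    sum_np2_over_ng = sum(
        sum(sizes[p] ** 2 for p in pop_labels if partition_of_pop[p] == g) / g_sizes[g]
        for g in group_labels
    )
    sigma_c = ss_wp / (N - P)
    n_prime = (N - sum_np2_over_ng) / (P - K)
    sigma_b = (ss_apwg / (P - K) - sigma_c) / n_prime
    n_dprime = (sum_np2_over_ng - sum(v**2 for v in sizes.values()) / N) / (K - 1)
    n_tprime = (N - sum(v**2 for v in g_sizes.values()) / N) / (K - 1)
    sigma_a = (ss_ag / (K - 1) - sigma_c - n_dprime * sigma_b) / n_tprime
    return sigma_a, sigma_b, sigma_c


class TestPopDistances:
    def test_identical_groups_zero_net(self):
        aln = sc.Alignment(
            ["a1", "a2", "b1", "b2"], ["AAAA", "AAAT", "AAAA", "AAAT"]
        )
        meta = make_meta(aln, ["X", "X", "Y", "Y"])
        d = ss.pop_distances(aln, meta)
        assert d.net[0, 1] == 0.0

    def test_negative_net_clamped(self):
        # within-diversity exceeds between -> raw net negative -> 0
        aln = sc.Alignment(
            ["a1", "a2", "b1", "b2"], ["AAAA", "TTTT", "AAAA", "TTTT"]
        )
        meta = make_meta(aln, ["X", "X", "Y", "Y"])
        d = ss.pop_distances(aln, meta)
        # dXY = mean(0,1,1,0)=0.5, dX=dY=1 -> raw -0.5 -> clamped
        assert d.net[0, 1] == 0.0

    def test_divergent_groups(self):
        aln = sc.Alignment(
            ["a1", "a2", "b1", "b2"], ["AAAA", "AAAA", "TTAA", "TTAA"]
        )
        meta = make_meta(aln, ["X", "X", "Y", "Y"])
        d = ss.pop_distances(aln, meta)
        assert d.within[0] == 0.0
        assert d.between[0, 1] == pytest.approx(0.5)
        assert d.net[0, 1] == pytest.approx(0.5)

    def test_singleton_group_within_zero(self):
        aln = sc.Alignment(["a1", "b1", "b2"], ["AAAA", "AATT", "AATA"])
        meta = make_meta(aln, ["X", "Y", "Y"])
        d = ss.pop_distances(aln, meta)
        assert d.within[list(d.labels).index("X")] == 0.0


class TestNJTree:
    def test_two_taxa(self):
        d = pd.DataFrame([[0.0, 0.1], [0.1, 0.0]], index=["A", "B"], columns=["A", "B"])
        tree = ss.nj_tree(d)
        assert tree.leaf_distances().loc["A", "B"] == pytest.approx(0.1)

    def test_three_taxa_ultrametric_cherry(self):
        labels = ["A", "B", "C"]
        mat = np.array([[0, 0.2, 1.0], [0.2, 0, 1.0], [1.0, 1.0, 0]])
        tree = ss.nj_tree(pd.DataFrame(mat, index=labels, columns=labels))
        ld = tree.leaf_distances()
        assert ld.loc["A", "B"] == pytest.approx(0.2)
        assert ld.loc["A", "C"] == pytest.approx(1.0)

    def test_additive_matrix_recovered_exactly(self):
        # known tree: A-u:2, B-u:3, u-v:1, C-v:4, D-v:5
        labels = ["A", "B", "C", "D"]
        mat = np.array(
            [
                [0.0, 5.0, 7.0, 8.0],
                [5.0, 0.0, 8.0, 9.0],
                [7.0, 8.0, 0.0, 9.0],
                [8.0, 9.0, 9.0, 0.0],
            ]
        )
        # four-point condition sanity for the oracle matrix
        sums = sorted([mat[0, 1] + mat[2, 3], mat[0, 2] + mat[1, 3], mat[0, 3] + mat[1, 2]])
        assert sums[1] == sums[2] and sums[0] <= sums[1]
        tree = ss.nj_tree(pd.DataFrame(mat, index=labels, columns=labels))
        ld = tree.leaf_distances()
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                assert ld.loc[a, b] == pytest.approx(mat[i, j], abs=1e-9)

    def test_nonsymmetric_rejected(self):
        d = pd.DataFrame([[0.0, 0.1], [0.2, 0.0]], index=["A", "B"], columns=["A", "B"])
        with pytest.raises(ValueError):
            ss.nj_tree(d)

    def test_branch_lengths_nonnegative(self, rng):
        for _ in range(5):
            labels = list("ABCDE")
            m = rng.random((5, 5)) * 0.01
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0.0)
            tree = ss.nj_tree(pd.DataFrame(m, index=labels, columns=labels))
            for edge in tree.tree.preorder_edge_iter():
                assert edge.length is None or edge.length >= 0


class TestMidpointRoot:
    def test_two_leaves_split_evenly(self):
        d = pd.DataFrame([[0.0, 0.4], [0.4, 0.0]], index=["A", "B"], columns=["A", "B"])
        rooted = ss.midpoint_root(ss.nj_tree(d))
        root = rooted.tree.seed_node
        depths = {}
        for leaf in rooted.tree.leaf_node_iter():
            depths[leaf.taxon.label] = leaf.distance_from_root()
        assert depths["A"] == pytest.approx(0.2)
        assert depths["B"] == pytest.approx(0.2)

    def test_caterpillar_root_on_diameter_path(self):
        # brute-force all-pairs path lengths identify the diameter pair
        labels = ["A", "B", "C", "D"]
        mat = np.array(
            [
                [0.0, 5.0, 7.0, 8.0],
                [5.0, 0.0, 8.0, 9.0],
                [7.0, 8.0, 0.0, 9.0],
                [8.0, 9.0, 9.0, 0.0],
            ]
        )
        diameter_pair = max(
            itertools.combinations(range(4), 2), key=lambda ij: mat[ij[0], ij[1]]
        )
        assert {labels[i] for i in diameter_pair} == {"B", "D"}
        rooted = ss.midpoint_root(ss.nj_tree(pd.DataFrame(mat, index=labels, columns=labels)))
        depths = {
            leaf.taxon.label: leaf.distance_from_root()
            for leaf in rooted.tree.leaf_node_iter()
        }
        # both diameter endpoints are at half the diameter from the root
        assert depths["B"] == pytest.approx(4.5)
        assert depths["D"] == pytest.approx(4.5)
        assert max(depths.values()) == pytest.approx(4.5)

    def test_symmetric_tree_centered(self):
        labels = ["A", "B"]
        d = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=labels, columns=labels)
        rooted = ss.midpoint_root(ss.nj_tree(d))
        depths = [lf.distance_from_root() for lf in rooted.tree.leaf_node_iter()]
        assert depths == pytest.approx([0.5, 0.5])

    def test_zero_diameter_flagged(self):
        d = pd.DataFrame([[0.0, 0.0], [0.0, 0.0]], index=["A", "B"], columns=["A", "B"])
        rooted = ss.midpoint_root(ss.nj_tree(d))
        assert rooted.zero_diameter


class TestAmova:
    def test_identical_groups_fct_zero(self, rng):
        aln = sc.Alignment(
            [f"s{i}" for i in range(8)],
            ["AAAA", "AATT", "AAAA", "AATT", "AAAA", "AATT", "AAAA", "AATT"],
        )
        meta = make_meta(aln, ["p1", "p1", "p2", "p2", "p3", "p3", "p4", "p4"])
        res = ss.amova(aln, meta, partition=[["p1", "p2"], ["p3", "p4"]])
        assert res.fct == pytest.approx(0.0, abs=1e-12)

    def test_fixed_groups_fct_one(self):
        aln = sc.Alignment(
            [f"s{i}" for i in range(8)],
            ["AAAA"] * 4 + ["TTTT"] * 4,
        )
        meta = make_meta(aln, ["p1", "p1", "p2", "p2", "p3", "p3", "p4", "p4"])
        res = ss.amova(aln, meta, partition=[["p1", "p2"], ["p3", "p4"]])
        assert res.fct == pytest.approx(1.0)
        assert res.sigma_b == pytest.approx(0.0, abs=1e-12)
        assert res.sigma_c == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force(self, rng):
        for _ in range(8):
            aln = random_alignment(rng, n=18, L=60, n_variants=3)
            locs = [f"p{i % 6}" for i in range(18)]
            meta = make_meta(aln, locs)
            partition = [["p0", "p1", "p2"], ["p3", "p4"], ["p5"]]
            res = ss.amova(aln, meta, partition)
            part_of = {p: g for g, blk in enumerate(partition) for p in blk}
            d = sc.pairwise_differences(aln).diffs
            sa, sb, scc = brute_force_amova(d, locs, part_of)
            assert res.sigma_a == pytest.approx(sa, abs=1e-9)
            assert res.sigma_b == pytest.approx(sb, abs=1e-9)
            assert res.sigma_c == pytest.approx(scc, abs=1e-9)

    def test_invariant_to_relabeling_within_groups(self, rng):
        aln = random_alignment(rng, n=12, L=50, n_variants=2)
        locs = [f"p{i % 4}" for i in range(12)]
        meta = make_meta(aln, locs)
        r1 = ss.amova(aln, meta, [["p0", "p1"], ["p2", "p3"]])
        r2 = ss.amova(aln, meta, [["p1", "p0"], ["p3", "p2"]])
        assert r1.fct == pytest.approx(r2.fct)
        assert r1.fsc == pytest.approx(r2.fsc)

    def test_partition_must_cover(self, rng):
        aln = random_alignment(rng, n=6, L=20)
        meta = make_meta(aln, ["p0", "p0", "p1", "p1", "p2", "p2"])
        with pytest.raises(ValueError):
            ss.amova(aln, meta, [["p0"], ["p1"]])


def two_cluster_dataset(rng, n_demes=6, per_deme=4, split_steps=6):
    """Demes 0..2 around one founder, 3.. around a divergent founder."""
    L = 120
    f1 = rng.integers(0, 4, size=L)
    f2 = f1.copy()
    for s in rng.choice(L, size=split_steps, replace=False):
        f2[s] = (f2[s] + 1) % 4
    seqs, locs = [], []
    for deme in range(n_demes):
        base = f1 if deme < n_demes // 2 else f2
        for _ in range(per_deme):
            seq = base.copy()
            for s in rng.choice(L, size=rng.poisson(1), replace=False):
                seq[s] = (seq[s] + rng.integers(1, 4)) % 4
            seqs.append("".join("ACGT"[b] for b in seq))
            locs.append(f"deme{deme}")
    ids = [f"x{i}" for i in range(len(seqs))]
    aln = sc.Alignment(ids, seqs)
    return aln, make_meta(aln, locs)


class TestSamova:
    def test_recovers_deep_split(self, rng):
        aln, meta = two_cluster_dataset(rng)
        res = ss.samova(aln, meta, K=2, n_restarts=5, seed=7)
        assert sorted(res.partition) == [
            ["deme0", "deme1", "deme2"],
            ["deme3", "deme4", "deme5"],
        ]

    def test_matches_exhaustive_maximum(self, rng):
        for seed in range(3):
            aln, meta = two_cluster_dataset(rng, n_demes=5, per_deme=3, split_steps=3)
            ann = ss.samova(aln, meta, K=2, n_restarts=5, seed=seed)
            exact = ss.exhaustive_samova_k2(aln, meta)
            assert ann.fct == pytest.approx(exact.fct, abs=1e-12)

    def test_beats_or_equals_fixed_partition(self, rng):
        aln, meta = two_cluster_dataset(rng)
        res = ss.samova(aln, meta, K=2, n_restarts=5, seed=3)
        fixed = ss.amova(
            aln, meta, [["deme0", "deme1"], ["deme2", "deme3", "deme4", "deme5"]]
        )
        assert res.fct >= fixed.fct - 1e-12

    def test_k_out_of_range(self, rng):
        aln, meta = two_cluster_dataset(rng, n_demes=3, per_deme=3)
        with pytest.raises(ValueError):
            ss.samova(aln, meta, K=3, seed=0)
        with pytest.raises(ValueError):
            ss.samova(aln, meta, K=1, seed=0)

    def test_deterministic_given_seed(self, rng):
        aln, meta = two_cluster_dataset(rng)
        a = ss.samova(aln, meta, K=2, n_restarts=3, seed=11)
        b = ss.samova(aln, meta, K=2, n_restarts=3, seed=11)
        assert a.partition == b.partition
        assert a.fct == b.fct
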