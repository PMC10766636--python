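import numpy as np
import pandas as pd
import pytest

from mitopop import abc_inference as abc
from mitopop import scenario_simulator as sim


@pytest.fixture
def rng():
    return np.random.default_rng(7)


def toy_table(rng, n=3000, signal=True):
    """Reference table where (if signal) statistics separate the scenarios."""
    rows = []
    names = abc.summary_names()
    for i in range(n):
        s = i % 3 + 1
        base = float(s) if signal else 0.0
        vals = base + rng.normal(0, 1.0, size=len(names))
        row = {"scenario": s, "Ta": rng.uniform(800, 1200),
               "T1": np.nan, "T2": rng.uniform(700, 2000), "T3": np.nan,
               "N_Madagascar": 100.0, "N_EastAfrica": 100.0, "N_WestAsia": 100.0}
        row.update(dict(zip(names, vals)))
        rows.append(row)
    return pd.DataFrame(rows)


class TestSummarize:
    def make_codes(self, blocks):
        """blocks: list of (n_rows, row_pattern) stacked."""
        rows = []
        for n, pattern in blocks:
            rows += [np.array(pattern, dtype=np.uint8)] * n
        return np.vstack(rows)

    def test_identical_populations_fst_zero(self):
        codes = self.make_codes([(4, [0, 1, 2, 3] * 3), (4, [0, 1, 2, 3] * 3)])
        pops = ["Madagascar"] * 4 + ["EastAfrica"] * 2 + ["WestAsia"] * 2
        sv = abc.summarize_matrix(codes, pops)
        s = sv.as_series()
        assert s["Madagascar_EastAfrica_fst"] == 0.0
        assert s["Madagascar_EastAfrica_between_mean_diff"] == 0.0

    def test_fixed_populations_fst_one(self):
        a = [0] * 10 + [1] * 2
        b = [3] * 10 + [1] * 2
        assert sum(x != y for x, y in zip(a, b)) == 10
        codes = self.make_codes([(4, a), (4, b), (4, a)])
        pops = ["Madagascar"] * 4 + ["EastAfrica"] * 4 + ["WestAsia"] * 4
        sv = abc.summarize_matrix(codes, pops)
        s = sv.as_series()
        assert s["Madagascar_EastAfrica_fst"] == pytest.approx(1.0)
        assert s["Madagascar_EastAfrica_between_mean_diff"] == pytest.approx(10.0)

    def test_matrix_and_alignment_paths_agree(self, rng):
        ds = sim.simulate_dataset(
            sim.scenario(2), {"Madagascar": 8, "EastAfrica": 6, "WestAsia": 6},
            model=sim.MutationModel(mu_site=1e-5), L=400, seed=99,
        )
        codes = ds.alignment.codes()
        sv_fast = abc.summarize_matrix(codes, list(ds.meta["population"]))
        sv_slow = abc.summarize_alignment(ds.alignment, ds.meta)
        assert sv_fast.names == sv_slow.names
        assert np.allclose(sv_fast.values, sv_slow.values, atol=1e-9)

    def test_undefined_tajima_masked(self):
        codes = self.make_codes([(4, [0, 0, 0]), (4, [1, 1, 1]), (4, [2, 2, 2])])
        pops = ["Madagascar"] * 4 + ["EastAfrica"] * 4 + ["WestAsia"] * 4
        sv = abc.summarize_matrix(codes, pops)
        s = sv.as_series()
        assert s["Madagascar_tajima_D"] == 0.0
        idx = sv.names.index("Madagascar_tajima_D")
        assert not sv.valid[idx]

    def test_empty_population_rejected(self):
        codes = self.make_codes([(4, [0, 1])])
        with pytest.raises(ValueError, match="empty population"):
            abc.summarize_matrix(codes, ["Madagascar"] * 4)


class TestAbcReject:
    def test_exact_count_retained(self, rng):
        table = toy_table(rng, n=10_000)
        obs = table[abc.summary_names()].iloc[0].to_numpy()
        ret = abc.abc_reject(obs, table, tolerance=0.01)
        assert len(ret.indices) == 100

    def test_observed_row_always_retained(self, rng):
        table = toy_table(rng, n=2000)
        obs = table[abc.summary_names()].iloc[123].to_numpy()
        ret = abc.abc_reject(obs, table, tolerance=0.001)
        assert 123 in ret.indices
        assert ret.distances.min() == 0.0

    def test_retained_closer_than_rejected(self, rng):
        table = toy_table(rng, n=1000)
        obs = np.zeros(len(abc.summary_names()))
        ret = abc.abc_reject(obs, table, tolerance=0.05)
        X = table[abc.summary_names()].to_numpy()
        med = np.median(X, axis=0)
        mad = np.median(np.abs(X - med), axis=0)
        all_d = np.sqrt((((X - obs) / mad) ** 2).sum(axis=1))
        rejected = np.setdiff1d(np.arange(len(table)), ret.indices)
        assert ret.distances.max() <= all_d[rejected].min() + 1e-12

    def test_affine_rescaling_invariance(self, rng):
        table = toy_table(rng, n=1000)
        names = abc.summary_names()
        obs = table[names].iloc[5].to_numpy().copy()
        ret1 = abc.abc_reject(obs, table, tolerance=0.02)
        col = names[3]
        table2 = table.copy()
        table2[col] = table2[col] * 7.0 + 11.0
        obs2 = obs.copy()
        obs2[3] = obs2[3] * 7.0 + 11.0
        ret2 = abc.abc_reject(obs2, table2, tolerance=0.02)
        assert sorted(ret1.indices) == sorted(ret2.indices)
        assert np.allclose(np.sort(ret1.distances), np.sort(ret2.distances))

    def test_zero_mad_column_dropped(self, rng):
        table = toy_table(rng, n=500)
        names = abc.summary_names()
        table[names[0]] = 1.0  # degenerate
        obs = table[names].iloc[0].to_numpy()
        with pytest.warns(UserWarning, match="zero-MAD"):
            ret = abc.abc_reject(obs, table, tolerance=0.1)
        assert names[0] in ret.dropped_columns

    def test_bad_tolerance(self, rng):
        table = toy_table(rng, n=100)
        obs = np.zeros(len(abc.summary_names()))
        with pytest.raises(ValueError):
            abc.abc_reject(obs, table, tolerance=0.0)


class TestScenarioPosterior:
    def test_single_scenario_retained(self, rng):
        table = toy_table(rng, n=3000, signal=True)
        names = abc.summary_names()
        obs = np.full(len(names), 2.0)  # scenario-2 territory
        ret = abc.abc_reject(obs, table, tolerance=0.002)
        res = abc.scenario_posterior(ret, table, obs)
        assert sum(res.pp.values()) == pytest.approx(1.0)
        assert res.pp[2] == max(res.pp.values())

    def test_all_one_scenario_degenerate(self, rng):
        table = toy_table(rng, n=900, signal=True)
        table = table[table["scenario"] == 2].reset_index(drop=True)
        obs = np.full(len(abc.summary_names()), 2.0)
        ret = abc.abc_reject(obs, table, tolerance=0.1)
        res = abc.scenario_posterior(ret, table, obs)
        assert res.pp[2] == pytest.approx(1.0)
        assert res.flagged

    def test_shuffled_labels_near_uniform(self, rng):
        table = toy_table(rng, n=6000, signal=False)  # stats carry no signal
        obs = np.zeros(len(abc.summary_names()))
        ret = abc.abc_reject(obs, table, tolerance=0.1)
        res = abc.scenario_posterior(ret, table, obs)
        for s in (1, 2, 3):
            assert res.pp[s] == pytest.approx(1 / 3, abs=0.12)

    def test_pps_sum_to_one_and_duplication_invariant(self, rng):
        table = toy_table(rng, n=1500, signal=True)
        obs = np.full(len(abc.summary_names()), 1.5)
        ret = abc.abc_reject(obs, table, tolerance=0.05)
        res = abc.scenario_posterior(ret, table, obs)
        doubled = pd.concat([table, table], ignore_index=True)
        ret2 = abc.abc_reject(obs, doubled, tolerance=0.05)
        res2 = abc.scenario_posterior(ret2, doubled, obs)
        assert sum(res.pp.values()) == pytest.approx(1.0)
        assert sum(res2.pp.values()) == pytest.approx(1.0)
        for s in (1, 2, 3):
            assert res2.pp[s] == pytest.approx(res.pp[s], abs=0.05)

    def test_ci_contains_point(self, rng):
        table = toy_table(rng, n=3000, signal=True)
        obs = np.full(len(abc.summary_names()), 2.0)
        ret = abc.abc_reject(obs, table, tolerance=0.05)
        res = abc.scenario_posterior(ret, table, obs)
        for s, p in res.pp.items():
            lo, hi = res.ci[s]
            assert lo - 1e-9 <= p <= hi + 1e-9


class TestEstimateParams:
    def test_concentrates_at_exact_match(self, rng):
        table = toy_table(rng, n=2000)
        obs = table[abc.summary_names()].iloc[77].to_numpy()
        ret = abc.abc_reject(obs, table, tolerance=1 / 2000)
        assert len(ret.indices) == 1
        post = abc.estimate_params(ret, table, obs, scenario_id=int(table.iloc[77]["scenario"]),
                                   parameter="T2")
        assert post.point == pytest.approx(table.iloc[77]["T2"])
        assert post.flagged  # fewer than min_rows retained

    def test_weights_normalized(self, rng):
        table = toy_table(rng, n=2000, signal=False)
        obs = np.zeros(len(abc.summary_names()))
        ret = abc.abc_reject(obs, table, tolerance=0.1)
        post = abc.estimate_params(ret, table, obs, scenario_id=2, parameter="T2")
        assert post.weights.sum() == pytest.approx(1.0)
        assert np.all(post.weights >= 0)

    def test_hpd_within_prior_when_clipped(self, rng):
        table = toy_table(rng, n=2000, signal=False)
        obs = np.zeros(len(abc.summary_names()))
        ret = abc.abc_reject(obs, table, tolerance=0.1)
        post = abc.estimate_params(
            ret, table, obs, scenario_id=2, parameter="T2", prior_bounds=(700, 2000)
        )
        assert 700 <= post.hpd[0] <= post.hpd[1] <= 2000
        assert post.hpd[0] <= post.point <= post.hpd[1]


class TestReferenceTable:
    def test_build_small_table(self):
        table = abc.build_reference_table(
            n_per_scenario=5,
            sample_sizes={"Madagascar": 5, "EastAfrica": 4, "WestAsia": 4},
            L=200,
            seed=3,
        )
        assert len(table) == 15
        assert sorted(table["scenario"].unique()) == [1, 2, 3]
        # scenario-specific parameters populated only where defined
        assert table.loc[table["scenario"] == 1, "T1"].notna().all()
        assert table.loc[table["scenario"] == 1, "T2"].isna().all()
        assert table.loc[table["scenario"] == 2, "T2"].notna().all()

    def test_deterministic(self):
        kw = dict(
            n_per_scenario=3,
            sample_sizes={"Madagascar": 4, "EastAfrica": 3, "WestAsia": 3},
            L=150,
            seed=11,
        )
        t1 = abc.build_reference_table(**kw)
        t2 = abc.build_reference_table(**kw)
        pd.testing.assert_frame_equal(t1, t2)
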