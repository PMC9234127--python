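import math

import numpy as np
import pandas as pd
import pytest

from tepnorm import (
    ValidationError,
    aggregate_ranks,
    bestkeeper,
    delta_ct_stability,
    genorm,
    normfinder,
    prepare_log_quantities,
    rank_stability,
)

from conftest import make_panel, random_ct_dict
from oracles import (
    oracle_bestkeeper,
    oracle_delta_ct,
    oracle_genorm,
    oracle_normfinder,
)


class TestLogQuantities:
    def test_calibration_arithmetic(self, panel_factory):
        panel = panel_factory({"A": [20, 21, 23], "B": [20, 20, 20], "C": [19, 20, 21]})
        a = prepare_log_quantities(panel)
        assert a.loc["A"].tolist() == [3.0, 2.0, 0.0]

    def test_efficiency_scales_by_log2(self, panel_factory):
        ct = {"A": [20, 21, 23], "B": [20, 20, 20], "C": [19, 20, 21]}
        a2 = prepare_log_quantities(make_panel(ct, efficiency=2.0))
        a21 = prepare_log_quantities(make_panel(ct, efficiency=2.1))
        np.testing.assert_allclose(a21, a2 * math.log2(2.1), rtol=1e-12)
        assert math.log2(2.1) == pytest.approx(1.0704, abs=1e-4)

    def test_gene_shift_leaves_pairwise_sds_unchanged(self, abc_panel):
        base = delta_ct_stability(abc_panel)
        shifted = make_panel(
            {"A": [25, 26, 27, 28], "B": [20, 21, 22, 23], "C": [20, 22, 21, 25]}
        )
        out = delta_ct_stability(shifted)
        pd.testing.assert_series_equal(base.values, out.values)


class TestDeltaCt:
    def test_worked_example(self, abc_panel):
        res = delta_ct_stability(abc_panel)
        s = math.sqrt(5 / 3)  # SD of {0,-1,1,-2}, n-1 denominator
        assert res.values["A"] == pytest.approx(s / 2, abs=1e-10)
        assert res.values["B"] == pytest.approx(s / 2, abs=1e-10)
        assert res.values["C"] == pytest.approx(s, abs=1e-10)
        assert res.values["A"] == pytest.approx(0.6455, abs=1e-4)
        assert res.ranks["C"] == 3.0 and res.ranks["A"] == res.ranks["B"] == 1.5

    def test_identical_genes_all_tied(self, panel_factory):
        panel = panel_factory({g: [20, 22, 24, 21] for g in "ABCD"})
        res = delta_ct_stability(panel)
        assert (res.values == 0).all()
        assert (res.ranks == 2.5).all()

    def test_requires_three_genes(self, panel_factory):
        panel = panel_factory({"A": [20, 21, 22], "B": [20, 21, 22]})
        with pytest.raises(ValidationError, match="three genes"):
            delta_ct_stability(panel)

    def test_sparse_pair_errors_naming_pair(self, panel_factory):
        ct = {"A": [20, 21, 22, 23], "B": [20, 21, 22, np.nan],
              "C": [np.nan, 21, 25, 24]}
        panel = make_panel(ct)
        with pytest.raises(ValidationError, match=r"\(B, C\)"):
            delta_ct_stability(panel)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(101)
        ct = random_ct_dict(rng)
        res = delta_ct_stability(make_panel(ct))
        expect = oracle_delta_ct(ct)
        for g, v in expect.items():
            assert res.values[g] == pytest.approx(v, rel=1e-12)


class TestGeNorm:
    def test_worked_example_trace(self, abc_panel):
        tr = genorm(abc_panel)
        first = tr.steps[0]["m_values"]
        s = math.sqrt(5 / 3)
        assert first["A"] == pytest.approx(s / 2, abs=1e-10)
        assert first["B"] == pytest.approx(s / 2, abs=1e-10)
        assert first["C"] == pytest.approx(s, abs=1e-10)
        assert tr.steps[0]["removed"] == "C"
        assert set(tr.final_pair) == {"A", "B"}
        assert tr.ranks["A"] == tr.ranks["B"] == 1.5 and tr.ranks["C"] == 3.0

    def test_identical_pair_always_final(self, panel_factory):
        rng = np.random.default_rng(5)
        ct = random_ct_dict(rng, n_genes=4)
        ct["T1"] = [20.0, 22.0, 24.0, 21.0, 23.0, 25.0, 19.0, 26.0]
        ct["T2"] = list(ct["T1"])  # mutual pairwise SD is exactly 0
        tr = genorm(make_panel(ct))
        assert set(tr.final_pair) == {"T1", "T2"}

    def test_requires_three_genes(self, panel_factory):
        panel = panel_factory({"A": [20, 21, 22], "B": [20, 21, 22]})
        with pytest.raises(ValidationError, match="at least three genes"):
            genorm(panel)

    def test_v_series_length_and_nf(self):
        rng = np.random.default_rng(23)
        ct = random_ct_dict(rng, n_genes=6, n_samples=10)
        tr = genorm(make_panel(ct))
        assert len(tr.v_series) == 6 - 2
        assert set(tr.normalization_factors) == set(range(2, 7))

    def test_full_trace_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(5):
            ct = random_ct_dict(rng, n_genes=6, n_samples=10)
            tr = genorm(make_panel(ct))
            exp = oracle_genorm(ct)
            assert len(tr.steps) == len(exp["steps"])
            for got, want in zip(tr.steps, exp["steps"]):
                assert got["removed"] == want["removed"]
                for g, m in want["m_values"].items():
                    assert got["m_values"][g] == pytest.approx(m, rel=1e-12)
            assert set(tr.final_pair) == set(exp["final_pair"])
            for k, v in exp["v_series"].items():
                assert tr.v_series[k] == pytest.approx(v, rel=1e-12)

    def test_first_step_equals_delta_ct(self):
        rng = np.random.default_rng(13)
        ct = random_ct_dict(rng, n_genes=7, n_samples=9)
        panel = make_panel(ct)
        tr = genorm(panel)
        dct = delta_ct_stability(panel)
        for g in ct:
            assert tr.steps[0]["m_values"][g] == pytest.approx(dct.values[g], abs=1e-13)


class TestNormFinder:
    def test_constant_centered_gene_is_most_stable(self, panel_factory):
        # gene tracking the panel mean exactly: zero variance, zero bias
        groups = ["a"] * 4 + ["b"] * 4
        rng = np.random.default_rng(2)
        ct = random_ct_dict(rng, n_genes=4)
        mean = [sum(ct[g][s] for g in ct) / len(ct) for s in range(8)]
        ct["Z"] = mean  # centered values are exactly 0 everywhere
        res = normfinder(make_panel(ct, groups=groups))
        assert res.rho["Z"] == pytest.approx(0.0, abs=1e-12)
        assert res.ranks["Z"] == 1.0

    def test_planted_group_shift_is_least_stable(self):
        rng = np.random.default_rng(8)
        groups = ["a"] * 4 + ["b"] * 4
        ct = {f"G{i}": list(20 + rng.normal(0, 0.1, 8)) for i in range(5)}
        shifted = 22 + rng.normal(0, 0.1, 8)
        shifted[4:] += 2.0
        ct["SH"] = list(shifted)
        res = normfinder(make_panel(ct, groups=groups))
        assert res.rho.idxmax() == "SH"

    def test_group_of_one_rejected(self):
        rng = np.random.default_rng(4)
        ct = random_ct_dict(rng, n_genes=3, n_samples=5)
        with pytest.raises(ValidationError, match="fewer than two"):
            normfinder(make_panel(ct, groups=["a"] * 4 + ["b"]))

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(55)
        groups = ["a"] * 3 + ["b"] * 3
        ct = random_ct_dict(rng, n_genes=5, n_samples=6)
        res = normfinder(make_panel(ct, groups=groups))
        expect = oracle_normfinder(ct, groups)
        for g, v in expect.items():
            assert res.rho[g] == pytest.approx(v, rel=1e-12)

    def test_single_group_falls_back_to_centered_sd(self):
        rng = np.random.default_rng(9)
        ct = random_ct_dict(rng, n_genes=4, n_samples=6)
        res = normfinder(make_panel(ct, groups=["g1"] * 6))
        # brute force: calibrated then sample-centered values, n-1 SD
        import statistics

        genes = list(ct)
        cal = {g: [min(ct[g]) - v for v in ct[g]] for g in genes}
        for s in range(6):
            mu = sum(cal[g][s] for g in genes) / len(genes)
            for g in genes:
                cal[g][s] -= mu
        for g in genes:
            assert res.rho[g] == pytest.approx(statistics.stdev(cal[g]), rel=1e-12)


class TestBestKeeper:
    def test_worked_example(self, panel_factory):
        panel = panel_factory(
            {"A": [20, 21, 22, 23], "B": [20, 21, 22, 23], "C": [20, 22, 21, 25]}
        )
        res = bestkeeper(panel)
        row = res.table.loc["A"]
        assert row["arith_mean"] == pytest.approx(21.5)
        assert row["sd"] == pytest.approx(1.0)  # mean absolute deviation
        assert row["cv_pct"] == pytest.approx(100 / 21.5, abs=1e-3)
        assert row["cv_pct"] == pytest.approx(4.651, abs=1e-3)
        assert row["geo_mean"] == pytest.approx((20 * 21 * 22 * 23) ** 0.25, rel=1e-12)
        assert row["geo_mean"] == pytest.approx(21.47, abs=0.01)

    def test_constant_gene_missing_r_ranked_by_sd(self, panel_factory):
        panel = panel_factory(
            {"K": [25, 25, 25, 25], "B": [20, 21, 22, 23], "C": [20, 22, 21, 25]}
        )
        res = bestkeeper(panel)
        assert res.table.loc["K", "sd"] == 0.0
        assert res.table.loc["K", "cv_pct"] == 0.0
        assert not res.table.loc["K", "inconsistent"]
        assert np.isnan(res.table.loc["K", "r"])
        assert res.ranks["K"] == 1.0

    def test_two_gene_index_is_rowwise_geometric_mean(self, panel_factory):
        ct1 = [20.0, 21.0, 22.0, 23.0]
        panel = panel_factory({"G1": ct1, "G2": [v + 1 for v in ct1]})
        res = bestkeeper(panel)
        expect = [math.sqrt(v * (v + 1)) for v in ct1]
        np.testing.assert_allclose(res.index.to_numpy(), expect, rtol=1e-12)
        # the index is a monotone transform of either gene -> r is ~1
        assert res.table.loc["G1", "r"] == pytest.approx(1.0, abs=1e-3)

    def test_sd_flag_cutoff(self, panel_factory):
        panel = panel_factory({"A": [20, 26, 20, 26], "B": [20, 20.4, 20, 20.4]})
        res = bestkeeper(panel, sd_flag_cutoff=1.0)
        assert bool(res.table.loc["A", "inconsistent"])
        assert not res.table.loc["B", "inconsistent"]

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(31)
        ct = random_ct_dict(rng)
        res = bestkeeper(make_panel(ct))
        expect = oracle_bestkeeper(ct)
        np.testing.assert_allclose(res.index.to_numpy(), expect["index"], rtol=1e-12)
        for g, row in expect["table"].items():
            for key in ("arith_mean", "geo_mean", "sd", "cv_pct", "min", "max", "r"):
                assert res.table.loc[g, key] == pytest.approx(row[key], rel=1e-10)

    def test_classic_sd_flag(self, panel_factory):
        panel = panel_factory(
            {"A": [20, 21, 22, 23], "B": [20, 21, 22, 24], "C": [21, 22, 23, 24]}
        )
        res = bestkeeper(panel, classic_sd=True)
        assert res.table.loc["A", "sd"] == pytest.approx(np.std([20, 21, 22, 23], ddof=1))


class TestAggregateRanks:
    def test_published_three_gene_ranking(self):
        ranks = {
            "delta_ct": pd.Series({"GAPDH": 1.0, "B2M": 2.0, "ACTB": 3.0}),
            "bestkeeper": pd.Series({"GAPDH": 1.0, "ACTB": 2.0, "B2M": 3.0}),
            "normfinder": pd.Series({"GAPDH": 1.0, "B2M": 2.0, "ACTB": 3.0}),
            "genorm": pd.Series({"B2M": 1.5, "GAPDH": 1.5, "ACTB": 3.0}),
        }
        agg = aggregate_ranks(ranks)
        order = agg.sort_values("comprehensive_rank").index.tolist()
        assert order == ["GAPDH", "B2M", "ACTB"]
        assert agg.loc["GAPDH", "aggregate_score"] == pytest.approx(1.5 ** 0.25, rel=1e-12)
        assert agg.loc["GAPDH", "aggregate_score"] == pytest.approx(1.107, abs=1e-3)
        assert agg.loc["B2M", "aggregate_score"] == pytest.approx(2.060, abs=1e-3)
        assert agg.loc["ACTB", "aggregate_score"] == pytest.approx(2.711, abs=1e-3)

    def test_unanimous_methods_reproduce_common_ranking(self):
        common = pd.Series({"A": 2.0, "B": 1.0, "C": 3.0})
        agg = aggregate_ranks({"m1": common, "m2": common, "m3": common})
        pd.testing.assert_series_equal(
            agg["comprehensive_rank"], common, check_names=False
        )

    def test_score_ties_break_alphabetically(self):
        r1 = pd.Series({"B": 1.0, "A": 2.0, "C": 3.0})
        r2 = pd.Series({"B": 2.0, "A": 1.0, "C": 3.0})
        agg = aggregate_ranks({"m1": r1, "m2": r2})
        assert agg.loc["A", "comprehensive_rank"] == 1.0
        assert agg.loc["B", "comprehensive_rank"] == 2.0

    def test_partial_gene_coverage_rejected(self):
        r1 = pd.Series({"A": 1.0, "B": 2.0})
        r2 = pd.Series({"A": 1.0})
        with pytest.raises(ValidationError, match="different gene set"):
            aggregate_ranks({"m1": r1, "m2": r2})

    def test_single_method_rejected(self):
        with pytest.raises(ValidationError, match="two methods"):
            aggregate_ranks({"m1": pd.Series({"A": 1.0})})


class TestInvariances:
    def _random_panel(self, seed=99):
        rng = np.random.default_rng(seed)
        ct = random_ct_dict(rng, n_genes=5, n_samples=8)
        return ct, ["a"] * 4 + ["b"] * 4

    def test_sample_loading_shift_cancels_except_bestkeeper(self):
        ct, groups = self._random_panel()
        rng = np.random.default_rng(1)
        offsets = rng.uniform(-2, 2, 8)
        shifted = {g: [v + o for v, o in zip(vals, offsets)] for g, vals in ct.items()}
        p0, p1 = make_panel(ct, groups), make_panel(shifted, groups)

        pd.testing.assert_series_equal(
            delta_ct_stability(p0).values, delta_ct_stability(p1).values,
            rtol=1e-10, atol=1e-10,
        )
        for s0, s1 in zip(genorm(p0).steps, genorm(p1).steps):
            for g in s0["m_values"]:
                assert s0["m_values"][g] == pytest.approx(s1["m_values"][g], abs=1e-10)
        pd.testing.assert_series_equal(
            normfinder(p0).rho, normfinder(p1).rho, rtol=1e-10, atol=1e-10
        )
        # BestKeeper works on the raw Ct scale: its dispersion must change
        assert not np.allclose(
            bestkeeper(p0).table["sd"], bestkeeper(p1).table["sd"], atol=1e-6
        )

    def test_per_gene_calibration_shift_cancels(self):
        ct, groups = self._random_panel(5)
        shifted = dict(ct)
        shifted["G2"] = [v + 3.7 for v in ct["G2"]]
        p0, p1 = make_panel(ct, groups), make_panel(shifted, groups)
        pd.testing.assert_series_equal(
            delta_ct_stability(p0).values, delta_ct_stability(p1).values,
            rtol=1e-10, atol=1e-10,
        )
        pd.testing.assert_series_equal(
            normfinder(p0).rho, normfinder(p1).rho, rtol=1e-10, atol=1e-10
        )
        t0, t1 = genorm(p0), genorm(p1)
        pd.testing.assert_series_equal(
            t0.m_at_elimination, t1.m_at_elimination, rtol=1e-10, atol=1e-10
        )


def test_rank_stability_end_to_end_table():
    rng = np.random.default_rng(12)
    ct = random_ct_dict(rng, n_genes=5, n_samples=8)
    table = rank_stability(make_panel(ct, groups=["a"] * 4 + ["b"] * 4))
    df = table.table
    assert sorted(df["comprehensive_rank"]) == [1, 2, 3, 4, 5]
    for col in ("delta_ct_value", "normfinder_rho", "bestkeeper_sd", "genorm_M"):
        assert (df[col] >= 0).all()
    assert df["bestkeeper_r"].abs().max() <= 1.0
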