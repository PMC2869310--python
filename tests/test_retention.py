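import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from costex.retention import (
    assign_ohnologon_expression,
    bin_retention,
    category_enrichment,
    extreme_decile_comparison,
    lowess_curve,
    normalize_between_arrays,
    probe_median,
    stratified_retention,
    summarize_expression,
    two_by_two_pvalue,
)


def _records(levels, retained, ids=None):
    n = len(levels)
    return pd.DataFrame(
        {
            "ohnologon_id": ids if ids is not None else [f"o{i:05d}" for i in range(n)],
            "level": levels,
            "retained": retained,
        }
    )


class TestProbeMedian:
    def test_six_probe_median(self):
        mat = pd.DataFrame({"gene_id": ["g1"] * 6, "c1": [1, 2, 3, 4, 5, 6]})
        out = probe_median(mat)
        assert out.loc[0, "c1"] == pytest.approx(3.5)

    def test_single_probe_identity(self):
        mat = pd.DataFrame({"gene_id": ["g1"], "c1": [7.0], "c2": [9.0]})
        out = probe_median(mat)
        assert out.loc[0, "c1"] == 7.0 and out.loc[0, "c2"] == 9.0

    def test_matches_brute_force(self, rng):
        block = rng.lognormal(2, 1, size=(6, 58))
        mat = pd.DataFrame(block, columns=[f"c{j}" for j in range(58)])
        mat.insert(0, "gene_id", "gX")
        out = probe_median(mat)
        for j in range(58):  # independent per-column median
            vals = sorted(block[:, j])
            assert out.loc[0, f"c{j}"] == pytest.approx((vals[2] + vals[3]) / 2, rel=1e-12)

    def test_unassigned_probe_errors(self):
        mat = pd.DataFrame({"gene_id": ["g1", None], "c1": [1.0, 2.0]})
        with pytest.raises(ValueError, match="no gene assigned"):
            probe_median(mat)


class TestNormalizeBetweenArrays:
    def test_identical_columns_unchanged(self):
        mat = pd.DataFrame({"gene_id": list("abc"), "c1": [1.0, 2.0, 3.0], "c2": [1.0, 2.0, 3.0]})
        out = normalize_between_arrays(mat, "quantile")
        np.testing.assert_allclose(out[["c1", "c2"]], mat[["c1", "c2"]])

    def test_hand_example(self):
        mat = pd.DataFrame({"c1": [1.0, 2.0, 3.0], "c2": [4.0, 5.0, 6.0]})
        out = normalize_between_arrays(mat, "quantile")
        np.testing.assert_allclose(out["c1"], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out["c2"], [2.5, 3.5, 4.5])

    def test_column_means_equalized(self, rng):
        mat = pd.DataFrame(rng.lognormal(0, 1, size=(100, 5)), columns=list("abcde"))
        out = normalize_between_arrays(mat, "quantile")
        means = out.mean(axis=0).to_numpy()
        np.testing.assert_allclose(means, means[0], rtol=1e-12)

    def test_ties_get_mean_of_quantile_values(self):
        mat = pd.DataFrame({"c1": [1.0, 1.0, 2.0], "c2": [3.0, 4.0, 5.0]})
        out = normalize_between_arrays(mat, "quantile")
        # ref = (2, 2.5, 3.5); tied 1.0s share mean(2, 2.5) = 2.25
        np.testing.assert_allclose(sorted(out["c1"]), [2.25, 2.25, 3.5])

    def test_scale_method(self, rng):
        mat = pd.DataFrame(rng.lognormal(0, 1, size=(50, 3)), columns=list("abc"))
        out = normalize_between_arrays(mat, "scale")
        medians = out.median(axis=0).to_numpy()
        np.testing.assert_allclose(medians, medians[0], rtol=1e-12)

    def test_none_is_identity(self):
        mat = pd.DataFrame({"c1": [1.0, 2.0], "c2": [5.0, 6.0]})
        out = normalize_between_arrays(mat, "none")
        pd.testing.assert_frame_equal(out, mat)

    def test_non_numeric_rejected(self):
        mat = pd.DataFrame({"c1": ["x", "y"], "c2": ["1", "2"]})
        with pytest.raises(TypeError):
            normalize_between_arrays(mat, "quantile")

    def test_needs_two_columns(self):
        with pytest.raises(ValueError):
            normalize_between_arrays(pd.DataFrame({"c1": [1.0]}), "quantile")


class TestSummarizeExpression:
    def test_constant_signal(self):
        mat = pd.DataFrame({"gene_id": ["g"], "c1": [8.0], "c2": [8.0], "c3": [8.0]})
        assert summarize_expression(mat).loc["g"] == pytest.approx(3.0)

    def test_median_then_log(self):
        mat = pd.DataFrame({"gene_id": ["g"], "c1": [2.0], "c2": [4.0], "c3": [8.0]})
        assert summarize_expression(mat).loc["g"] == pytest.approx(2.0)

    def test_condition_order_irrelevant(self, rng):
        vals = rng.lognormal(1, 1, size=(10, 7))
        mat = pd.DataFrame(vals, columns=[f"c{j}" for j in range(7)])
        mat.insert(0, "gene_id", [f"g{i}" for i in range(10)])
        shuffled = mat[["gene_id"] + [f"c{j}" for j in (3, 1, 6, 0, 2, 5, 4)]]
        pd.testing.assert_series_equal(summarize_expression(mat), summarize_expression(shuffled))

    def test_nonpositive_rejected_without_floor(self):
        mat = pd.DataFrame({"gene_id": ["g"], "c1": [0.0], "c2": [4.0]})
        with pytest.raises(ValueError, match="floor"):
            summarize_expression(mat)

    def test_floor_applies(self):
        mat = pd.DataFrame({"gene_id": ["g"], "c1": [0.0], "c2": [4.0]})
        assert summarize_expression(mat, floor=4.0).loc["g"] == pytest.approx(2.0)
        # auto floor = smallest positive signal = 4.0
        assert summarize_expression(mat, floor="auto").loc["g"] == pytest.approx(2.0)


class TestAssignExpression:
    def _levels(self):
        return pd.Series({"g1": 1.0, "g2": 2.0, "g3": 3.0})

    def test_singleton(self):
        rec = pd.DataFrame({"ohnologon_id": ["o1"], "members": ["g2"]})
        out = assign_ohnologon_expression(rec, self._levels(), seed=0)
        assert out.loc[0, "level"] == 2.0

    def test_equal_levels_seed_independent(self):
        levels = pd.Series({"g1": 5.0, "g2": 5.0})
        rec = pd.DataFrame({"ohnologon_id": ["o1"], "members": ["g1,g2"]})
        for seed in range(20):
            assert assign_ohnologon_expression(rec, levels, seed=seed).loc[0, "level"] == 5.0

    def test_missing_members_dropped(self):
        rec = pd.DataFrame({"ohnologon_id": ["o1", "o2"], "members": ["g1,g2", "gX,gY"]})
        out = assign_ohnologon_expression(rec, self._levels(), seed=0)
        assert list(out["ohnologon_id"]) == ["o1"]

    def test_partial_membership_uses_eligible(self):
        rec = pd.DataFrame({"ohnologon_id": ["o1"], "members": ["gX,g3"]})
        out = assign_ohnologon_expression(rec, self._levels(), seed=0)
        assert out.loc[0, "level"] == 3.0

    def test_members_picked_uniformly_over_seeds(self):
        rec = pd.DataFrame({"ohnologon_id": ["o1"], "members": ["g1,g2"]})
        levels = pd.Series({"g1": 1.0, "g2": 2.0})
        picks = [
            assign_ohnologon_expression(rec, levels, seed=seed)["level"].iloc[0]
            for seed in range(10_000)
        ]
        frac_first = np.mean(np.asarray(picks) == 1.0)
        assert frac_first == pytest.approx(0.5, abs=0.015)

    def test_reproducible(self):
        rec = pd.DataFrame(
            {"ohnologon_id": [f"o{i}" for i in range(50)], "members": ["g1,g2"] * 50}
        )
        a = assign_ohnologon_expression(rec, self._levels(), seed=3)
        b = assign_ohnologon_expression(rec, self._levels(), seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestBinRetention:
    def test_single_full_bin(self):
        rec = _records(np.full(40, 0.5), np.ones(40, dtype=bool))
        out = bin_retention(rec, 1.0)
        assert len(out) == 1
        assert out.loc[0, "retention"] == 1.0
        assert bool(out.loc[0, "included"])

    def test_small_bin_excluded(self):
        rec = _records(np.full(29, 0.5), np.ones(29, dtype=bool))
        out = bin_retention(rec, 1.0)
        assert not bool(out.loc[0, "included"])

    def test_three_bin_toy(self):
        levels = np.concatenate([np.full(50, 0.5), np.full(60, 1.5), np.full(40, 2.5)])
        retained = np.concatenate(
            [np.arange(50) < 10, np.arange(60) < 30, np.arange(40) < 30]
        )
        out = bin_retention(_records(levels, retained), 1.0)
        np.testing.assert_allclose(out["retention"], [0.2, 0.5, 0.75])
        np.testing.assert_array_equal(out["n"], [50, 60, 40])

    def test_anchoring_and_half_open(self):
        rec = _records([-0.3, 0.0, 0.19, 0.2], [True] * 4)
        out = bin_retention(rec, 0.2, min_count=1)
        np.testing.assert_allclose(out["lo"], [-0.4, 0.0, 0.2])
        np.testing.assert_array_equal(out["n"], [1, 2, 1])

    def test_empty_input(self):
        out = bin_retention(_records([], []), 1.0)
        assert len(out) == 0

    def test_count_conservation(self, rng):
        rec = _records(rng.normal(8, 2, 1000), rng.random(1000) < 0.5)
        out = bin_retention(rec, 0.2)
        assert out["n"].sum() == 1000

    def test_invalid_interval(self):
        with pytest.raises(ValueError):
            bin_retention(_records([1.0], [True]), 0.0)


@settings(max_examples=50, deadline=None)
@given(
    levels=st.lists(st.floats(min_value=-50, max_value=50, allow_nan=False), min_size=1, max_size=200),
    interval=st.sampled_from([0.2, 0.5, 1.0]),
)
def test_binning_is_a_partition(levels, interval):
    rec = _records(np.asarray(levels), np.ones(len(levels), dtype=bool))
    out = bin_retention(rec, interval, min_count=1)
    assert out["n"].sum() == len(levels)
    for lev in levels:
        # each level falls inside exactly one bin (floor anchoring)
        idx = np.floor(lev / interval)
        matches = np.isclose(out["lo"], idx * interval)
        assert matches.sum() == 1


class TestExtremeDeciles:
    def test_all_retained(self):
        out = extreme_decile_comparison(_records(np.arange(100.0), np.ones(100, dtype=bool)))
        assert (out.freq_bottom, out.freq_top, out.fold, out.p) == (1.0, 1.0, 1.0, 1.0)

    def test_constructed_fold_four(self):
        retained = np.zeros(100, dtype=bool)
        retained[:10] = np.arange(10) < 2   # bottom decile: 2/10
        retained[90:] = np.arange(10) < 8   # top decile: 8/10
        out = extreme_decile_comparison(_records(np.arange(100.0), retained))
        assert out.freq_bottom == pytest.approx(0.2)
        assert out.freq_top == pytest.approx(0.8)
        assert out.fold == pytest.approx(4.0)

    def test_p_matches_brute_force_chi2(self):
        retained = np.zeros(200, dtype=bool)
        retained[:20] = np.arange(20) < 6    # 6/20
        retained[180:] = np.arange(20) < 15  # 15/20
        out = extreme_decile_comparison(_records(np.arange(200.0), retained))
        observed = np.array([[6, 14], [15, 5]], dtype=float)
        total = observed.sum()
        expected = np.outer(observed.sum(1), observed.sum(0)) / total
        stat = ((observed - expected) ** 2 / expected).sum()
        p_brute = scipy.stats.chi2.sf(stat, df=1)
        assert out.p == pytest.approx(p_brute, rel=1e-12)

    def test_zero_bottom_retention_flagged_infinite(self):
        retained = np.zeros(100, dtype=bool)
        retained[50:] = True
        out = extreme_decile_comparison(_records(np.arange(100.0), retained))
        assert out.fold_is_infinite and np.isinf(out.fold)

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            extreme_decile_comparison(_records(np.arange(10.0), np.ones(10, dtype=bool)))

    def test_ties_broken_by_id_stable(self):
        rec = _records(np.zeros(100), np.arange(100) < 50)
        a = extreme_decile_comparison(rec)
        b = extreme_decile_comparison(rec.sample(frac=1, random_state=0).reset_index(drop=True))
        assert a == b


class TestTwoByTwo:
    def test_chi2_oracle(self):
        table = np.array([[30, 20], [20, 30]], dtype=float)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        stat = ((table - expected) ** 2 / expected).sum()
        assert two_by_two_pvalue(table) == pytest.approx(scipy.stats.chi2.sf(stat, 1), rel=1e-12)

    def test_fisher_for_small_expected(self):
        table = np.array([[1, 9], [8, 2]])
        assert two_by_two_pvalue(table) == pytest.approx(
            scipy.stats.fisher_exact(table)[1], rel=1e-12
        )

    def test_degenerate_margin(self):
        assert two_by_two_pvalue(np.array([[10, 0], [10, 0]])) == 1.0


class TestStratifiedRetention:
    def test_eight_record_quartiles(self):
        rec = _records(np.arange(8.0), np.array([0, 0, 1, 0, 1, 1, 1, 1], dtype=bool))
        strata = pd.DataFrame({"ohnologon_id": rec["ohnologon_id"], "stratum": "all"})
        out = stratified_retention(rec, strata)
        np.testing.assert_allclose(out["retention"], [0.0, 0.5, 1.0, 1.0])
        np.testing.assert_array_equal(out["n"], [2, 2, 2, 2])

    def test_partition_conserves_weighted_mean(self, rng):
        rec = _records(rng.normal(0, 1, 200), rng.random(200) < 0.6)
        strata = pd.DataFrame(
            {
                "ohnologon_id": rec["ohnologon_id"],
                "stratum": np.where(np.arange(200) % 2 == 0, "even", "odd"),
            }
        )
        out = stratified_retention(rec, strata)
        weighted = (out["retention"] * out["n"]).sum() / out["n"].sum()
        assert weighted == pytest.approx(rec["retained"].mean(), rel=1e-12)

    def test_small_stratum_skipped(self):
        rec = _records(np.arange(3.0), np.ones(3, dtype=bool))
        strata = pd.DataFrame({"ohnologon_id": rec["ohnologon_id"], "stratum": "tiny"})
        assert len(stratified_retention(rec, strata)) == 0

    def test_quartile_sizes_balanced(self, rng):
        rec = _records(rng.normal(0, 1, 103), rng.random(103) < 0.5)
        strata = pd.DataFrame({"ohnologon_id": rec["ohnologon_id"], "stratum": "s"})
        out = stratified_retention(rec, strata)
        assert out["n"].max() - out["n"].min() <= 1


class TestCategoryEnrichment:
    def _base_records(self, n=1200, seed=0):
        rng = np.random.default_rng(seed)
        return _records(rng.normal(8, 2, n), rng.random(n) < 0.5)

    def test_redundant_category_removed(self):
        rec = self._base_records()
        ids = rec["ohnologon_id"].to_numpy()
        big = ids[:500]
        small = np.concatenate([ids[:428], ids[500:522]])  # overlap 428/450 > 0.9
        membership = pd.DataFrame(
            {
                "category": ["big"] * len(big) + ["small"] * len(small),
                "ohnologon_id": np.concatenate([big, small]),
            }
        )
        out = category_enrichment(rec, membership, min_genes=400)
        assert list(out["category"]) == ["big"]

    def test_size_filter(self):
        rec = self._base_records()
        ids = rec["ohnologon_id"].to_numpy()
        membership = pd.DataFrame({"category": "tiny", "ohnologon_id": ids[:399]})
        assert len(category_enrichment(rec, membership, min_genes=400)) == 0
        membership2 = pd.DataFrame({"category": "ok", "ohnologon_id": ids[:401]})
        assert list(category_enrichment(rec, membership2, min_genes=400)["category"]) == ["ok"]

    def test_chi2_matches_brute_force(self):
        levels = np.arange(100.0)
        retained = np.zeros(100, dtype=bool)
        retained[:50] = np.arange(50) < 30   # category: 30/50
        retained[50:] = np.arange(50) < 20   # rest: 20/50
        rec = _records(levels, retained)
        membership = pd.DataFrame(
            {"category": "c", "ohnologon_id": rec["ohnologon_id"][:50]}
        )
        out = category_enrichment(rec, membership, min_genes=10)
        table = np.array([[30, 20], [20, 30]], dtype=float)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        stat = ((table - expected) ** 2 / expected).sum()
        assert out.loc[0, "p_retention"] == pytest.approx(scipy.stats.chi2.sf(stat, 1), rel=1e-12)
        assert out.loc[0, "retention"] == pytest.approx(0.6)
        assert out.loc[0, "retention_others"] == pytest.approx(0.4)

    def test_t_test_columns(self):
        rec = self._base_records()
        ids = rec["ohnologon_id"].to_numpy()
        membership = pd.DataFrame({"category": "c", "ohnologon_id": ids[:600]})
        out = category_enrichment(rec, membership, min_genes=100)
        member_levels = rec["level"][:600]
        other_levels = rec["level"][600:]
        t = scipy.stats.ttest_ind(member_levels, other_levels)
        assert out.loc[0, "p_level"] == pytest.approx(t.pvalue, rel=1e-12)
        assert out.loc[0, "mean_level"] == pytest.approx(member_levels.mean(), rel=1e-12)


class TestLowess:
    def test_constant_input(self):
        x = np.linspace(0, 10, 20)
        xs, ys = lowess_curve(x, np.full(20, 3.0))
        np.testing.assert_allclose(ys, 3.0, atol=1e-9)

    def test_exactly_linear(self):
        x = np.linspace(0, 10, 30)
        xs, ys = lowess_curve(x, 2.0 * x + 1.0)
        np.testing.assert_allclose(ys, 2.0 * xs + 1.0, atol=1e-6)

    def test_smooths_noisy_sigmoid(self, rng):
        x = np.linspace(-6, 6, 300)
        truth = 1.0 / (1.0 + np.exp(-x))
        noise_sd = 0.15
        y = truth + noise_sd * rng.standard_normal(300)
        xs, ys = lowess_curve(x, y, frac=0.3)
        resid_sd = np.std(ys - 1.0 / (1.0 + np.exp(-xs)))
        assert resid_sd < noise_sd

    def test_few_points_pass_through(self):
        with pytest.warns(UserWarning, match="lowess skipped"):
            xs, ys = lowess_curve([3.0, 1.0, 2.0], [30.0, 10.0, 20.0])
        np.testing.assert_allclose(xs, [1.0, 2.0, 3.0])
        np.testing.assert_allclose(ys, [10.0, 20.0, 30.0])
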