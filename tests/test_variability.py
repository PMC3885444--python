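import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import betainc

from glatcomp.core import Treatment
from glatcomp import variability as V
from glatcomp.synthetic import SimulationConfig, simulate_study

from conftest import four_group_study, make_matrix, make_meta


class TestVarianceFTest:
    def test_hand_computed_f(self):
        r = V.variance_f_test([1, 2, 3, 4], [10, 10.1, 9.9, 10.2], "greater")
        assert r.f == pytest.approx(100.0)
        assert (r.dfn, r.dfd) == (3, 3)

    def test_identical_vectors_symmetric_null_point(self):
        r = V.variance_f_test([1.0, 2.0, 5.0], [1.0, 2.0, 5.0], "greater")
        assert r.f == pytest.approx(1.0)
        assert r.p == pytest.approx(0.5)

    def test_reflection_identity(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=6), rng.normal(size=9)
        p_xy = V.variance_f_test(x, y, "greater").p
        p_yx = V.variance_f_test(y, x, "greater").p
        assert p_xy + p_yx == pytest.approx(1.0, abs=1e-12)

    def test_p_matches_independent_beta_tail(self):
        # F survival function re-derived via the regularised incomplete beta
        rng = np.random.default_rng(1)
        for _ in range(100):
            dfn = int(rng.integers(2, 40))
            dfd = int(rng.integers(2, 40))
            f = float(rng.uniform(0.05, 8.0))
            oracle = betainc(dfd / 2, dfn / 2, dfd / (dfd + dfn * f))
            p = float(stats.f.sf(f, dfn, dfd))
            assert p == pytest.approx(oracle, abs=1e-10)

    def test_degenerate_denominator(self):
        r = V.variance_f_test([1.0, 2.0, 3.0], [5.0, 5.0, 5.0], "greater")
        assert r.degenerate and r.p == 0.0 and np.isinf(r.f)
        r2 = V.variance_f_test([5.0, 5.0], [7.0, 7.0], "greater")
        assert r2.degenerate and r2.p == 1.0


class TestActivationFilter:
    def test_missing_medium_errors(self):
        m = make_matrix(np.zeros((2, 4)))
        meta = make_meta(
            {"s0": Treatment.GA, "s1": Treatment.GA,
             "s2": Treatment.GENERIC, "s3": Treatment.GENERIC}
        )
        with pytest.raises(ValueError, match="MEDIUM"):
            V.activation_variable_probes(m, meta)

    def test_null_calibration_within_binomial_bounds(self):
        m, meta = four_group_study(n_probes=4000, seed=7)
        act = V.activation_variable_probes(m, meta, alpha=0.05)
        # union of two dependent one-sided 5% screens: rate in (0.05, 0.0975]
        n = 4000
        lo = stats.binom.ppf(0.005, n, 0.05) / n
        hi = stats.binom.ppf(0.995, n, 0.0975) / n
        assert lo <= len(act) / n <= hi

    def test_planted_inflation_recovered(self):
        rng = np.random.default_rng(2)
        n, n_pl = 3000, 150
        m, meta = four_group_study(n_probes=n, seed=2)
        X = m.values.copy()
        gen_cols = [m.sample_ids.index(s) for s in meta.samples_with(Treatment.GENERIC)]
        mu = X[:n_pl][:, gen_cols].mean(axis=1, keepdims=True)
        X[:n_pl, :][:, gen_cols] = mu + (X[:n_pl][:, gen_cols] - mu) * 2.0
        m2 = make_matrix(X, sample_ids=m.sample_ids)
        act = set(V.activation_variable_probes(m2, meta))
        planted = set(m.probe_ids[:n_pl])
        # power of the generic-vs-medium F screen at var ratio 4, df (10, 7)
        power = float(stats.f.sf(stats.f.isf(0.05, 10, 7) / 4.0, 10, 7))
        recovered = len(act & planted)
        assert stats.binom.ppf(0.005, n_pl, power) <= recovered


class TestCompareGroupVariability:
    def test_empty_probe_set_errors(self, small_study):
        m, meta, _, _ = small_study
        with pytest.raises(ValueError):
            V.compare_group_variability(m, meta, [])

    def test_exchangeable_groups_fold_near_one(self):
        folds = []
        for seed in range(4):
            m, meta = four_group_study(n_probes=3000, seed=100 + seed)
            c = V.compare_group_variability(m, meta, m.probe_ids)
            folds.append(c.fold)
        assert 0.6 < float(np.mean(folds)) < 1.6

    def test_planted_asymmetry_gives_large_fold(self):
        cfg = SimulationConfig(n_probes=2000, n_inflated=300, batch_sd=0.0, seed=5)
        m, meta, _, truth = simulate_study(cfg)
        c = V.compare_group_variability(m, meta, truth.variance_inflated)
        assert c.n_generic_more_variable > 10 * max(1, c.n_ga_more_variable)
        assert c.fold > 3


class TestToleranceMethod:
    def test_floor_excludes_dim_upregulated_probe(self):
        # probe0: huge fold change but RS mean 5.9 < 6.0 -> excluded
        m = make_matrix(
            [[5.9, 5.9, 1.0, 1.0], [7.0, 7.0, 6.5, 6.5], [8.0, 8.0, 7.9, 7.9]]
        )
        meta = make_meta(
            {"s0": Treatment.REFERENCE_STANDARD, "s1": Treatment.REFERENCE_STANDARD,
             "s2": Treatment.MEDIUM, "s3": Treatment.MEDIUM}
        )
        with pytest.warns(UserWarning, match="2 probes"):
            probes = V.select_tolerance_probes(m, meta, n_top=3)
        assert "p0" not in probes and len(probes) == 2

    def test_top_k_by_absolute_fold_change(self):
        m = make_matrix(
            [[10.0, 10.0, 7.0, 7.0], [10.0, 10.0, 8.0, 8.0], [10.0, 10.0, 9.0, 9.0]]
        )
        meta = make_meta(
            {"s0": Treatment.REFERENCE_STANDARD, "s1": Treatment.REFERENCE_STANDARD,
             "s2": Treatment.MEDIUM, "s3": Treatment.MEDIUM}
        )
        assert V.select_tolerance_probes(m, meta, n_top=2) == ["p0", "p1"]

    def test_selection_invariant_to_probe_order(self, small_study):
        m, meta, _, _ = small_study
        rng = np.random.default_rng(0)
        sel = V.select_tolerance_probes(m, meta, n_top=100)
        perm = list(rng.permutation(m.probe_ids))
        sel_perm = V.select_tolerance_probes(m.subset_probes(perm), meta, n_top=100)
        assert sorted(sel) == sorted(sel_perm)

    def test_ranges_min_max_and_degenerate(self):
        m = make_matrix([[5.0, 6.0], [4.0, 4.0]])
        meta = make_meta({s: Treatment.REFERENCE_STANDARD for s in m.sample_ids})
        tol = V.tolerance_ranges(m, meta, ["p0", "p1"])
        assert tol.ranges.loc["p0"].tolist() == [5.0, 6.0]
        assert tol.ranges.loc["p1"].tolist() == [4.0, 4.0]  # zero width, valid

    def test_reference_samples_always_within_own_ranges(self, small_study):
        m, meta, _, _ = small_study
        probes = m.probe_ids[:50]
        tol = V.tolerance_ranges(m, meta, probes)
        r = V.tolerance_percentages(m, meta, tol, Treatment.REFERENCE_STANDARD)
        assert (r.pct_within == 100.0).all()

    def test_half_within_inclusive_bounds(self):
        m = make_matrix([[5.0, 6.0, 5.5, 4.9, 6.1, 5.0]])
        meta = make_meta(
            {"s0": Treatment.REFERENCE_STANDARD, "s1": Treatment.REFERENCE_STANDARD,
             "s2": Treatment.GA, "s3": Treatment.GA, "s4": Treatment.GA,
             "s5": Treatment.GA}
        )
        tol = V.tolerance_ranges(m, meta, ["p0"])
        r = V.tolerance_percentages(m, meta, tol, Treatment.GA)
        assert r.pct_within.loc["p0"] == pytest.approx(50.0)

    def test_percentage_monotone_in_range_width(self, small_study):
        m, meta, _, _ = small_study
        probes = m.probe_ids[:30]
        tol = V.tolerance_ranges(m, meta, probes)
        r1 = V.tolerance_percentages(m, meta, tol, Treatment.GENERIC)
        wider = tol.ranges.copy()
        wider["range_low"] -= 1.0
        wider["range_high"] += 1.0
        r2 = V.tolerance_percentages(
            m, meta, V.ToleranceResult(ranges=wider), Treatment.GENERIC
        )
        assert (r2.pct_within >= r1.pct_within).all()

    def test_curve_sorted_ascending(self, small_study):
        m, meta, _, _ = small_study
        tol = V.tolerance_ranges(m, meta, m.probe_ids[:100])
        r = V.tolerance_percentages(m, meta, tol, Treatment.GA)
        assert (np.diff(r.curve["pct_within"].to_numpy()) >= 0).all()

    def test_count_failing(self):
        tol = V.ToleranceResult(
            ranges=pd.DataFrame(),
            pct_within=pd.Series([50.0, 80.0, 100.0], index=list("abc")),
        )
        assert V.count_failing(tol, 75) == 1
        assert V.count_failing(tol, 0) == 0
        with pytest.raises(ValueError):
            V.count_failing(tol, 101)


class TestVarianceRatio:
    def _study(self, values):
        m = make_matrix(values)
        n = len(values[0])
        half = n // 2
        meta = make_meta(
            {f"s{j}": (Treatment.GENERIC if j < half else Treatment.GA)
             for j in range(n)}
        )
        return m, meta

    def test_ratio_of_sample_variances(self):
        m, meta = self._study([[0.0, 4.0, 1.0, 3.0]])  # var 8 vs var 2
        df = V.variance_ratio_ranking(m, meta)
        assert df["ratio"].iloc[0] == pytest.approx(4.0)

    def test_identical_groups_unit_ratio(self):
        m, meta = self._study([[1.0, 5.0, 1.0, 5.0], [2.0, 8.0, 2.0, 8.0]])
        df = V.variance_ratio_ranking(m, meta)
        np.testing.assert_allclose(df["ratio"], 1.0)

    def test_scaling_generic_by_c_scales_ratio_by_c_squared(self, small_study):
        m, meta, _, _ = small_study
        sub = m.subset_probes(m.probe_ids[:50])
        base = V.variance_ratio_ranking(sub, meta).set_index("probe_id")["ratio"]
        scaled_data = sub.data.copy()
        gen = meta.samples_with(Treatment.GENERIC)
        scaled_data[gen] *= 3.0
        scaled = V.variance_ratio_ranking(
            type(sub)(scaled_data), meta
        ).set_index("probe_id")["ratio"]
        np.testing.assert_allclose(scaled[base.index], base * 9.0, rtol=1e-12)

    def test_zero_ga_variance_sentinel_first(self):
        m, meta = self._study([[1.0, 2.0, 7.0, 7.0], [1.0, 2.0, 0.0, 4.0]])
        df = V.variance_ratio_ranking(m, meta)
        assert df.iloc[0]["probe_id"] == "p0"
        assert np.isinf(df.iloc[0]["ratio"]) and df.iloc[0]["degenerate"]


class TestCoefficientOfVariation:
    def test_constant_and_hand_computed(self):
        m = make_matrix([[4.0, 4.0, 4.0], [2.0, 4.0, 6.0]])
        meta = make_meta({s: Treatment.GA for s in m.sample_ids})
        df = V.coefficient_of_variation(m, meta, Treatment.GA)
        assert df.loc["p0", "cv"] == pytest.approx(0.0)
        assert df.loc["p1", "cv"] == pytest.approx(0.5)  # sd 2 / mean 4

    def test_sample_reordering_invariance(self):
        rng = np.random.default_rng(3)
        m = make_matrix(rng.normal(7, 1, (20, 6)))
        meta = make_meta({s: Treatment.GENERIC for s in m.sample_ids})
        df1 = V.coefficient_of_variation(m, meta, Treatment.GENERIC)
        shuffled = m.subset_samples(list(rng.permutation(m.sample_ids)))
        df2 = V.coefficient_of_variation(shuffled, meta, Treatment.GENERIC)
        np.testing.assert_allclose(df1["cv"], df2["cv"], atol=1e-12)

    def test_nonpositive_mean_flagged(self):
        m = make_matrix([[-1.0, -3.0]])
        meta = make_meta({s: Treatment.GA for s in m.sample_ids})
        df = V.coefficient_of_variation(m, meta, Treatment.GA)
        assert df.loc["p0", "undefined"] and np.isnan(df.loc["p0", "cv"])


class TestSubsampleSensitivity:
    def test_paired_t_closed_form(self):
        t, p, degenerate = V.paired_difference_test([1.0, 2.0, 3.0])
        assert t == pytest.approx(3.464, abs=1e-3)
        assert p == pytest.approx(0.0742, abs=1e-3)
        assert not degenerate

    def test_all_zero_differences_degenerate(self):
        t, p, degenerate = V.paired_difference_test([0.0, 0.0, 0.0])
        assert degenerate and p == 1.0

    def test_fixed_seed_reproducible(self, small_study):
        m, meta, _, _ = small_study
        t1, p1 = V.subsample_sensitivity(m, meta, n_repeats=3, seed=42)
        t2, p2 = V.subsample_sensitivity(m, meta, n_repeats=3, seed=42)
        pd.testing.assert_frame_equal(t1, t2)
        assert p1 == p2

    def test_detects_planted_inflation(self, small_study):
        m, meta, _, _ = small_study
        _, p = V.subsample_sensitivity(m, meta, n_repeats=10, seed=1)
        assert p < 0.05
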