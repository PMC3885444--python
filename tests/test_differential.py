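import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from glatcomp.core import Treatment
from glatcomp import differential as D

from conftest import four_group_study, make_matrix, make_meta


def bh_oracle(p):
    """Direct-formula BH with explicit sort, for cross-checking."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * n / rank)
        q[i] = prev
    return q


class TestBhAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(
            D.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert D.bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 30))
            np.testing.assert_allclose(D.bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.uniform(size=500)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(D.bh_adjust(p), q_sm, atol=1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        np.testing.assert_allclose(
            D.bh_adjust(p)[perm], D.bh_adjust(p[perm]), atol=1e-14
        )

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            D.bh_adjust([0.5, 1.5])


class TestAnovaPerProbe:
    def _two_groups(self, a, b):
        vals = np.concatenate([a, b])[None, :]
        m = make_matrix(vals)
        meta = make_meta(
            {f"s{j}": (Treatment.GA if j < len(a) else Treatment.GENERIC)
             for j in range(len(vals[0]))}
        )
        return m, meta

    def test_two_group_anova_equals_pooled_t(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=5), rng.normal(size=8)
        m, meta = self._two_groups(a, b)
        p_anova = D.anova_per_probe(
            m, meta, [Treatment.GA, Treatment.GENERIC]
        ).iloc[0]
        p_t = stats.ttest_ind(a, b, equal_var=True).pvalue
        assert p_anova == pytest.approx(p_t, abs=1e-12)

    def test_three_group_toy_hand_anova(self):
        # groups {1,2,3},{4,5,6},{7,8,9}: SSB=54 (df 2), SSW=6 (df 6) -> F=27
        m = make_matrix(np.arange(1.0, 10.0)[None, :])
        meta = make_meta(
            {
                **{f"s{j}": Treatment.GA for j in range(3)},
                **{f"s{j}": Treatment.GENERIC for j in range(3, 6)},
                **{f"s{j}": Treatment.MEDIUM for j in range(6, 9)},
            }
        )
        p = D.anova_per_probe(
            m, meta, [Treatment.GA, Treatment.GENERIC, Treatment.MEDIUM]
        ).iloc[0]
        assert p == pytest.approx(float(stats.f.sf(27.0, 2, 6)), abs=1e-12)

    def test_null_p_uniform(self):
        m, meta = four_group_study(n_probes=10000, seed=4)
        p = D.anova_per_probe(m, meta, [Treatment.GA, Treatment.GENERIC])
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_small_group_errors(self):
        m = make_matrix(np.zeros((1, 3)))
        meta = make_meta(
            {"s0": Treatment.GA, "s1": Treatment.GA, "s2": Treatment.GENERIC}
        )
        with pytest.raises(ValueError):
            D.anova_per_probe(m, meta, [Treatment.GA, Treatment.GENERIC])


def _two_group_matrix(n_probes, n_a, n_b, seed=0, shift=0.0, n_shift=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (n_probes, n_a + n_b))
    X[:n_shift, :n_a] += shift
    m = make_matrix(X)
    meta = make_meta(
        {f"s{j}": (Treatment.GA if j < n_a else Treatment.GENERIC)
         for j in range(n_a + n_b)}
    )
    return m, meta


class TestModeratedFit:
    def _cellmeans(self, n_a, n_b):
        X = np.zeros((n_a + n_b, 2))
        X[:n_a, 0] = 1
        X[n_a:, 1] = 1
        return X, np.array([1.0, -1.0])

    def test_zero_prior_df_recovers_ordinary_t(self):
        m, _ = _two_group_matrix(200, 4, 4, seed=5)
        X, c = self._cellmeans(4, 4)
        fit = D.moderated_linear_fit(m, X, c, prior_df=0.0)
        t_ref = stats.ttest_ind(m.values[:, :4], m.values[:, 4:], axis=1,
                                equal_var=True)
        np.testing.assert_allclose(fit.t, t_ref.statistic, atol=1e-10)
        np.testing.assert_allclose(fit.p, t_ref.pvalue, atol=1e-10)

    def test_infinite_prior_df_uses_common_variance(self):
        m, _ = _two_group_matrix(200, 4, 4, seed=6)
        X, c = self._cellmeans(4, 4)
        fit = D.moderated_linear_fit(m, X, c, prior_df=np.inf)
        effects = fit.effect.to_numpy()
        ts = fit.t.to_numpy()
        # t / effect constant across probes when one pooled sd is used
        ratio = ts / effects
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-10)

    def test_moderation_improves_ranking_at_small_n(self):
        from sklearn.metrics import roc_auc_score

        m, _ = _two_group_matrix(5000, 3, 3, seed=7, shift=1.0, n_shift=250)
        X, c = self._cellmeans(3, 3)
        truth = np.zeros(5000, dtype=int)
        truth[:250] = 1
        mod = D.moderated_linear_fit(m, X, c)
        ord_ = D.moderated_linear_fit(m, X, c, prior_df=0.0)
        auc_mod = roc_auc_score(truth, np.abs(mod.t.to_numpy()))
        auc_ord = roc_auc_score(truth, np.abs(ord_.t.to_numpy()))
        assert auc_mod >= auc_ord

    @pytest.mark.parametrize("d0_true", [4.0, 10.0, 50.0])
    def test_prior_df_recovered_within_25pct(self, d0_true):
        rng = np.random.default_rng(int(d0_true))
        n_probes, n = 20000, 6
        s0 = 0.05
        sigma2 = s0 * d0_true / rng.chisquare(d0_true, n_probes)
        Y = rng.normal(0, 1, (n_probes, n)) * np.sqrt(sigma2)[:, None]
        m = make_matrix(Y)
        X, c = self._cellmeans(3, 3)
        fit = D.moderated_linear_fit(m, X, c)
        assert fit.prior_df == pytest.approx(d0_true, rel=0.25)

    def test_rank_deficient_design_errors(self):
        m, _ = _two_group_matrix(10, 3, 3)
        X = np.ones((6, 2))  # two identical columns
        with pytest.raises(ValueError, match="aliased"):
            D.moderated_linear_fit(m, X, np.array([1.0, -1.0]))


class TestSnr:
    def test_worked_example_no_floor(self):
        score = D.snr_scores([2.0, 4.0], [0.0, 2.0])[0]
        assert score == pytest.approx(2.0 / (2.0 * math.sqrt(2.0)), abs=1e-4)
        assert score == pytest.approx(0.7071, abs=1e-4)

    def test_identical_classes_zero_score(self):
        assert D.snr_scores([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])[0] == 0.0

    def test_sd_floor_engages_for_tight_data(self):
        # sd = 0 but |mu| = 10 -> floor 2.0 per class
        score = D.snr_scores([10.0, 10.0], [5.0, 5.0])[0]
        assert score == pytest.approx(5.0 / (2.0 + 1.0))

    def test_exhaustive_permutation_matches_bruteforce(self):
        rng = np.random.default_rng(8)
        m, meta = _two_group_matrix(5, 3, 3, seed=8)
        res = D.snr_test(m, meta, Treatment.GA, Treatment.GENERIC, n_perm=1000)
        combined = m.values
        for i, probe in enumerate(m.probe_ids):
            obs = abs(D.snr_scores(combined[i, :3], combined[i, 3:])[0])
            count = 0
            total = 0
            for idx in itertools.combinations(range(6), 3):
                mask = np.zeros(6, bool)
                mask[list(idx)] = True
                s = abs(D.snr_scores(combined[i, mask], combined[i, ~mask])[0])
                count += s >= obs - 1e-12
                total += 1
            assert res["snr_p"].iloc[i] == pytest.approx(count / total, abs=1e-12)


class TestTwoSampleT:
    def test_welch_worked_example(self):
        m, meta = _two_group_matrix(1, 3, 3)
        m = make_matrix([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
        res = D.two_sample_t(m, meta, Treatment.GA, Treatment.GENERIC)
        assert res["t"].iloc[0] == pytest.approx(-3.674, abs=1e-3)
        assert res["t_p"].iloc[0] == pytest.approx(0.0214, abs=1e-3)

    def test_equal_groups_null_point(self):
        m, meta = _two_group_matrix(1, 2, 2)
        m = make_matrix([[5.0, 7.0, 5.0, 7.0]])
        res = D.two_sample_t(m, meta, Treatment.GA, Treatment.GENERIC)
        assert res["t"].iloc[0] == pytest.approx(0.0)
        assert res["t_p"].iloc[0] == pytest.approx(1.0)

    def test_antisymmetric_under_class_swap(self):
        m, meta = _two_group_matrix(50, 4, 6, seed=9)
        ab = D.two_sample_t(m, meta, Treatment.GA, Treatment.GENERIC)
        ba = D.two_sample_t(m, meta, Treatment.GENERIC, Treatment.GA)
        np.testing.assert_allclose(ab["t"], -ba["t"], atol=1e-12)
        np.testing.assert_allclose(ab["t_p"], ba["t_p"], atol=1e-12)


class TestWilcoxon:
    def test_exact_tail_worked_example(self):
        m, meta = _two_group_matrix(1, 3, 3)
        m = make_matrix([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
        res = D.wilcoxon_rank_sum(m, meta, Treatment.GA, Treatment.GENERIC)
        assert res["wilcoxon_p"].iloc[0] == pytest.approx(0.1, abs=1e-12)

    def test_identical_multisets_p_one(self):
        m, meta = _two_group_matrix(1, 3, 3)
        m = make_matrix([[1.0, 5.0, 9.0, 9.0, 5.0, 1.0]])
        res = D.wilcoxon_rank_sum(m, meta, Treatment.GA, Treatment.GENERIC)
        assert res["wilcoxon_p"].iloc[0] == pytest.approx(1.0)

    def test_exact_and_normal_approx_agree_at_n10(self):
        m, meta = _two_group_matrix(100, 10, 10, seed=10)
        res = D.wilcoxon_rank_sum(m, meta, Treatment.GA, Treatment.GENERIC)
        approx = stats.mannwhitneyu(
            m.values[:, :10], m.values[:, 10:], axis=1,
            alternative="two-sided", method="asymptotic",
        ).pvalue
        np.testing.assert_allclose(res["wilcoxon_p"], approx, atol=0.01)


class TestConsensusAndFoldChange:
    def _table(self, qs, signs):
        return pd.DataFrame(
            {
                "anova_q": [qs[0]], "limma_q": [qs[1]],
                "t_q": [qs[2]], "snr_q": [qs[3]],
                "log2_fc": [signs[0]], "limma_effect": [signs[1]],
                "t": [signs[2]], "snr_score": [signs[3]],
            },
            index=pd.Index(["p0"], name="probe_id"),
        )

    def test_all_four_significant_same_direction_included(self):
        t = self._table([0.01, 0.02, 0.04, 0.049], [1, 1, 1, 1])
        higher_a, higher_b = D.consensus_significant(t)
        assert higher_a == ["p0"] and higher_b == []

    def test_three_of_four_excluded(self):
        t = self._table([0.01, 0.02, 0.04, 0.06], [1, 1, 1, 1])
        assert D.consensus_significant(t) == ([], [])

    def test_direction_disagreement_excluded(self):
        t = self._table([0.01, 0.01, 0.01, 0.01], [1, -1, 1, 1])
        assert D.consensus_significant(t) == ([], [])

    def test_consensus_subset_of_each_individual_set(self, small_study):
        m, meta, _, _ = small_study
        sub = m.subset_probes(m.probe_ids[:300])
        table = D.build_differential_table(sub, meta, n_perm=200, seed=0)
        higher_a, higher_b = D.consensus_significant(table)
        consensus = set(higher_a) | set(higher_b)
        for qcol in ("anova_q", "limma_q", "t_q", "snr_q"):
            individual = set(table.index[table[qcol] <= 0.05])
            assert consensus <= individual

    def test_fold_change_ranking_order_and_antisymmetry(self):
        m = make_matrix(
            [[1.0, 1.0, 5.0, 5.0], [9.0, 9.0, 1.0, 1.0], [3.0, 3.0, 3.5, 3.5]]
        )
        meta = make_meta(
            {"s0": Treatment.GA, "s1": Treatment.GA,
             "s2": Treatment.GENERIC, "s3": Treatment.GENERIC}
        )
        fwd = D.fold_change_ranking(m, meta, Treatment.GA, Treatment.GENERIC)
        assert fwd["probe_id"].tolist() == ["p1", "p0", "p2"]
        rev = D.fold_change_ranking(m, meta, Treatment.GENERIC, Treatment.GA)
        assert rev["probe_id"].tolist() == fwd["probe_id"].tolist()
        np.testing.assert_allclose(rev["log2_fc"], -fwd["log2_fc"])
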