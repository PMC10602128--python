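"""Evaluation statistics against hand-worked and brute-force oracles."""

import numpy as np
import pytest

from thetapet.errors import ConfigError
from thetapet.stats import (
    classification_metrics,
    cohens_d_ttest,
    confusion_rates,
    icc_across_runs,
    spearman_ols,
)


def _labels_from_counts(tp, fn, tn, fp):
    reference = np.concatenate([np.ones(tp + fn, int), np.zeros(tn + fp, int)])
    comparator = np.concatenate(
        [np.ones(tp, int), np.zeros(fn, int), np.zeros(tn, int), np.ones(fp, int)]
    )
    return reference, comparator


class TestConfusionRates:
    def test_identity_gives_perfect_agreement(self):
        y = np.array([1, 0, 1, 1, 0])
        rep = confusion_rates(y, y)
        assert rep.tpr == 1.0 and rep.tnr == 1.0
        assert rep.pos_mismatch == 0.0 and rep.neg_mismatch == 0.0

    def test_published_model_comparison_cell(self):
        """TP=236 of 245 positives, TN=1040 of 1045 negatives →
        mismatch rates 3.67% and 0.48%."""
        ref, cmp_ = _labels_from_counts(tp=236, fn=9, tn=1040, fp=5)
        rep = confusion_rates(ref, cmp_)
        assert rep.pos_mismatch_pct() == 3.67
        assert rep.neg_mismatch_pct() == 0.48

    def test_published_mtl_comparison_cell(self):
        ref, cmp_ = _labels_from_counts(tp=191, fn=54, tn=993, fp=52)
        rep = confusion_rates(ref, cmp_)
        assert rep.pos_mismatch_pct() == 22.04

    def test_row_order_invariance(self, rng):
        ref = rng.integers(0, 2, 300)
        cmp_ = rng.integers(0, 2, 300)
        perm = rng.permutation(300)
        a, b = confusion_rates(ref, cmp_), confusion_rates(ref[perm], cmp_[perm])
        assert (a.tp, a.tn, a.fp, a.fn) == (b.tp, b.tn, b.fp, b.fn)

    def test_no_positives_leaves_tpr_undefined(self, caplog):
        rep = confusion_rates(np.zeros(10, int), np.ones(10, int))
        assert rep.tpr is None and rep.pos_mismatch is None
        assert rep.tnr == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ConfigError):
            confusion_rates([0, 1], [0, 1, 1])


class TestClassificationMetrics:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        p = np.array([0.1, 0.2, 0.8, 0.9])
        rep = classification_metrics(y, (p > 0.5).astype(int), p)
        assert rep.roc_auc == 1.0 and rep.mcc == 1.0
        assert rep.balanced_accuracy == 1.0 and rep.f1 == 1.0

    def test_hand_worked_auc(self):
        """Six scans, one discordant pair among nine (the positive at 0.35
        ranks below the negative at 0.4): AUC = 8/9 by pair counting."""
        p = np.array([0.1, 0.2, 0.35, 0.4, 0.8, 0.7])
        y = np.array([0, 0, 1, 0, 1, 1])
        rep = classification_metrics(y, (p > 0.5).astype(int), p)
        assert rep.roc_auc == pytest.approx(8 / 9)

    def test_anticorrelated_probabilities_score_below_half(self):
        y = np.array([0, 0, 1, 1, 1, 0])
        rep = classification_metrics(y, y, 1.0 - y * 0.5 - 0.1)
        assert rep.roc_auc < 0.5

    def test_constant_probabilities_fall_back_to_half(self, caplog):
        y = np.array([0, 1, 0, 1])
        rep = classification_metrics(y, y, np.full(4, 0.5))
        assert rep.roc_auc == 0.5

    def test_auc_equals_pairwise_concordance_oracle(self, rng):
        """Rank AUC equals brute-force concordant-pair counting with midrank
        tie handling, checked on all instances up to n = 200."""
        for n in (20, 97, 200):
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                y[0] = 1 - y[0]
            p = np.round(rng.uniform(0, 1, n), 2)  # induce ties
            rep = classification_metrics(y, (p > 0.5).astype(int), p)
            pos, neg = p[y == 1], p[y == 0]
            wins = sum(
                1.0 if a > b else 0.5 if a == b else 0.0
                for a in pos for b in neg
            )
            assert rep.roc_auc == pytest.approx(wins / (len(pos) * len(neg)))


class TestSpearmanOLS:
    def test_exact_linear_relationship(self):
        x = np.arange(10, dtype=float)
        rep = spearman_ols(x, 2 * x + 1)
        assert rep.spearman_rho == pytest.approx(1.0)
        assert rep.ols_slope == pytest.approx(2.0)
        assert rep.ols_intercept == pytest.approx(1.0)
        assert rep.n_pairs == 10

    def test_monotone_invariance_of_rho(self):
        x = np.linspace(-2, 2, 50)
        rep = spearman_ols(x, -(x ** 3))
        assert rep.spearman_rho == pytest.approx(-1.0)
        assert rep.ols_slope != pytest.approx(-1.0)

    def test_independent_variables_near_zero(self, rng):
        x = rng.normal(size=2000)
        y = rng.normal(size=2000)
        rep = spearman_ols(x, y)
        assert abs(rep.spearman_rho) < 0.08

    def test_missing_values_dropped_pairwise(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([2.0, 4.0, 6.0, np.nan, 10.0])
        rep = spearman_ols(x, y)
        assert rep.n_pairs == 3

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ConfigError):
            spearman_ols([1.0, 2.0], [1.0, 2.0])

    def test_constant_input_reported_missing(self):
        rep = spearman_ols(np.ones(5), np.arange(5.0))
        assert rep.spearman_rho is None


class TestCohensD:
    def test_identical_groups_null(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        rep = cohens_d_ttest(a, a.copy())
        assert rep.cohens_d == pytest.approx(0.0)
        assert rep.p_value == pytest.approx(1.0)

    def test_hand_worked_pooled_d(self):
        """a = {2,4}, b = {0,2}: pooled SD = √2, d = 2/√2 = √2."""
        rep = cohens_d_ttest([2.0, 4.0], [0.0, 2.0])
        assert rep.cohens_d == pytest.approx(np.sqrt(2))

    def test_bonferroni_caps_at_one(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.1, 1, 20)
        rep = cohens_d_ttest(a, b, n_comparisons=50)
        assert rep.p_adjusted == 1.0 or rep.p_adjusted == pytest.approx(
            min(1.0, rep.p_value * 50)
        )

    def test_bonferroni_monotone_in_comparisons(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 1, 30)
        adj = [
            cohens_d_ttest(a, b, n_comparisons=k).p_adjusted for k in (1, 2, 4, 8)
        ]
        assert all(x <= y for x, y in zip(adj, adj[1:]))
        assert all(x <= 1.0 for x in adj)

    def test_agrees_with_pingouin_pooled_effsize(self, rng):
        import pingouin as pg

        a = rng.normal(0.0, 1.0, 25)
        b = rng.normal(0.7, 1.2, 35)
        rep = cohens_d_ttest(a, b)
        assert rep.cohens_d == pytest.approx(
            float(pg.compute_effsize(a, b, eftype="cohen")), abs=1e-10
        )

    def test_small_groups_rejected(self):
        with pytest.raises(ConfigError):
            cohens_d_ttest([1.0], [1.0, 2.0])

    def test_zero_variance_reported_missing(self):
        rep = cohens_d_ttest([1.0, 1.0, 1.0], [1.0, 1.0])
        assert rep.cohens_d is None


class TestICC:
    def test_identical_runs_perfect_agreement(self, rng):
        col = rng.normal(0, 1, 12)
        M = np.column_stack([col, col, col])
        assert icc_across_runs(M) == pytest.approx(1.0)

    def test_independent_runs_near_zero(self, rng):
        M = rng.normal(0, 1, (500, 4))
        assert abs(icc_across_runs(M)) < 0.12

    def test_constant_offset_breaks_absolute_agreement(self, rng):
        col = rng.normal(0, 1, 30)
        M = np.column_stack([col, col + 1.0])
        assert icc_across_runs(M) < 1.0

    def test_matches_mean_squares_oracle_on_toy_matrix(self):
        """Hand mean-squares ICC(2,1) on a 4×2 matrix."""
        M = np.array([[1.0, 2.0], [3.0, 3.5], [5.0, 4.0], [7.0, 8.0]])
        n, k = M.shape
        grand = M.mean()
        ms_rows = k * np.sum((M.mean(axis=1) - grand) ** 2) / (n - 1)
        ms_cols = n * np.sum((M.mean(axis=0) - grand) ** 2) / (k - 1)
        resid = M - M.mean(axis=1, keepdims=True) - M.mean(axis=0) + grand
        ms_err = np.sum(resid ** 2) / ((n - 1) * (k - 1))
        expected = (ms_rows - ms_err) / (
            ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
        )
        assert icc_across_runs(M) == pytest.approx(expected, abs=1e-10)

    def test_constant_matrix_undefined(self):
        assert np.isnan(icc_across_runs(np.ones((5, 3))))

    def test_shape_requirements(self):
        with pytest.raises(ConfigError):
            icc_across_runs(np.ones((2, 2)))
        with pytest.raises(ConfigError):
            icc_across_runs(np.ones((5, 1)))
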