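import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

import oracles
from irsflow.prediction import (
    HIGH,
    LOW,
    ClassifierReport,
    ThresholdRule,
    anova_across_doses,
    bootstrap_auc_ci,
    classify_and_score,
    gaussian_threshold,
    ks_normality,
    pearson,
    roc_analysis,
)


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        res = pearson(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0, abs=1e-12)
        assert res.p_value < 1e-10

    def test_covariance_formula_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0])
        res = pearson(x, y)
        assert res.r == pytest.approx(oracles.pearson_r(x, y), rel=1e-12)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson(np.arange(5.0), np.full(5, 3.0))

    def test_nan_pairs_dropped(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([1.0, 2.5, 3.0, 3.5, 5.5])
        res = pearson(x, y)
        assert res.n_used == 4

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match=">= 3"):
            pearson([1.0, 2.0], [1.0, 2.0])


class TestKSNormality:
    def test_gaussian_draws_rarely_rejected(self):
        """Under the null the KS p-value should clear 0.05 in the vast
        majority of replicates (the estimated-parameter version is
        conservative)."""
        passes = 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            values = rng.normal(10.0, 2.0, size=10_000)
            _, p, _ = ks_normality(values)
            passes += p > 0.05
        assert passes >= 90

    def test_bimodal_has_larger_d_than_gaussian(self):
        rng = np.random.default_rng(7)
        n = 4000
        gauss = rng.normal(0.0, 1.0, size=n)
        rng = np.random.default_rng(7)
        bimodal = np.concatenate([rng.normal(-3, 0.5, n // 2), rng.normal(3, 0.5, n - n // 2)])
        d_gauss, _, r2_gauss = ks_normality(gauss)
        d_bimodal, _, r2_bimodal = ks_normality(bimodal)
        assert d_bimodal > d_gauss
        assert r2_bimodal < r2_gauss

    def test_gaussian_histogram_fit_r2_high(self):
        rng = np.random.default_rng(5)
        _, _, r2 = ks_normality(rng.normal(size=5000))
        assert r2 > 0.9

    def test_constant_values_error(self):
        with pytest.raises(ValueError, match="constant"):
            ks_normality(np.full(100, 3.0))


class TestGaussianThreshold:
    # mean 10, sample SD exactly 2
    values = np.array([8.0, 10.0, 12.0])

    def test_one_sd(self):
        rule = gaussian_threshold(self.values, k=1, direction=HIGH)
        assert rule.cutoff == pytest.approx(12.0, rel=1e-12)

    def test_two_sd(self):
        rule = gaussian_threshold(self.values, k=2, direction=HIGH)
        assert rule.cutoff == pytest.approx(14.0, rel=1e-12)

    def test_low_direction(self):
        rule = gaussian_threshold(self.values, k=1, direction=LOW)
        assert rule.cutoff == pytest.approx(8.0, rel=1e-12)

    def test_zero_sd_errors(self):
        with pytest.raises(ValueError, match="zero SD"):
            gaussian_threshold(np.full(5, 1.0), k=1)

    def test_invalid_k(self):
        with pytest.raises(ValueError, match="k must be"):
            ThresholdRule("x", HIGH, 3, 1.0)

    def test_centile_coverage_monte_carlo(self):
        """mean±1SD captures ~68.27% and ±2SD ~95.45% of Gaussian draws."""
        rng = np.random.default_rng(2)
        draws = rng.normal(size=200_000)
        mu, sd = draws.mean(), draws.std(ddof=1)
        within1 = 100.0 * np.mean(np.abs(draws - mu) <= sd)
        within2 = 100.0 * np.mean(np.abs(draws - mu) <= 2 * sd)
        assert within1 == pytest.approx(100 * (2 * stats.norm.cdf(1) - 1), abs=0.4)
        assert within2 == pytest.approx(100 * (2 * stats.norm.cdf(2) - 1), abs=0.4)


class TestClassifyAndScore:
    def test_perfect_separation(self):
        values = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        grades = np.array([0, 1, 1, 2, 2, 3])
        rule = ThresholdRule("idx", HIGH, 1, 5.0)
        rep = classify_and_score(values, grades, rule)
        assert (rep.sensitivity, rep.specificity, rep.accuracy) == (100.0, 100.0, 100.0)
        assert (rep.ppv, rep.npv) == (100.0, 100.0)

    def test_cohort_2x2_arithmetic(self):
        """A 50-patient cohort with 18 overreactors, 8 of whom are caught
        with no false alarms: the 2x2 arithmetic gives sens 44.4%,
        spec 100%, acc 80%, NPV 76.2% (and PPV is forced to 100% by the
        zero false-positive count)."""
        rep = ClassifierReport.from_counts(tp=8, fp=0, tn=32, fn=10)
        expected = oracles.confusion_metrics(8, 0, 32, 10)
        assert rep.sensitivity == pytest.approx(expected["sensitivity"])
        assert rep.sensitivity == pytest.approx(44.4, abs=0.05)
        assert rep.specificity == 100.0
        assert rep.accuracy == pytest.approx(80.0, abs=1e-12)
        assert rep.npv == pytest.approx(76.2, abs=0.05)
        assert rep.ppv == 100.0

    def test_all_predicted_negative(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0, 1, size=50)
        grades = np.array([2] * 18 + [0] * 32)
        rule = ThresholdRule("idx", HIGH, 1, 2.0)  # above every score
        rep = classify_and_score(values, grades, rule)
        assert rep.sensitivity == 0.0
        assert rep.specificity == 100.0
        assert rep.accuracy == pytest.approx(64.0)
        assert rep.ppv is None  # undefined, never imputed as 0

    def test_single_class_truth_errors(self):
        rule = ThresholdRule("idx", HIGH, 1, 0.5)
        with pytest.raises(ValueError, match="single-class"):
            classify_and_score(np.arange(5.0), np.zeros(5), rule)

    def test_nan_values_dropped_pairwise(self):
        values = np.array([np.nan, 1.0, 2.0, 10.0, 11.0])
        grades = np.array([3, 0, 1, 2, 3])
        rep = classify_and_score(values, grades, ThresholdRule("idx", HIGH, 1, 5.0))
        assert rep.n_dropped == 1
        assert rep.n == 4

    def test_metric_identity_random(self, rng):
        """accuracy == (sens·P + spec·N)/(P+N) for arbitrary reports."""
        for _ in range(200):
            tp, fp, tn, fn = rng.integers(1, 30, size=4)
            rep = ClassifierReport.from_counts(int(tp), int(fp), int(tn), int(fn))
            pos, neg = tp + fn, tn + fp
            expected = (rep.sensitivity * pos + rep.specificity * neg) / (pos + neg)
            assert rep.accuracy == pytest.approx(expected, rel=1e-12)


class TestROC:
    def test_perfect_ranking(self):
        roc = roc_analysis([1.0, 2.0, 3.0, 4.0], [0, 0, 1, 1])
        assert roc.auc == pytest.approx(1.0)

    def test_uninformative_scores(self):
        roc = roc_analysis([5.0, 5.0, 5.0, 5.0], [0, 1, 0, 1])
        assert roc.auc == pytest.approx(0.5)

    def test_tied_scores_pair_counting_oracle(self):
        scores = [1.0, 2.0, 2.0, 3.0, 4.0]
        labels = [0, 0, 1, 1, 1]
        roc = roc_analysis(scores, labels)
        assert roc.auc == pytest.approx(oracles.auc_pair_counting(scores, labels), abs=1e-12)

    def test_trapezoid_equals_mann_whitney_random(self, rng):
        for _ in range(300):
            n = int(rng.integers(4, 25))
            scores = rng.integers(0, 6, size=n).astype(float)  # many ties
            labels = rng.integers(0, 2, size=n)
            if labels.all() or not labels.any():
                continue
            roc = roc_analysis(scores, labels)
            assert roc.auc == pytest.approx(oracles.auc_pair_counting(scores, labels), abs=1e-10)
            assert roc.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-10)

    def test_direction_symmetry(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        auc_high = roc_analysis(scores, labels, HIGH).auc
        auc_low = roc_analysis(-scores, labels, LOW).auc
        assert auc_low == pytest.approx(auc_high, abs=1e-12)

    def test_youden_cutoff_separating_case(self):
        scores = np.array([1.0, 2.0, 3.0, 10.0, 11.0])
        labels = np.array([0, 0, 0, 1, 1])
        roc = roc_analysis(scores, labels)
        assert 3.0 < roc.optimal_cutoff <= 10.0
        # predicted positive iff score >= cutoff reproduces the labels
        assert np.array_equal(scores >= roc.optimal_cutoff, labels.astype(bool))

    def test_youden_tie_breaks_toward_specificity(self):
        # J is maximal (=0.5) at cutoffs 2 and 3; prefer the one with fewer FPs
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        labels = np.array([0, 1, 0, 1])
        roc = roc_analysis(scores, labels)
        fpr_at = lambda c: np.mean(scores[labels == 0] >= c)
        tpr_at = lambda c: np.mean(scores[labels == 1] >= c)
        j_opt = tpr_at(roc.optimal_cutoff) - fpr_at(roc.optimal_cutoff)
        for c in np.unique(scores):
            j_c = tpr_at(c) - fpr_at(c)
            assert j_opt >= j_c - 1e-12
            if j_c == j_opt:
                assert fpr_at(roc.optimal_cutoff) <= fpr_at(c)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="single-class"):
            roc_analysis([1.0, 2.0], [1, 1])

    def test_bootstrap_ci_brackets_point_auc(self, rng):
        scores = rng.normal(size=60) + rng.integers(0, 2, size=60) * 1.5
        labels = scores > np.median(scores)
        scores = scores + rng.normal(scale=0.5, size=60)
        point = roc_analysis(scores, labels).auc
        lo, hi = bootstrap_auc_ci(scores, labels, n_boot=500, seed=8)
        assert lo <= point <= hi


class TestANOVA:
    def test_equal_group_means_give_zero_f(self):
        groups = {0.0: np.array([1.0, 2.0, 3.0]), 1.0: np.array([0.0, 2.0, 4.0])}
        f, p = anova_across_doses(groups)
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_textbook_sums_of_squares(self):
        g1, g2 = [3.0, 4.0, 5.0], [7.0, 8.0, 12.0]
        f, p = anova_across_doses({0.0: np.array(g1), 2.0: np.array(g2)})
        assert f == pytest.approx(oracles.anova_f([g1, g2]), rel=1e-12)
        assert 0 < p < 1

    def test_matches_oracle_random(self, rng):
        for _ in range(100):
            groups = [list(rng.normal(loc=m, size=rng.integers(2, 10)))
                      for m in rng.normal(size=rng.integers(2, 5))]
            f, _ = anova_across_doses({float(i): np.array(g) for i, g in enumerate(groups)})
            assert f == pytest.approx(oracles.anova_f(groups), rel=1e-10, abs=1e-10)

    def test_single_group_errors(self):
        with pytest.raises(ValueError, match=">= 2 dose groups"):
            anova_across_doses({0.0: np.array([1.0, 2.0])})
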