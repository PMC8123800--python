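"""Discrimination metrics against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from urorisk.errors import MetricError, ValidationError
from urorisk.evaluation import (
    auc,
    auc_ci,
    auc_difference_test,
    binary_endpoint,
    mean_diff_bca,
    ordinal_levels,
    proportional_odds_or,
    threshold_for_sensitivity,
)


def pairwise_auc(scores, labels):
    """Independent oracle: exhaustive concordant-pair enumeration."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestEndpoints:
    @pytest.mark.parametrize(
        "outcome,endpoint,expected",
        [
            ("Gs6", "gs_ge_3p4", False),
            ("BiopsyNegative", "any_cancer", False),
            ("NEC", "any_cancer", False),
            ("Gs6", "any_cancer", True),
            ("Gs3+4", "gs_ge_4p3", False),
            ("Gs8plus", "any_cancer", True),
            ("Gs8plus", "gs_ge_3p4", True),
            ("Gs8plus", "gs_ge_4p3", True),
        ],
    )
    def test_binary_definitions(self, outcome, endpoint, expected):
        assert binary_endpoint(outcome, endpoint) is expected

    def test_unknown_endpoint_raises(self):
        with pytest.raises(MetricError):
            binary_endpoint("Gs6", "gs_ge_9")

    def test_ordinal_levels_pool_no_cancer_and_high_grade(self):
        lv = ordinal_levels(["NEC", "BiopsyNegative", "Gs6", "Gs3+4", "Gs4+3", "Gs8plus"])
        assert list(lv) == [0, 0, 1, 2, 3, 3]


class TestAuc:
    def test_worked_example(self):
        assert auc([0.9, 0.7, 0.6, 0.8], [True, True, False, False]) == 0.75

    def test_perfect_separation(self):
        assert auc([1, 1, 0, 0], [True, True, False, False]) == 1.0

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_matches_exhaustive_pair_enumeration(self, data):
        n = data.draw(st.integers(4, 25))
        scores = data.draw(
            st.lists(st.integers(0, 8).map(float), min_size=n, max_size=n)
        )
        labels = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
        if not (any(labels) and not all(labels)):
            labels[0], labels[1] = True, False
        assert auc(scores, labels) == pytest.approx(pairwise_auc(scores, labels))

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=60)
        labels = rng.random(60) < 0.4
        assert auc(np.exp(scores), labels) == pytest.approx(auc(scores, labels))

    def test_reversal_identity_without_ties(self):
        rng = np.random.default_rng(1)
        scores = rng.permutation(40).astype(float)
        labels = rng.random(40) < 0.5
        assert auc(scores, labels) + auc(-scores, labels) == pytest.approx(1.0)

    def test_single_class_raises(self):
        with pytest.raises(MetricError):
            auc([1.0, 2.0], [True, True])


class TestAucCi:
    def test_perfect_separation_degenerate_interval(self):
        s = [1.0] * 10 + [0.0] * 10
        y = [True] * 10 + [False] * 10
        roc = auc_ci(s, y, n_resamples=50, seed=0)
        assert roc.auc == roc.ci_lower == roc.ci_upper == 1.0

    def test_two_resamples_bounds_are_min_max(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=40)
        y = rng.random(40) < 0.5
        roc = auc_ci(s, y, n_resamples=2, seed=3)
        assert roc.ci_lower <= roc.ci_upper

    def test_reproducible(self):
        rng = np.random.default_rng(4)
        s, y = rng.normal(size=50), rng.random(50) < 0.5
        a = auc_ci(s, y, n_resamples=100, seed=5)
        b = auc_ci(s, y, n_resamples=100, seed=5)
        assert (a.ci_lower, a.ci_upper) == (b.ci_lower, b.ci_upper)


class TestAucDifference:
    def test_identical_scores_null(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=60)
        y = rng.random(60) < 0.5
        delta, p = auc_difference_test(s, s, y, n_resamples=100, seed=0)
        assert delta == 0.0 and p == 1.0

    def test_sign_symmetry(self):
        rng = np.random.default_rng(1)
        y = rng.random(80) < 0.5
        a = y + 0.5 * rng.normal(size=80)
        b = rng.normal(size=80)
        d1, p1 = auc_difference_test(a, b, y, n_resamples=200, seed=2)
        d2, p2 = auc_difference_test(b, a, y, n_resamples=200, seed=2)
        assert d1 == pytest.approx(-d2)
        assert p1 == pytest.approx(p2)

    def test_detects_signal_against_noise(self):
        rng = np.random.default_rng(3)
        y = rng.random(300) < 0.5
        signal = y + 0.8 * rng.normal(size=300)
        noise = rng.normal(size=300)
        _, p = auc_difference_test(signal, noise, y, n_resamples=300, seed=4)
        assert p < 0.01

    def test_unpaired_inputs_raise(self):
        with pytest.raises(ValidationError):
            auc_difference_test([1, 2], [1, 2, 3], [True, False, True])


class TestProportionalOdds:
    @staticmethod
    def _simulate(beta, n=400, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.random(n)
        latent = beta * x + rng.logistic(size=n)
        cuts = np.quantile(beta * 0.5 + rng.logistic(size=4000), [0.45, 0.65, 0.85])
        levels = np.digitize(latent, cuts)
        outcomes = np.array(["NEC", "Gs6", "Gs3+4", "Gs4+3"], dtype=object)[levels]
        return x, outcomes

    def test_null_or_near_one(self):
        x, outcomes = self._simulate(beta=0.0, seed=1)
        eff = proportional_odds_or(x, outcomes)
        assert eff.ci_lower < 1.0 < eff.ci_upper

    def test_recovers_positive_slope(self):
        x, outcomes = self._simulate(beta=6.0, seed=2)
        eff = proportional_odds_or(x, outcomes)
        assert eff.converged
        assert eff.ci_lower < np.exp(0.1 * 6.0) < eff.ci_upper

    def test_scaling_identity(self):
        """OR per 0.1 on raw scores equals OR per 1.0 on 10x scores."""
        x, outcomes = self._simulate(beta=4.0, seed=3)
        a = proportional_odds_or(x, outcomes, per=0.1)
        b = proportional_odds_or(10 * x, outcomes, per=1.0)
        assert a.or_per_01 == pytest.approx(b.or_per_01, rel=1e-5)

    def test_too_few_levels_raise(self):
        with pytest.raises(MetricError):
            proportional_odds_or([0.1, 0.9], ["NEC", "Gs6"])


class TestMeanDiffBca:
    def test_identical_groups_cover_zero(self):
        rng = np.random.default_rng(0)
        g = rng.normal(size=40)
        est = mean_diff_bca(g, g.copy(), n_resamples=500, seed=1)
        assert est.ci_lower <= 0.0 <= est.ci_upper

    def test_constant_groups_zero_width(self):
        est = mean_diff_bca([2.0] * 10, [1.5] * 12, n_resamples=200, seed=2)
        assert est.delta == pytest.approx(0.5)
        assert est.ci_lower == est.ci_upper == pytest.approx(0.5)

    def test_point_estimate_inside_interval(self):
        rng = np.random.default_rng(3)
        est = mean_diff_bca(
            rng.normal(0.5, 1, 50), rng.normal(0, 1, 50), n_resamples=800, seed=4
        )
        assert est.ci_lower <= est.delta <= est.ci_upper
        assert est.method == "bca"

    def test_singleton_group_falls_back_to_percentile(self):
        rng = np.random.default_rng(5)
        with pytest.warns(UserWarning):
            est = mean_diff_bca([1.3], rng.normal(size=20), n_resamples=200, seed=6)
        assert est.method == "percentile"

    def test_empty_group_raises(self):
        with pytest.raises(ValidationError):
            mean_diff_bca([], [1.0])


class TestThresholdForSensitivity:
    def test_perfect_classifier_no_spillover(self):
        s = [0.9, 0.8, 0.2, 0.1]
        y = [True, True, False, False]
        thr, spill = threshold_for_sensitivity(s, y, 0.9)
        assert spill == 0.0

    def test_handcrafted_overlap_exact(self):
        """90% sensitivity forces exactly half the negatives above the cut."""
        pos = [0.30, 0.40, 0.50, 0.60, 0.70, 0.75, 0.80, 0.85, 0.90, 0.95]
        neg = [0.10, 0.20, 0.45, 0.55]  # two of four at/above 0.40
        thr, spill = threshold_for_sensitivity(pos + neg, [True] * 10 + [False] * 4, 0.9)
        assert thr == 0.40
        assert spill == 0.5

    def test_full_sensitivity_returns_min_positive(self):
        pos = [0.3, 0.5, 0.9]
        neg = [0.1, 0.6]
        thr, _ = threshold_for_sensitivity(pos + neg, [True] * 3 + [False] * 2, 1.0)
        assert thr == 0.3

    def test_invalid_target_raises(self):
        with pytest.raises(ValidationError):
            threshold_for_sensitivity([1, 0], [True, False], 0.0)
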