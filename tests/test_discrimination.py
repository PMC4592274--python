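"""ROC construction, AUC with DeLong inference, operating points and
likelihood ratios."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from psacorrect.discrimination import (
    auc,
    compare_auc_paired,
    likelihood_ratio,
    posterior_odds,
    roc_curve,
    spec_at_sensitivity,
    with_prior_odds,
)
from psacorrect.exceptions import ConfigError, DataError


def brute_force_auc(scores, labels):
    """Pairwise Mann-Whitney count: wins + half-ties over all pos/neg pairs."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestROC:
    def test_toy_enumeration(self):
        scores = [0.9, 0.8, 0.7, 0.6, 0.5]
        labels = [1, 1, 0, 0, 0]
        c = roc_curve(scores, labels)
        assert c.thresholds.tolist() == [math.inf, 0.9, 0.8, 0.7, 0.6, 0.5]
        assert c.sensitivity.tolist() == [0.0, 0.5, 1.0, 1.0, 1.0, 1.0]
        assert c.specificity.tolist() == [1.0, 1.0, 1.0, 2 / 3, 1 / 3, 0.0]

    def test_perfect_separation_passes_through_ideal_corner(self):
        c = roc_curve([3, 4, 1, 2], [1, 1, 0, 0])
        assert any(s == 1.0 and p == 1.0 for s, p in zip(c.sensitivity, c.specificity))

    def test_all_tied_scores_collapse_to_endpoints(self):
        c = roc_curve([5.0] * 6, [1, 1, 0, 0, 0, 0])
        assert c.sensitivity.tolist() == [0.0, 1.0]
        assert c.specificity.tolist() == [1.0, 0.0]
        assert auc([5.0] * 6, [1, 1, 0, 0, 0, 0]).auc == 0.5

    def test_monotone_invariants(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=60)
        y = rng.random(60) < 0.4
        c = roc_curve(s, y)
        assert np.all(np.diff(c.sensitivity) >= 0)       # thresholds descend
        assert np.all(np.diff(c.specificity) <= 0)
        assert (c.sensitivity[0], c.specificity[0]) == (0.0, 1.0)
        assert (c.sensitivity[-1], c.specificity[-1]) == (1.0, 0.0)

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            roc_curve([1, 2, 3], [1, 1, 1])


class TestAUC:
    def test_simple_interleaving(self):
        assert auc([2.0, 1.0, 3.0], [1, 0, 0]).auc == 0.5

    @pytest.mark.filterwarnings("ignore:AUC")
    def test_matches_brute_force_on_random_tied_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            n = rng.integers(2, 13)
            scores = rng.integers(0, 4, n).astype(float)   # heavy ties
            labels = np.zeros(n, dtype=bool)
            labels[rng.choice(n, rng.integers(1, n), replace=False)] = True
            if labels.all() or not labels.any():
                continue
            assert auc(scores, labels).auc == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12)

    @pytest.mark.filterwarnings("ignore:AUC")
    @given(st.lists(st.integers(-5000, 5000), min_size=4, max_size=30),
           st.data())
    @settings(derandomize=True, max_examples=60)
    def test_rank_invariance_and_complement(self, raw_scores, data):
        labels = data.draw(st.lists(st.booleans(), min_size=len(raw_scores),
                                    max_size=len(raw_scores)))
        if all(labels) or not any(labels):
            return
        s = np.asarray(raw_scores, dtype=float) / 1000.0  # coarse grid: the
        # monotone transform below cannot collapse distinct values
        a = auc(s, labels).auc
        assert auc(np.exp(s / 3) * 2 + 1, labels).auc == pytest.approx(a, abs=1e-12)
        if len(np.unique(s)) == len(s):                    # tie-free
            assert auc(-s, labels).auc == pytest.approx(1 - a, abs=1e-12)

    def test_delong_matches_independent_reference(self):
        """AUC, DeLong variance/CI and the paired test agree with values from
        an independent reference implementation (pROC's DeLong routines) on a
        frozen instance."""
        rng = np.random.default_rng(20240917)
        n = 40
        y = np.array([True] * 15 + [False] * 25)
        a = rng.normal(0, 1, n) + 0.8 * y
        b = 0.6 * a + rng.normal(0, 1, n) * 0.8 + 0.3 * y
        ra = auc(a, y)
        assert ra.auc == pytest.approx(0.709333333333, abs=1e-10)
        assert ra.variance == pytest.approx(8.304169312169e-03, rel=1e-9)
        assert ra.ci_low == pytest.approx(0.530727273938, abs=1e-10)
        assert ra.ci_high == pytest.approx(0.887939392729, abs=1e-10)
        cmp_ = compare_auc_paired(a, b, y)
        assert cmp_.p_value == pytest.approx(0.105285430767, abs=1e-10)

    def test_ci_truncated_to_unit_interval(self):
        res = auc([1, 2, 3, 4], [0, 0, 1, 1])
        assert 0.0 <= res.ci_low <= res.ci_high <= 1.0

    def test_negative_orientation_warns_not_flips(self):
        with pytest.warns(UserWarning, match="negatively oriented"):
            res = auc([3, 2, 1, 0], [0, 0, 1, 1])
        assert res.auc == 0.0


class TestPairedComparison:
    def test_identical_scores_give_zero_difference_p_one(self):
        s = np.arange(20.0)
        y = np.r_[np.ones(8), np.zeros(12)].astype(bool)
        cmp_ = compare_auc_paired(s, s, y)
        assert cmp_.difference == 0.0 and cmp_.p_value == 1.0

    def test_monotone_transform_gives_p_one(self):
        rng = np.random.default_rng(4)
        s = rng.normal(size=50)
        y = rng.random(50) < 0.4
        cmp_ = compare_auc_paired(s, np.exp(s), y)
        assert cmp_.difference == pytest.approx(0.0, abs=1e-12)
        assert cmp_.p_value == 1.0

    def test_bootstrap_agrees_with_delong_on_moderate_instance(self):
        rng = np.random.default_rng(5)
        n = 150
        y = rng.random(n) < 0.4
        base = rng.normal(size=n) + 0.7 * y
        a = base + rng.normal(size=n) * 0.5
        b = base + rng.normal(size=n) * 0.5
        p_d = compare_auc_paired(a, b, y).p_value
        p_b = compare_auc_paired(a, b, y, method="bootstrap", seed=0).p_value
        assert abs(p_d - p_b) < 0.1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ConfigError):
            compare_auc_paired([1.0, 2.0, 3.0], [1.0, 2.0], [1, 0, 1])


class TestOperatingPoints:
    def test_perfect_classifier_keeps_full_specificity(self):
        c = roc_curve([4, 5, 1, 2, 3], [1, 1, 0, 0, 0])
        op = spec_at_sensitivity(c, 0.90)
        assert op.achieved_sensitivity == 1.0 and op.specificity == 1.0

    @pytest.mark.filterwarnings("ignore:AUC")
    def test_null_scores_give_complementary_specificity(self):
        rng = np.random.default_rng(6)
        s = rng.normal(size=10_000)
        y = rng.random(10_000) < 0.3
        op = spec_at_sensitivity(roc_curve(s, y), 0.90)
        assert op.specificity == pytest.approx(0.10, abs=0.02)

    def test_step_convention_overshoots_target_slightly(self):
        rng = np.random.default_rng(7)
        s = rng.normal(size=500)
        y = rng.random(500) < 0.4
        op = spec_at_sensitivity(roc_curve(s, y), 0.90)
        assert op.achieved_sensitivity >= 0.90
        # largest threshold satisfying the constraint: the next-larger
        # threshold must fall below the target sensitivity
        c = roc_curve(s, y)
        idx = np.nonzero(c.thresholds == op.threshold)[0][0]
        assert c.sensitivity[idx - 1] < 0.90

    def test_interpolation_hits_target_exactly(self):
        c = roc_curve([0.9, 0.8, 0.7, 0.6, 0.5, 0.4], [1, 1, 1, 0, 0, 0])
        op = spec_at_sensitivity(c, 0.5, interpolate=True)
        assert op.achieved_sensitivity == pytest.approx(0.5)

    def test_unreachable_target_rejected(self):
        c = roc_curve([1, 2], [0, 1])
        with pytest.raises(ConfigError):
            spec_at_sensitivity(c, 1.5)

    def test_lr_invariant_holds_bit_exactly(self):
        rng = np.random.default_rng(8)
        s = rng.normal(size=300)
        y = rng.random(300) < 0.25
        for target in (0.5, 0.8, 0.9, 0.95):
            op = spec_at_sensitivity(roc_curve(s, y), target)
            assert op.likelihood_ratio == op.achieved_sensitivity / (1 - op.specificity)


class TestLikelihoodRatio:
    @pytest.mark.parametrize("sens, spec, lr2dp", [
        (0.90, 0.142, 1.05),
        (0.90, 0.168, 1.08),
        (0.90, 0.058, 0.96),
        (0.90, 0.133, 1.04),
        (0.5, 0.5, 1.0),
    ])
    def test_published_operating_points(self, sens, spec, lr2dp):
        assert round(likelihood_ratio(sens, spec), 2) == lr2dp

    def test_perfect_specificity_flags_infinite_lr(self):
        lr = likelihood_ratio(0.8, 1.0)
        assert math.isinf(lr) and lr > 0

    def test_posterior_odds(self):
        # prior odds from 21.2% prevalence: 0.212/0.788
        prior = 0.212 / 0.788
        assert posterior_odds(prior, 1.05) == pytest.approx(0.282, abs=5e-4)
        assert posterior_odds(0.7, 1.0) == 0.7
        with pytest.raises(ConfigError):
            posterior_odds(-1.0, 1.0)

    def test_with_prior_odds_attaches_posterior(self):
        c = roc_curve([4, 5, 1, 2, 3.0], [1, 1, 0, 0, 0])
        op = with_prior_odds(spec_at_sensitivity(c, 0.9), prior_odds=0.25)
        assert op.posterior_odds == op.prior_odds * op.likelihood_ratio
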