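"""Jackknife distributions, the three uncertainty estimators, dominance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stavarsel import (
    JackknifeDistribution,
    RelaxedLogistic,
    UncertaintyConfig,
    bootstrap_bounds,
    conservative_bounds,
    jackknife_prediction_distribution,
    naive_normal_bounds,
)
from stavarsel._glm import sigmoid


def _records(y, p):
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(len(y))],
            "true_label": np.asarray(y, dtype=int),
            "point_probability": np.asarray(p, dtype=float),
        }
    )


class TestJackknife:
    def test_intercept_only_support_enumerates_exactly(self):
        """Cohort of 20 with 7 positives, intercept-only model: deleting a
        positive or a negative training sample gives exactly two distinct
        prevalences over the n-2 = 18 remaining samples."""
        y = np.r_[np.ones(7), np.zeros(13)].astype(int)
        held_out = 19  # a negative sample
        tr = np.arange(20) != held_out
        dist = jackknife_prediction_distribution(
            np.empty((19, 0)), y[tr], np.empty(0), sample_id="s19"
        )
        # training has 7 positives, 12 negatives; each deletion leaves 18
        assert set(np.round(dist.probabilities, 12)) == {
            round(6 / 18, 12),
            round(7 / 18, 12),
        }
        assert dist.n_iterations == 19
        assert dist.ci_low == pytest.approx(6 / 18)
        assert dist.ci_high == pytest.approx(7 / 18)
        assert dist.ci_low <= dist.mean <= dist.ci_high

    def test_monte_carlo_matches_exhaustive_bounds(self, rng):
        """MC with many draws and exhaustive enumeration share the same
        support, hence identical order-statistic CI bounds."""
        n = 13
        X = rng.normal(size=(n, 2))
        y = np.r_[np.zeros(6), np.ones(7)].astype(int)
        X[y == 1] += 1.0
        x_held = rng.normal(size=2)
        exhaustive = jackknife_prediction_distribution(
            X, y, x_held, config=UncertaintyConfig(exhaustive_max_n=60)
        )
        mc = jackknife_prediction_distribution(
            X,
            y,
            x_held,
            config=UncertaintyConfig(exhaustive_max_n=5, jackknife_iterations=5000),
            seed=42,
        )
        assert mc.mode == "monte_carlo" and exhaustive.mode == "exhaustive"
        assert mc.ci_low == exhaustive.ci_low
        assert mc.ci_high == exhaustive.ci_high
        assert set(mc.probabilities) <= set(exhaustive.probabilities)

    def test_fixed_distribution_zero_width(self):
        """A model whose refits never change gives a zero-width CI."""
        dist = JackknifeDistribution.from_probabilities("s", np.full(50, 0.73), 0.95, "exhaustive")
        assert dist.ci_low == dist.ci_high == 0.73
        assert dist.mean == pytest.approx(0.73)

    def test_deletions_losing_a_class_are_excluded(self):
        y = np.r_[np.ones(1), np.zeros(11)].astype(int)  # single positive
        dist = jackknife_prediction_distribution(np.empty((12, 0)), y, np.empty(0))
        # the deletion removing the lone positive is invalid: 11 supports
        assert dist.n_iterations == 11
        np.testing.assert_allclose(dist.probabilities, 1 / 11)

    def test_ci_nested_in_level(self, rng):
        n = 14
        X = rng.normal(size=(n, 1))
        y = np.r_[np.zeros(7), np.ones(7)].astype(int)
        X[y == 1] += 1.0
        x_held = np.array([0.2])
        d95 = jackknife_prediction_distribution(X, y, x_held, config=UncertaintyConfig(ci_level=0.95))
        d99 = jackknife_prediction_distribution(X, y, x_held, config=UncertaintyConfig(ci_level=0.99))
        assert d99.ci_low <= d95.ci_low
        assert d99.ci_high >= d95.ci_high

    def test_refits_differing_imply_positive_width(self, rng):
        """Whenever deletion refits disagree, the CI has positive width."""
        n = 16
        X = rng.normal(size=(n, 1))
        y = (rng.random(n) < sigmoid(2 * X[:, 0])).astype(int)
        if y.sum() in (0, n):
            pytest.skip("degenerate draw")
        dist = jackknife_prediction_distribution(X, y, np.array([0.1]))
        if np.unique(dist.probabilities).size > 1:
            assert dist.ci_high > dist.ci_low

    def test_too_small_training_set_is_error(self):
        with pytest.raises(ValueError, match=">= 6"):
            jackknife_prediction_distribution(
                np.empty((4, 0)), np.array([0, 0, 1, 1]), np.empty(0)
            )


class TestNaive:
    def test_wald_closed_form(self):
        """spec = 0.8 with 20 negatives: lower bound 0.8 - 1.96*sqrt(.16/20)."""
        y = np.r_[np.zeros(20), np.ones(5)]
        p = np.r_[np.full(16, 0.1), np.full(4, 0.9), np.full(5, 0.9)]
        s = naive_normal_bounds(_records(y, p))
        z = stats.norm.ppf(0.975)
        assert z == pytest.approx(1.959964, abs=1e-6)
        assert s.specificity == pytest.approx(0.8)
        assert s.specificity_lower == pytest.approx(0.8 - z * np.sqrt(0.8 * 0.2 / 20))
        assert s.specificity_lower == pytest.approx(0.625, abs=0.005)

    def test_degenerate_at_boundary(self):
        y = np.r_[np.zeros(13), np.ones(4)]
        p = np.r_[np.full(13, 0.1), np.full(4, 0.9)]
        s = naive_normal_bounds(_records(y, p))
        assert s.specificity_lower == 1.0  # p_hat(1-p_hat) = 0: no width


class TestBootstrap:
    def test_seeded_reproducibility(self, rng):
        y = np.r_[np.zeros(10), np.ones(10)]
        p = rng.random(20)
        a = bootstrap_bounds(_records(y, p), UncertaintyConfig(bootstrap_B=500), seed=3)
        b = bootstrap_bounds(_records(y, p), UncertaintyConfig(bootstrap_B=500), seed=3)
        assert a.to_dict() == b.to_dict()

    def test_perfect_separation_zero_width_warning(self):
        y = np.r_[np.zeros(8), np.ones(8)]
        p = np.r_[np.full(8, 0.1), np.full(8, 0.9)]
        with pytest.warns(UserWarning, match="perfect separation"):
            s = bootstrap_bounds(_records(y, p), UncertaintyConfig(bootstrap_B=200), seed=0)
        assert s.specificity_lower == s.specificity == 1.0
        assert s.sensitivity_lower == s.sensitivity == 1.0

    def test_lower_bound_on_tenths_grid(self):
        """10 negatives: every resampled specificity is a multiple of 0.1,
        and order-statistic percentiles stay on that grid."""
        y = np.r_[np.zeros(10), np.ones(10)]
        p = np.r_[np.full(9, 0.1), [0.9], np.full(10, 0.9)]  # one negative wrong
        s = bootstrap_bounds(_records(y, p), UncertaintyConfig(bootstrap_B=2000), seed=1)
        assert s.specificity == pytest.approx(0.9)
        assert s.specificity_lower <= 0.9
        assert (round(s.specificity_lower * 10, 6)).is_integer()


class TestConservative:
    def _dist(self, sid, lo, hi, mean=None):
        mean = mean if mean is not None else (lo + hi) / 2
        return JackknifeDistribution(sid, np.array([lo, mean, hi]), lo, hi, mean, 3)

    def test_worst_case_rule(self):
        dists = [
            self._dist("n1", 0.10, 0.60),  # negative, CI crosses 0.5: misclassified
            self._dist("n2", 0.05, 0.20),  # negative, safely below
            self._dist("p1", 0.55, 0.90),  # positive, safely above
            self._dist("p2", 0.30, 0.80, mean=0.7),  # positive, CI crosses: misclassified
        ]
        labels = [0, 0, 1, 1]
        s = conservative_bounds(dists, labels)
        assert s.specificity_lower == pytest.approx(0.5)
        assert s.sensitivity_lower == pytest.approx(0.5)
        # point summary from means: n1 mean 0.35 < 0.5 -> correct
        assert s.specificity == pytest.approx(1.0)
        assert s.sensitivity == pytest.approx(1.0)

    def test_zero_width_cis_reduce_to_point(self):
        dists = [self._dist("a", 0.2, 0.2), self._dist("b", 0.1, 0.1), self._dist("c", 0.9, 0.9)]
        s = conservative_bounds(dists, [0, 0, 1])
        assert s.specificity_lower == s.specificity == 1.0
        assert s.sensitivity_lower == s.sensitivity == 1.0
        assert s.balanced_accuracy_lower == s.balanced_accuracy

    def test_dominance_for_random_fixtures(self, rng):
        for _ in range(20):
            n = 12
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            lo = rng.random(n) * 0.6
            hi = lo + rng.random(n) * (1 - lo)
            dists = [self._dist(f"s{i}", lo[i], hi[i], rng.uniform(lo[i], hi[i])) for i in range(n)]
            s = conservative_bounds(dists, labels)
            assert s.specificity_lower <= s.specificity
            assert s.sensitivity_lower <= s.sensitivity
            assert s.balanced_accuracy_lower <= s.balanced_accuracy

    def test_missing_distribution_is_error(self):
        with pytest.raises(ValueError, match="one jackknife distribution per sample"):
            conservative_bounds([self._dist("a", 0.1, 0.2)], [0, 1])
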