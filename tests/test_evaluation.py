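"""Evaluation layer: AUC, thresholds, DeLong, calibration, sparsification."""

import numpy as np
import pytest

from riskuq import (
    accuracy,
    adaptive_bins,
    auc,
    bootstrap_ci,
    delong_test,
    prediction_ace,
    sparsification,
    uncertainty_accuracy_calibration,
    youden_threshold,
)


def pair_counting_auc(y, s):
    """O(n^2) oracle: concordant pairs (ties half) over all pos/neg pairs."""
    y = np.asarray(y)
    s = np.asarray(s)
    pos = s[y == 1][:, None]
    neg = s[y == 0][None, :]
    return ((pos > neg).sum() + 0.5 * (pos == neg).sum()) / (pos.size * neg.size)


class TestAUC:
    def test_worked_example(self):
        assert auc([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8]) == pytest.approx(0.75)

    def test_all_ties_half(self):
        assert auc([0, 1, 0, 1], [0.3, 0.3, 0.3, 0.3]) == pytest.approx(0.5)

    def test_perfect_separation(self):
        assert auc([0, 0, 1, 1], [0.0, 0.0, 1.0, 1.0]) == 1.0

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auc([1, 1, 1], [0.1, 0.2, 0.3])

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(200):
            n = rng.integers(4, 201)
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            s = np.round(rng.uniform(size=n), 2)  # rounding forces ties
            assert auc(y, s) == pytest.approx(pair_counting_auc(y, s), abs=1e-12)

    def test_patient_reordering_invariant(self, rng):
        y = rng.integers(0, 2, 100)
        y[:2] = [0, 1]
        s = rng.uniform(size=100)
        perm = rng.permutation(100)
        assert auc(y, s) == pytest.approx(auc(y[perm], s[perm]), abs=1e-12)


class TestAccuracy:
    @pytest.mark.parametrize("y,p,expected", [
        ([0, 1, 1, 0], [0.0, 1.0, 1.0, 0.0], 1.0),
        ([0, 1, 1, 0], [1.0, 0.0, 0.0, 1.0], 0.0),
        ([0, 1, 1, 0], [0.4, 0.6, 0.4, 0.6], 0.5),
    ])
    def test_examples(self, y, p, expected):
        assert accuracy(y, p, 0.5) == expected

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            accuracy([0, 1], [0.2, 0.8], 0.0)


class TestYouden:
    def test_perfect_separation_gap_midpoint(self):
        t = youden_threshold([0, 0, 1, 1], [0.1, 0.2, 0.7, 0.9])
        assert 0.2 < t <= 0.7
        assert t == pytest.approx(0.45)
        y = np.array([0, 0, 1, 1])
        p = np.array([0.1, 0.2, 0.7, 0.9])
        sens = np.mean(p[y == 1] >= t)
        spec = np.mean(p[y == 0] < t)
        assert sens + spec - 1 == 1.0

    def test_random_scores_small_J(self, rng):
        y = rng.integers(0, 2, 3000)
        p = rng.uniform(size=3000)
        t = youden_threshold(y, p)
        sens = np.mean(p[y == 1] >= t)
        spec = np.mean(p[y == 0] < t)
        assert sens + spec - 1 < 0.12


class TestDeLong:
    def test_identical_scores_p_one(self, rng):
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        s = rng.uniform(size=50)
        a, b, p = delong_test(y, s, s)
        assert a == b
        assert p == 1.0

    def test_auc_matches_evaluation_auc(self, rng):
        y = rng.integers(0, 2, 120)
        y[:2] = [0, 1]
        sa, sb = rng.uniform(size=120), rng.uniform(size=120)
        a, b, _ = delong_test(y, sa, sb)
        assert a == pytest.approx(auc(y, sa), abs=1e-12)
        assert b == pytest.approx(auc(y, sb), abs=1e-12)

    def test_informative_vs_noise_rejects_with_permutation_oracle(self, rng):
        n = 200
        y = rng.integers(0, 2, n)
        y[:2] = [0, 1]
        informative = y + rng.normal(0, 0.6, n)
        noise = rng.uniform(size=n)
        _, _, p = delong_test(y, informative, noise)
        assert p < 0.01
        # permutation oracle: swap the paired scores per patient under the
        # null of exchangeable predictors; both must reject
        observed = abs(auc(y, informative) - auc(y, noise))
        count = 0
        B = 500
        for i in range(B):
            swap = rng.uniform(size=n) < 0.5
            pa = np.where(swap, noise, informative)
            pb = np.where(swap, informative, noise)
            if abs(auc(y, pa) - auc(y, pb)) >= observed:
                count += 1
        assert (count + 1) / (B + 1) < 0.01

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            delong_test([0, 1, 1], [0.1, 0.9, 0.5], [0.2, 0.8])


class TestAdaptiveBins:
    def test_exact_division(self, rng):
        bins = adaptive_bins(rng.uniform(size=100), 25)
        sizes = np.bincount(bins)
        assert list(sizes) == [25, 25, 25, 25]

    def test_remainder_distribution(self, rng):
        bins = adaptive_bins(rng.uniform(size=110), 25)
        sizes = sorted(np.bincount(bins), reverse=True)
        assert sizes == [28, 28, 27, 27]

    def test_too_few_values_raises(self, rng):
        with pytest.raises(ValueError):
            adaptive_bins(rng.uniform(size=24), 25)

    def test_bins_ordered_by_value_and_floor_respected(self, rng):
        v = np.round(rng.uniform(size=203), 1)  # heavy ties
        bins = adaptive_bins(v, 25)
        sizes = np.bincount(bins)
        assert sizes.sum() == 203
        assert np.all(sizes >= 25)
        # every value in bin i is <= every value in bin i+1
        for i in range(bins.max()):
            assert v[bins == i].max() <= v[bins == i + 1].min()

    def test_ties_stay_in_one_bin(self):
        v = np.array([0.1] * 30 + [0.2] * 10 + [0.3] * 20)
        bins = adaptive_bins(v, 25)
        for val in (0.1, 0.2, 0.3):
            assert len(np.unique(bins[v == val])) == 1


class TestPredictionACE:
    def test_constant_event_rate_predictor_calibrated(self, rng):
        y = rng.integers(0, 2, 5000)
        p = np.full(5000, y.mean())
        assert prediction_ace(y, p, 25).ace < 0.02

    def test_true_probability_predictor_low_ace(self, rng):
        p = rng.uniform(0.05, 0.95, 10_000)
        y = (rng.uniform(size=10_000) < p).astype(int)
        assert prediction_ace(y, p, 25).ace < 0.03

    def test_anticalibrated_predictor_high_ace(self, rng):
        p = rng.uniform(0.05, 0.95, 10_000)
        y = (rng.uniform(size=10_000) < p).astype(int)
        assert prediction_ace(y, 1.0 - p, 25).ace > 0.3

    def test_ace_shrinks_with_n(self, rng):
        aces = []
        for n in (1000, 10_000):
            p = rng.uniform(0.05, 0.95, n)
            y = (rng.uniform(size=n) < p).astype(int)
            aces.append(prediction_ace(y, p, 25).ace)
        assert aces[1] < aces[0]


class TestUncertaintyAccuracyCalibration:
    def test_oracle_uncertainty_monotone_bins(self, rng):
        n = 400
        y = rng.integers(0, 2, n)
        p = rng.uniform(size=n)
        correct = ((p >= 0.5).astype(int) == y)
        u = np.where(correct, 0.0, 1.0)
        res = uncertainty_accuracy_calibration(y, p, u, 0.5, 25)
        acc = res.bin_stats.sort_values("certainty")["accuracy"].to_numpy()
        assert np.all(np.diff(acc) >= 0)
        assert acc[-1] == 1.0

    def test_independent_uncertainty_flat_curve(self, rng):
        n = 4000
        y = rng.integers(0, 2, n)
        p = np.where(y == 1, rng.uniform(0.3, 1.0, n), rng.uniform(0.0, 0.7, n))
        u = rng.uniform(size=n)  # unrelated to correctness
        res = uncertainty_accuracy_calibration(y, p, u, 0.5, 25)
        overall = np.mean((p >= 0.5).astype(int) == y)
        assert np.max(np.abs(res.bin_stats["accuracy"] - overall)) < 0.1

    def test_unnormalised_uncertainties_rejected(self, rng):
        with pytest.raises(ValueError, match="normalised"):
            uncertainty_accuracy_calibration([0, 1] * 20, [0.5] * 40,
                                             np.linspace(0, 2, 40), 0.5, 10)


class TestSparsification:
    def _cohort(self, rng, n=120):
        y = rng.integers(0, 2, n)
        y[:2] = [0, 1]
        p = np.clip(y * 0.6 + rng.normal(0.2, 0.25, n), 0, 1)
        return y, p

    def test_oracle_uncertainty_accuracy_monotone(self, rng):
        y, p = self._cohort(rng)
        u = (np.abs((p >= 0.5).astype(int) - y)).astype(float)  # 1 iff wrong
        curve = sparsification(y, p, u, metric="accuracy")
        assert len(curve.values) == len(y) // 2 + 1
        assert np.all(np.diff(curve.values) >= -1e-12)

    def test_anti_oracle_accuracy_nonincreasing(self, rng):
        y, p = self._cohort(rng)
        u = 1.0 - (np.abs((p >= 0.5).astype(int) - y)).astype(float)  # certain = wrong
        curve = sparsification(y, p, u, metric="accuracy")
        assert np.all(np.diff(curve.values) <= 1e-12)

    def test_constant_uncertainty_matches_random_removal(self, rng):
        y, p = self._cohort(rng, n=200)
        curve = sparsification(y, p, np.zeros(200), metric="accuracy")
        # permutation oracle: distribution of the curve under random orders
        checkpoints = [50, 100]
        draws = {c: [] for c in checkpoints}
        for _ in range(300):
            order = rng.permutation(200)
            for c in checkpoints:
                keep = order[c:]
                draws[c].append(np.mean((p[keep] >= 0.5).astype(int) == y[keep]))
        for c in checkpoints:
            mu, sd = np.mean(draws[c]), np.std(draws[c])
            assert abs(curve.values[c] - mu) < 4 * sd + 1e-9

    def test_auc_missing_after_class_lost(self):
        y = np.array([1, 0, 0, 0, 0, 0])
        p = np.array([0.9, 0.1, 0.2, 0.3, 0.1, 0.2])
        u = np.array([1.0, 0.5, 0.4, 0.3, 0.2, 0.1])  # positive removed first
        curve = sparsification(y, p, u, metric="auc")
        assert not np.isnan(curve.values[0])
        assert np.all(np.isnan(curve.values[1:]))

    def test_fraction_grid_strictly_increasing(self, rng):
        y, p = self._cohort(rng)
        curve = sparsification(y, p, rng.uniform(size=len(y)), metric="auc")
        assert np.all(np.diff(curve.fractions_removed) > 0)


class TestBootstrapCI:
    def test_degenerate_metric_zero_width(self, rng):
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        lo, hi = bootstrap_ci(lambda yy, ss: 0.7, y, rng.uniform(size=60), B=200, seed=1)
        assert lo == hi == 0.7

    def test_interval_contains_point_estimate(self, rng):
        y = rng.integers(0, 2, 300)
        y[:2] = [0, 1]
        s = y + rng.normal(0, 0.8, 300)
        lo, hi = bootstrap_ci(auc, y, s, B=500, seed=2)
        assert lo <= auc(y, s) <= hi

    def test_auc_coverage_near_nominal(self, rng):
        # coverage simulation at n=300: true AUC from a large sample
        big_y = rng.integers(0, 2, 200_000)
        big_s = big_y + rng.normal(0, 1.0, 200_000)
        true_auc = auc(big_y, big_s)
        hits = 0
        reps = 200
        for i in range(reps):
            y = rng.integers(0, 2, 300)
            y[:2] = [0, 1]
            s = y + rng.normal(0, 1.0, 300)
            lo, hi = bootstrap_ci(auc, y, s, B=200, seed=i)
            hits += lo <= true_auc <= hi
        assert 0.89 <= hits / reps <= 0.99
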