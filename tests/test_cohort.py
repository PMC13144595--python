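"""Synthetic cohort generation: prevalence calibration, splits, shift."""

import dataclasses

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import mannwhitneyu

from riskuq import (
    CohortSpec,
    Cohort,
    CovariateShift,
    apply_covariate_shift,
    calibrate_intercept,
    generate_cohort,
    inner_split,
    ntcp_cohort_spec,
    split_cohort,
    tcp_cohort_spec,
)
from riskuq.cohort import _draw_features


def _zero_effect_spec(target, n=100, label_noise=0.0):
    spec = ntcp_cohort_spec(n_patients=n, seed=5, label_noise=label_noise)
    zeros = {ep: np.zeros(len(spec.feature_columns)) for ep in spec.endpoints}
    return dataclasses.replace(
        spec, prevalences={ep: target for ep in spec.endpoints}, effect_sizes=zeros
    )


class TestCalibrateIntercept:
    def test_symmetric_logistic(self):
        assert calibrate_intercept(_zero_effect_spec(0.5), "dysphagia") == pytest.approx(0.0)

    def test_closed_form_logit(self):
        b0 = calibrate_intercept(_zero_effect_spec(0.22), "dysphagia")
        assert b0 == pytest.approx(np.log(0.22 / 0.78), abs=1e-9)

    def test_monte_carlo_oracle_nonzero_effects(self):
        # independent large-sample oracle for the marginal event rate
        spec = dataclasses.replace(ntcp_cohort_spec(seed=7),
                                   prevalences={"dysphagia": 0.42, "xerostomia": 0.42})
        b0 = calibrate_intercept(spec, "xerostomia")
        rng = np.random.default_rng(987654)
        X = _draw_features(spec, 1_000_000, rng).to_numpy()
        prevalence = expit(b0 + X @ spec.effects("xerostomia")).mean()
        assert prevalence == pytest.approx(0.42, abs=0.005)

    def test_label_noise_accounted_for(self):
        spec = _zero_effect_spec(0.22, n=40_000, label_noise=0.1)
        cohort = generate_cohort(spec)
        assert cohort.prevalence("dysphagia") == pytest.approx(0.22, abs=0.01)

    def test_unreachable_prevalence_raises(self):
        with pytest.raises(ValueError, match="unreachable"):
            calibrate_intercept(_zero_effect_spec(0.05, label_noise=0.2), "dysphagia")


class TestGenerateCohort:
    def test_spec_validation(self):
        with pytest.raises(ValueError):
            CohortSpec(n_patients=1, prevalences={"a": 0.2})
        with pytest.raises(ValueError):
            CohortSpec(n_patients=10, prevalences={"a": 1.5})
        with pytest.raises(ValueError):
            CohortSpec(n_patients=10, prevalences={"a": 0.2}, label_noise=0.5)

    def test_near_certain_endpoint(self):
        spec = _zero_effect_spec(0.999, n=300)
        cohort = generate_cohort(spec)
        assert cohort.labels["dysphagia"].mean() > 0.98

    def test_deterministic_given_seed(self):
        spec = ntcp_cohort_spec(n_patients=200, seed=3)
        a, b = generate_cohort(spec), generate_cohort(spec)
        assert np.array_equal(a.feature_matrix, b.feature_matrix)
        assert a.labels.equals(b.labels)
        assert a.true_prob.equals(b.true_prob)

    def test_true_prob_matches_linear_model(self):
        cohort = generate_cohort(ntcp_cohort_spec(n_patients=100, seed=3))
        b0, beta = cohort.linear_models["dysphagia"]
        expected = expit(b0 + cohort.feature_matrix @ beta)
        np.testing.assert_allclose(cohort.true_prob["dysphagia"], expected)

    def test_true_prob_is_bayes_optimal(self, ntcp_splits, dysphagia_model):
        # no classifier can out-rank the generative probabilities
        from riskuq import auc

        ival = ntcp_splits["ival"]
        y = ival.y("dysphagia")
        bayes = auc(y, ival.true_prob["dysphagia"])
        fitted = auc(y, dysphagia_model.predict(ival.feature_matrix))
        assert fitted <= bayes + 0.02

    def test_csv_roundtrip(self, tmp_path):
        cohort = generate_cohort(ntcp_cohort_spec(n_patients=50, seed=8))
        path = tmp_path / "cohort.csv"
        cohort.to_csv(path)
        back = Cohort.from_csv(path)
        np.testing.assert_allclose(back.feature_matrix, cohort.feature_matrix)
        assert back.labels.equals(cohort.labels)
        assert list(back.split) == list(cohort.split)

    def test_spec_yaml_roundtrip(self, tmp_path):
        spec = tcp_cohort_spec(seed=4, label_noise=0.05)
        spec.to_yaml(tmp_path / "spec.yaml")
        back = CohortSpec.from_yaml(tmp_path / "spec.yaml")
        assert back.prevalences == spec.prevalences
        assert back.label_noise == spec.label_noise
        assert back.seed == spec.seed


class TestSplits:
    @pytest.mark.parametrize(
        "n,fraction,expected_dev,expected_val",
        [(1205, 0.80, 964, 241), (340, 0.75, 255, 85), (10, 0.8, 8, 2)],
    )
    def test_split_sizes_round_half_even(self, n, fraction, expected_dev, expected_val):
        cohort = generate_cohort(ntcp_cohort_spec(n_patients=n, seed=1))
        dev, val = split_cohort(cohort, fraction, seed=2)
        assert (dev.n, val.n) == (expected_dev, expected_val)

    @pytest.mark.parametrize("n,fraction,expected", [(964, 0.8, 771), (100, 0.8, 80)])
    def test_inner_split_sizes(self, n, fraction, expected):
        cohort = generate_cohort(ntcp_cohort_spec(n_patients=n, seed=1))
        train, valid = inner_split(cohort, fraction, seed=3)
        assert train.n == expected
        assert valid.n == n - expected

    def test_split_disjoint_exhaustive_reproducible(self):
        cohort = generate_cohort(ntcp_cohort_spec(n_patients=101, seed=1))
        d1, v1 = split_cohort(cohort, 0.8, seed=9)
        d2, v2 = split_cohort(cohort, 0.8, seed=9)
        assert np.array_equal(d1.patient_ids, d2.patient_ids)
        ids = np.concatenate([d1.patient_ids, v1.patient_ids])
        assert sorted(ids) == sorted(cohort.patient_ids)
        assert set(d1.split) == {"train"}
        assert set(v1.split) == {"independent_validation"}

    def test_degenerate_fraction_raises(self):
        cohort = generate_cohort(ntcp_cohort_spec(n_patients=10, seed=1))
        with pytest.raises(ValueError):
            split_cohort(cohort, 0.01, seed=0)


class TestCovariateShift:
    def test_zero_shift_is_identity(self):
        cohort = generate_cohort(ntcp_cohort_spec(n_patients=300, seed=6))
        shifted = apply_covariate_shift(cohort, CovariateShift())
        assert shifted.features.equals(cohort.features)
        assert shifted.labels.equals(cohort.labels)
        assert shifted.true_prob.equals(cohort.true_prob)

    def test_mean_offset(self):
        cohort = generate_cohort(ntcp_cohort_spec(n_patients=4000, seed=6))
        shifted = apply_covariate_shift(cohort, CovariateShift(loc=3.0))
        for col in cohort.continuous_columns:
            delta = shifted.features[col].mean() - cohort.features[col].mean()
            assert delta == pytest.approx(3.0, abs=1e-9)

    def test_shift_inflates_ensemble_variance(self, ntcp_splits, fast_config):
        # epistemic uncertainty must rise out of distribution
        from riskuq import ensemble_predict, sample_variance, train_ensemble

        members = train_ensemble(
            ntcp_splits["train"], ntcp_splits["valid"], "dysphagia", M=5,
            base_config=fast_config,
        )
        probe = generate_cohort(ntcp_cohort_spec(n_patients=500, seed=77))
        shifted = apply_covariate_shift(probe, CovariateShift(loc=3.0))
        var_in = sample_variance(ensemble_predict(members, probe.feature_matrix)).values
        var_out = sample_variance(ensemble_predict(members, shifted.feature_matrix)).values
        stat = mannwhitneyu(var_out, var_in, alternative="greater")
        assert stat.pvalue < 0.05
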