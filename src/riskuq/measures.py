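"""Scalar uncertainty measures over prediction sample sets.

Three measures reduce a patient's T sampled probabilities to one number:

* predictive (binary) entropy of the mean prediction, H(p_bar), in bits —
  total uncertainty, bounded in [0, 1];
* variance of the samples (population form, divide by T) — dispersion of
  the predicted probabilities, bounded by p_bar(1 - p_bar) <= 0.25;
* mutual information, MI = H(p_bar) - mean_t H(p_t) — the epistemic
  component: information the samples carry about the model parameters.

Variance and MI live on measure-specific scales and are min-max normalised
against a reference cohort before calibration analyses; entropy is already
in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import xlogy

from riskuq.methods import PredictionSamples

MEASURES = ("entropy", "variance", "mutual_information")

_MI_NEG_TOL = 1e-12  # numerical tolerance before clamping MI at zero


def binary_entropy(p: np.ndarray | float) -> np.ndarray | float:
    """Binary entropy H(p) = -p log2 p - (1-p) log2 (1-p), in bits.

    0*log(0) is taken as 0, so H(0) = H(1) = 0 and H(0.5) = 1 exactly.
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr < 0) or np.any(p_arr > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    h = -(xlogy(p_arr, p_arr) + xlogy(1.0 - p_arr, 1.0 - p_arr)) / np.log(2.0)
    return float(h) if np.isscalar(p) else h


@dataclass
class UncertaintyScores:
    """Per-patient scalar uncertainties for one (method, measure) pair."""

    patient_ids: np.ndarray
    values: np.ndarray
    measure: str
    method: str = ""
    normalised: bool = False
    norm_bounds: tuple[float, float] | None = None
    norm_reference: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.patient_ids) != len(self.values):
            raise ValueError("patient_ids / values length mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "patient_id": self.patient_ids,
            "method": self.method,
            "measure": self.measure,
            "value": self.values,
            "normalised": self.normalised,
        })


def _require_T(samples: PredictionSamples, minimum: int) -> None:
    if samples.n_samples < minimum:
        raise ValueError(f"measure requires at least {minimum} samples per patient")


def predictive_entropy(samples: PredictionSamples) -> UncertaintyScores:
    """Binary entropy of the mean prediction (total uncertainty, bits)."""
    _require_T(samples, 1)
    return UncertaintyScores(
        patient_ids=samples.patient_ids,
        values=binary_entropy(samples.mean_prediction),
        measure="entropy",
        method=samples.method,
    )


def sample_variance(samples: PredictionSamples) -> UncertaintyScores:
    """Population variance (1/T) of each patient's sample row."""
    _require_T(samples, 2)
    values = samples.samples.var(axis=1, ddof=0)
    # exactly-constant rows must give exactly zero, not float dust
    values[np.ptp(samples.samples, axis=1) == 0.0] = 0.0
    return UncertaintyScores(
        patient_ids=samples.patient_ids,
        values=values,
        measure="variance",
        method=samples.method,
    )


def mutual_information(samples: PredictionSamples) -> UncertaintyScores:
    """MI = H(mean prediction) - mean per-sample entropy (epistemic, bits).

    Non-negative by Jensen's inequality; tiny negative values from floating
    point are clamped to zero within a 1e-12 tolerance.
    """
    _require_T(samples, 2)
    total = binary_entropy(samples.mean_prediction)
    expected = binary_entropy(samples.samples).mean(axis=1)
    mi = total - expected
    mi = np.where(mi > -_MI_NEG_TOL, np.maximum(mi, 0.0), mi)
    if np.any(mi < 0):
        # beyond numerical tolerance: clamp but keep the operation total
        warnings.warn("mutual information below -1e-12 before clamping")
        mi = np.maximum(mi, 0.0)
    return UncertaintyScores(
        patient_ids=samples.patient_ids,
        values=mi,
        measure="mutual_information",
        method=samples.method,
    )


def compute_measure(samples: PredictionSamples, measure: str) -> UncertaintyScores:
    """Dispatch one of ``entropy`` / ``variance`` / ``mutual_information``."""
    if measure == "entropy":
        return predictive_entropy(samples)
    if measure == "variance":
        return sample_variance(samples)
    if measure == "mutual_information":
        return mutual_information(samples)
    raise ValueError(f"unknown measure {measure!r}")


def minmax_normalise(
    scores: UncertaintyScores,
    reference: UncertaintyScores | None = None,
    reference_name: str = "independent_validation",
) -> UncertaintyScores:
    """Min-max scale ``scores`` using bounds from ``reference``.

    Default reference is the score set itself (the cohort under evaluation),
    so bounds come from the cohort on which calibration is assessed.  Values
    outside the reference range are clipped to [0, 1].  A degenerate
    (constant) reference maps everything to 0 with a warning.
    """
    ref = reference if reference is not None else scores
    if len(ref.values) == 0:
        raise ValueError("normalisation reference is empty")
    lo = float(np.min(ref.values))
    hi = float(np.max(ref.values))
    if hi <= lo:
        warnings.warn("degenerate min-max reference (constant values); returning zeros")
        vals = np.zeros_like(scores.values)
    else:
        vals = np.clip((scores.values - lo) / (hi - lo), 0.0, 1.0)
    return UncertaintyScores(
        patient_ids=scores.patient_ids,
        values=vals,
        measure=scores.measure,
        method=scores.method,
        normalised=True,
        norm_bounds=(lo, hi),
        norm_reference=reference_name,
    )
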