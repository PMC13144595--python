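"""Discrimination, calibration and sparsification analysis.

Implements the evaluation layer for probabilistic binary risk models:

* AUC (Mann-Whitney form, via scikit-learn) and accuracy at a fixed 0.5 or
  Youden-J threshold;
* the DeLong test for the difference of two correlated AUCs on paired
  predictions (structural-components covariance estimate);
* Adaptive Calibration Error (ACE): equal-frequency bins holding at least
  ``min_per_bin`` patients (default 25), unweighted mean absolute gap
  between per-bin observed event fraction and mean predicted probability;
* the certainty-vs-accuracy variant of ACE, binning on 1 - normalised
  uncertainty against per-bin classification accuracy;
* sparsification: remove patients one at a time in order of descending
  uncertainty, recomputing AUC/accuracy after each removal, down to half
  the cohort — a rising curve means the uncertainty separates reliable
  from unreliable predictions;
* label-stratified percentile bootstrap confidence intervals.

All operations are deterministic; ties are broken by patient order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.metrics import roc_auc_score

from riskuq._rng import derive_rng


def _check_binary(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels, dtype=int).ravel()
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return y


def auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Probability a random positive outranks a random negative (ties 1/2)."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float).ravel()
    if len(s) != len(y):
        raise ValueError("labels and scores differ in length")
    return float(roc_auc_score(y, s))


def accuracy(labels: np.ndarray, probabilities: np.ndarray, threshold: float = 0.5) -> float:
    """Fraction of patients with (probability >= threshold) == label."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    y = np.asarray(labels, dtype=int).ravel()
    p = np.asarray(probabilities, dtype=float).ravel()
    return float(np.mean((p >= threshold).astype(int) == y))


def youden_threshold(labels: np.ndarray, probabilities: np.ndarray) -> float:
    """Cut-point maximising Youden's J = sensitivity + specificity - 1.

    Candidates are the midpoints between consecutive distinct observed
    scores (so perfectly separated classes yield the midpoint of the
    separating gap); ties resolve to the lowest threshold.
    """
    y = _check_binary(labels)
    p = np.asarray(probabilities, dtype=float).ravel()
    distinct = np.unique(p)
    if len(distinct) == 1:
        return float(distinct[0])
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    best_t, best_j = candidates[0], -np.inf
    for t in candidates:
        sens = np.mean(p[y == 1] >= t)
        spec = np.mean(p[y == 0] < t)
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return float(best_t)


def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    z = x[order]
    n = len(x)
    ranks = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j < n and z[j] == z[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n)
    out[order] = ranks
    return out


def delong_test(labels: np.ndarray, scores_a: np.ndarray, scores_b: np.ndarray) -> tuple[float, float, float]:
    """DeLong test for two correlated AUCs on paired predictions.

    Returns ``(auc_a, auc_b, p_value)`` with a two-sided p-value from the
    structural-components covariance estimate of the AUC difference.  A
    degenerate zero-variance difference with equal AUCs yields p = 1.
    """
    y = _check_binary(labels)
    a = np.asarray(scores_a, dtype=float).ravel()
    b = np.asarray(scores_b, dtype=float).ravel()
    if len(a) != len(y) or len(b) != len(y):
        raise ValueError("scores must be paired with labels (same length)")
    pos = y == 1
    m, n = int(pos.sum()), int((~pos).sum())
    aucs = np.empty(2)
    v10 = np.empty((2, m))
    v01 = np.empty((2, n))
    for r, s in enumerate((a, b)):
        tx = _midrank(s[pos])
        ty = _midrank(s[~pos])
        tz = _midrank(s)
        aucs[r] = tz[pos].sum() / (m * n) - (m + 1.0) / (2.0 * n)
        v10[r] = (tz[pos] - tx) / n
        v01[r] = 1.0 - (tz[~pos] - ty) / m
    s10 = np.cov(v10)
    s01 = np.cov(v01)
    cov = s10 / m + s01 / n
    delta = aucs[0] - aucs[1]
    var = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    if var <= 1e-15:
        p = 1.0 if abs(delta) < 1e-12 else 0.0
    else:
        z = delta / np.sqrt(var)
        p = float(2.0 * norm.sf(abs(z)))
    return float(aucs[0]), float(aucs[1]), p


def adaptive_bins(values: np.ndarray, min_per_bin: int = 25, max_bins: int = 15) -> np.ndarray:
    """Equal-frequency bin assignment with every bin >= ``min_per_bin``.

    The number of bins is min(max_bins, floor(n / min_per_bin)) — the usual
    fixed number of adaptive-calibration ranges, reduced on small cohorts so
    every bin keeps at least ``min_per_bin`` patients; counts are
    floor(n / n_bins) with the remainder distributed one-per-bin from the
    lowest-value bin upward.  Tied values are never split across a bin
    boundary (the lower bin absorbs them, so counts may exceed the nominal
    size).  Returns a bin index per input element, ordered by value.
    """
    v = np.asarray(values, dtype=float).ravel()
    n = len(v)
    if n < min_per_bin:
        raise ValueError(f"need at least min_per_bin={min_per_bin} values, got {n}")
    k = min(max_bins, n // min_per_bin)
    base, rem = divmod(n, k)
    sizes = [base + 1] * rem + [base] * (k - rem)
    order = np.argsort(v, kind="mergesort")
    assignment = np.empty(n, dtype=int)
    start = 0
    bin_id = 0
    while start < n:
        nominal = sizes[bin_id] if bin_id < len(sizes) else sizes[-1]
        end = min(start + nominal, n)
        while end < n and v[order[end]] == v[order[end - 1]]:
            end += 1  # ties absorbed into the lower bin
        assignment[order[start:end]] = bin_id
        start = end
        bin_id += 1
    # a short leftover tail (tie absorption consumed its quota) merges left
    last = bin_id - 1
    if last > 0 and int(np.sum(assignment == last)) < min_per_bin:
        assignment[assignment == last] = last - 1
    return assignment


@dataclass
class CalibrationResult:
    """Adaptive-bin calibration summary (prediction or uncertainty variant)."""

    variant: str
    bin_assignments: np.ndarray
    bin_stats: pd.DataFrame
    ace: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ace <= 1.0:
            raise ValueError("ACE must lie in [0, 1]")


def prediction_ace(labels: np.ndarray, probabilities: np.ndarray, min_per_bin: int = 25) -> CalibrationResult:
    """Adaptive Calibration Error of predicted probabilities.

    Bins partition the cohort by predicted probability; ACE is the
    unweighted mean over bins of |observed event fraction - mean predicted
    probability| (mean prediction, not bin midpoint, as the confidence).
    """
    y = np.asarray(labels, dtype=int).ravel()
    p = np.asarray(probabilities, dtype=float).ravel()
    bins = adaptive_bins(p, min_per_bin)
    rows = []
    for bi in range(bins.max() + 1):
        sel = bins == bi
        rows.append({
            "bin": bi,
            "count": int(sel.sum()),
            "confidence": float(p[sel].mean()),
            "observed": float(y[sel].mean()),
        })
    stats = pd.DataFrame(rows)
    stats["gap"] = (stats["observed"] - stats["confidence"]).abs()
    return CalibrationResult(
        variant="prediction_calibration",
        bin_assignments=bins,
        bin_stats=stats,
        ace=float(stats["gap"].mean()),
    )


def uncertainty_accuracy_calibration(
    labels: np.ndarray,
    probabilities: np.ndarray,
    uncertainties: np.ndarray,
    threshold: float = 0.5,
    min_per_bin: int = 25,
) -> CalibrationResult:
    """Certainty-vs-accuracy calibration over adaptive bins.

    ``uncertainties`` must be normalised to [0, 1]; certainty is their
    complement.  Patients are binned by certainty and each bin's
    classification accuracy (at ``threshold``) is compared with its mean
    certainty; the ACE-style score is the unweighted mean absolute gap.
    """
    y = np.asarray(labels, dtype=int).ravel()
    p = np.asarray(probabilities, dtype=float).ravel()
    u = np.asarray(uncertainties, dtype=float).ravel()
    if np.any(u < 0) or np.any(u > 1):
        raise ValueError("uncertainties must be normalised to [0, 1]")
    certainty = 1.0 - u
    correct = ((p >= threshold).astype(int) == y).astype(float)
    bins = adaptive_bins(certainty, min_per_bin)
    rows = []
    for bi in range(bins.max() + 1):
        sel = bins == bi
        rows.append({
            "bin": bi,
            "count": int(sel.sum()),
            "certainty": float(certainty[sel].mean()),
            "accuracy": float(correct[sel].mean()),
        })
    stats = pd.DataFrame(rows)
    stats["gap"] = (stats["accuracy"] - stats["certainty"]).abs()
    return CalibrationResult(
        variant="uncertainty_accuracy",
        bin_assignments=bins,
        bin_stats=stats,
        ace=float(stats["gap"].mean()),
    )


@dataclass
class SparsificationCurve:
    """Metric values along the most-uncertain-first removal path."""

    fractions_removed: np.ndarray
    values: np.ndarray
    metric: str
    method: str = ""
    measure: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "fraction_removed": self.fractions_removed,
            self.metric: self.values,
            "method": self.method,
            "measure": self.measure,
        })


def sparsification(
    labels: np.ndarray,
    probabilities: np.ndarray,
    uncertainties: np.ndarray,
    metric: str = "auc",
    max_removed_fraction: float = 0.5,
    threshold: float = 0.5,
    patient_ids: np.ndarray | None = None,
) -> SparsificationCurve:
    """Iteratively drop the most uncertain patient and re-score the rest.

    One patient is removed per step (ties in uncertainty broken by patient
    id), up to ``floor(n * max_removed_fraction)`` removals.  If the
    retained set loses a class, AUC is recorded as missing (NaN) from that
    step on.
    """
    y = _check_binary(labels)
    p = np.asarray(probabilities, dtype=float).ravel()
    u = np.asarray(uncertainties, dtype=float).ravel()
    n = len(y)
    if n < 4:
        raise ValueError("sparsification needs at least 4 patients")
    if metric not in ("auc", "accuracy"):
        raise ValueError("metric must be 'auc' or 'accuracy'")
    if patient_ids is None:
        patient_ids = np.arange(n)
    removal_order = np.lexsort((np.asarray(patient_ids), -u))
    n_steps = int(np.floor(n * max_removed_fraction))
    values = np.empty(n_steps + 1)
    class_lost = False
    for step in range(n_steps + 1):
        keep = removal_order[step:]
        yk, pk = y[keep], p[keep]
        if metric == "auc":
            if class_lost or len(np.unique(yk)) < 2:
                class_lost = True
                values[step] = np.nan
            else:
                values[step] = roc_auc_score(yk, pk)
        else:
            values[step] = np.mean((pk >= threshold).astype(int) == yk)
    return SparsificationCurve(
        fractions_removed=np.arange(n_steps + 1) / n,
        values=values,
        metric=metric,
    )


def bootstrap_ci(
    metric_fn,
    labels: np.ndarray,
    scores: np.ndarray,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Label-stratified percentile bootstrap CI for a metric(labels, scores).

    Patients are resampled with replacement within each label class, so
    every replicate keeps both classes and the original class balance.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    y = np.asarray(labels, dtype=int).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    rng = derive_rng(seed, "bootstrap")
    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)
    stats = np.empty(B)
    for i in range(B):
        take = np.concatenate([
            rng.choice(idx_pos, size=len(idx_pos), replace=True),
            rng.choice(idx_neg, size=len(idx_neg), replace=True),
        ])
        stats[i] = metric_fn(y[take], s[take])
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)
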