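"""Prediction sample sets under the three uncertainty-quantification methods.

Each method yields, per patient, a set of T sampled event probabilities:

* **MC dropout** — T stochastic forward passes with dropout active at
  inference (default T=50); the dropout rate is chosen from a grid by
  validation AUC of the MC-mean prediction.
* **Deep ensembles** — M independently initialised models trained on
  identical data splits (default M=10); one deterministic prediction each.
* **Test-time augmentation (TTA)** — deterministic forward passes on T
  randomly augmented copies of each case (default T=50), probing input
  rather than parameter randomness.

The mean of the samples is the final prediction for every method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from riskuq._rng import derive_int_seed, derive_rng
from riskuq.cohort import Cohort
from riskuq.nnet import (
    AugmentationPolicy,
    FeatureMeta,
    ModelConfig,
    TrainedNet,
    augment_features,
    train_model,
)

METHODS = ("mc_dropout", "deep_ensemble", "tta")


@dataclass
class PredictionSamples:
    """Per-patient prediction sample matrix (n_patients x T)."""

    patient_ids: np.ndarray
    samples: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (patients x T)")
        if len(self.patient_ids) != self.samples.shape[0]:
            raise ValueError("patient_ids / samples length mismatch")
        if np.any(self.samples < 0) or np.any(self.samples > 1):
            raise ValueError("prediction samples must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def mean_prediction(self) -> np.ndarray:
        """Row mean of the samples — the final prediction."""
        return self.samples.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        cols = {f"sample_{t:03d}": self.samples[:, t] for t in range(self.n_samples)}
        df = pd.DataFrame({"patient_id": self.patient_ids, **cols})
        df["mean_prediction"] = self.mean_prediction
        df["method"] = self.method
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PredictionSamples":
        df = pd.read_csv(path)
        sample_cols = sorted(c for c in df.columns if c.startswith("sample_"))
        return cls(
            patient_ids=df["patient_id"].to_numpy(),
            samples=df[sample_cols].to_numpy(),
            method=str(df["method"].iloc[0]),
        )


@dataclass
class UQConfig:
    """Settings shared by the three UQ methods."""

    n_samples: int = 50
    ensemble_size: int = 10
    dropout_grid: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5)
    augmentation: AugmentationPolicy = field(default_factory=AugmentationPolicy)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.ensemble_size < 2:
            raise ValueError("ensemble_size must be >= 2")


def mc_dropout_predict(
    model: TrainedNet,
    X: np.ndarray,
    T: int = 50,
    seed: int = 0,
    patient_ids: np.ndarray | None = None,
) -> PredictionSamples:
    """T stochastic forward passes with dropout active at inference."""
    X = np.asarray(X, dtype=float)
    if patient_ids is None:
        patient_ids = np.arange(X.shape[0])
    if model.config.dropout_rate == 0.0:
        # degenerate: all passes identical to the deterministic prediction
        p = model.predict(X)
        return PredictionSamples(patient_ids, np.tile(p[:, None], (1, T)), "mc_dropout")
    rng = derive_rng(seed, "mc_dropout")
    samples = np.column_stack([model.predict_stochastic(X, rng) for _ in range(T)])
    return PredictionSamples(patient_ids, samples, "mc_dropout")


def select_dropout_rate(
    train: Cohort,
    valid: Cohort,
    endpoint: str,
    grid: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5),
    base_config: ModelConfig | None = None,
    seed: int = 0,
    T: int = 50,
    augmentation: AugmentationPolicy | None = None,
) -> tuple[float, dict[float, float]]:
    """Grid-select the dropout rate maximising validation AUC.

    One model is trained per candidate rate; each is scored by the AUC of
    its MC-dropout mean prediction (T samples) on the validation cohort.
    Ties are broken towards the smaller rate.
    """
    if len(grid) == 0:
        raise ValueError("dropout grid is empty")
    y_valid = valid.y(endpoint)
    if len(np.unique(y_valid)) < 2:
        raise ValueError("validation cohort has a single class; AUC undefined")
    base_config = base_config or ModelConfig()
    aucs: dict[float, float] = {}
    for rate in grid:
        cfg = base_config.replace(dropout_rate=float(rate))
        model = train_model(train, valid, endpoint, cfg, augmentation=augmentation,
                            seed=derive_int_seed(seed, "rate_fit", rate))
        samples = mc_dropout_predict(model, valid.feature_matrix, T=T,
                                     seed=derive_int_seed(seed, "rate_mc", rate))
        aucs[float(rate)] = float(roc_auc_score(y_valid, samples.mean_prediction))
    best = max(sorted(aucs), key=lambda r: (aucs[r], -r))
    return best, aucs


def train_ensemble(
    train: Cohort,
    valid: Cohort,
    endpoint: str,
    M: int = 10,
    base_config: ModelConfig | None = None,
    seeds: list[int] | None = None,
    augmentation: AugmentationPolicy | None = None,
    check_overlap: bool = True,
) -> list[TrainedNet]:
    """Train M models on identical splits with different initialisations.

    Each member's init seed also drives its mini-batch shuffling, so the
    members differ only through that one random source.
    """
    base_config = base_config or ModelConfig()
    if seeds is None:
        seeds = [derive_int_seed(base_config.init_seed, "ensemble_member", m) for m in range(M)]
    if len(seeds) != M:
        raise ValueError("need exactly M seeds")
    return [
        train_model(train, valid, endpoint, base_config, augmentation=augmentation,
                    seed=s, check_overlap=check_overlap)
        for s in seeds
    ]


def ensemble_predict(
    models: list[TrainedNet],
    X: np.ndarray,
    patient_ids: np.ndarray | None = None,
) -> PredictionSamples:
    """One deterministic prediction per ensemble member (T = M columns)."""
    if len(models) < 2:
        raise ValueError("an ensemble needs at least 2 members")
    X = np.asarray(X, dtype=float)
    if patient_ids is None:
        patient_ids = np.arange(X.shape[0])
    samples = np.column_stack([m.predict(X) for m in models])
    return PredictionSamples(patient_ids, samples, "deep_ensemble")


def tta_predict(
    model: TrainedNet,
    X: np.ndarray,
    policy: AugmentationPolicy,
    T: int = 50,
    seed: int = 0,
    meta: FeatureMeta | None = None,
    patient_ids: np.ndarray | None = None,
) -> PredictionSamples:
    """Deterministic forward passes on T augmented copies of each case.

    Dropout stays off: TTA probes input, not parameter, randomness.
    """
    X = np.asarray(X, dtype=float)
    if patient_ids is None:
        patient_ids = np.arange(X.shape[0])
    if meta is None:
        meta = model.feature_meta
    rng = derive_rng(seed, "tta")
    samples = np.column_stack([
        model.predict(augment_features(X, policy, rng, meta)) for _ in range(T)
    ])
    return PredictionSamples(patient_ids, samples, "tta")
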