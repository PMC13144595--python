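"""Dropout-capable feed-forward binary classifier.

A deliberately small probabilistic classifier standing in for large imaging
backbones: the uncertainty-quantification layer interacts with it only
through a narrow contract (train; deterministic forward pass; stochastic
forward pass with dropout masks resampled per call; feature augmentation).
Implemented directly on NumPy: fully-connected ReLU layers with inverted
dropout, a sigmoid output, binary cross-entropy loss, Adam updates,
mini-batch shuffling and early stopping on validation loss with the
best-validation parameters restored.

Follows the model/results split: :class:`DropoutNet` is the unfitted model,
``fit`` returns a :class:`TrainedNet` carrying parameters, training history
and a ``summary()``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from riskuq._rng import derive_rng
from riskuq.cohort import Cohort

PROB_EPS = 1e-7  # probability clamp applied before any logarithm


@dataclass
class ModelConfig:
    """Hyperparameters of the feed-forward classifier.

    ``dropout_rate`` is used both as a training-time regulariser and, for
    MC dropout, at inference.  ``init_seed`` controls weight initialisation
    and the induced mini-batch shuffling; two fits with the same config,
    data and seed are bit-identical.
    """

    hidden_layer_sizes: tuple[int, ...] = (16, 8)
    dropout_rate: float = 0.2
    learning_rate: float = 1e-3
    max_epochs: int = 500
    batch_size: int = 64
    early_stopping_patience: int = 20
    init_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    def replace(self, **kw) -> "ModelConfig":
        d = asdict(self)
        d.update(kw)
        d["hidden_layer_sizes"] = tuple(d["hidden_layer_sizes"])
        return ModelConfig(**d)


@dataclass
class AugmentationPolicy:
    """Input perturbations used for training augmentation and TTA.

    Continuous features receive additive Gaussian noise (``continuous_sigma``
    standard deviations of the standardized scale) and optional
    multiplicative jitter; one-hot categorical groups are, with probability
    ``categorical_resample_prob``, resampled uniformly over their observed
    levels, so categorical columns always stay valid one-hot indicators.
    """

    continuous_sigma: float = 0.3
    multiplicative_jitter: float = 0.0
    categorical_resample_prob: float = 0.1

    def __post_init__(self) -> None:
        if self.continuous_sigma < 0 or self.multiplicative_jitter < 0:
            raise ValueError("noise scales must be non-negative")
        if not 0.0 <= self.categorical_resample_prob <= 1.0:
            raise ValueError("categorical_resample_prob must be in [0,1]")

    def is_identity(self) -> bool:
        return (
            self.continuous_sigma == 0.0
            and self.multiplicative_jitter == 0.0
            and self.categorical_resample_prob == 0.0
        )


@dataclass
class FeatureMeta:
    """Column-structure of the encoded feature matrix."""

    continuous_idx: list[int]
    categorical_groups: list[list[int]]

    @classmethod
    def from_cohort(cls, cohort: Cohort) -> "FeatureMeta":
        cols = list(cohort.features.columns)
        cont = [cols.index(c) for c in cohort.continuous_columns]
        groups = [[cols.index(c) for c in g] for g in cohort.categorical_groups.values()]
        return cls(continuous_idx=cont, categorical_groups=groups)


def augment_features(
    X: np.ndarray,
    policy: AugmentationPolicy,
    seed: int | np.random.Generator,
    meta: FeatureMeta | None = None,
) -> np.ndarray:
    """Apply one random augmentation draw to a feature matrix.

    Without ``meta`` all columns are treated as continuous.
    """
    rng = seed if isinstance(seed, np.random.Generator) else derive_rng(seed, "augment")
    X = np.array(X, dtype=float, copy=True)
    if meta is None:
        meta = FeatureMeta(continuous_idx=list(range(X.shape[1])), categorical_groups=[])
    if meta.continuous_idx:
        cont = np.asarray(meta.continuous_idx)
        if policy.continuous_sigma > 0:
            X[:, cont] += rng.normal(0.0, policy.continuous_sigma, size=(X.shape[0], cont.size))
        if policy.multiplicative_jitter > 0:
            X[:, cont] *= rng.normal(1.0, policy.multiplicative_jitter, size=(X.shape[0], cont.size))
    if policy.categorical_resample_prob > 0:
        for group in meta.categorical_groups:
            g = np.asarray(group)
            resample = rng.uniform(size=X.shape[0]) < policy.categorical_resample_prob
            if resample.any():
                new_levels = rng.integers(0, g.size, size=int(resample.sum()))
                block = np.zeros((int(resample.sum()), g.size))
                block[np.arange(block.shape[0]), new_levels] = 1.0
                X[np.ix_(resample, g)] = block
    return X


def _bce(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, PROB_EPS, 1.0 - PROB_EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


class _Params:
    """Weight/bias stacks with Adam state."""

    def __init__(self, sizes: list[int], rng: np.random.Generator):
        self.W = [rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
                  for i in range(len(sizes) - 1)]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        self._mW = [np.zeros_like(w) for w in self.W]
        self._vW = [np.zeros_like(w) for w in self.W]
        self._mb = [np.zeros_like(b) for b in self.b]
        self._vb = [np.zeros_like(b) for b in self.b]
        self._t = 0

    def copy_weights(self) -> tuple[list[np.ndarray], list[np.ndarray]]:
        return [w.copy() for w in self.W], [b.copy() for b in self.b]

    def adam_step(self, gW, gb, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self._t += 1
        c1 = 1.0 - beta1 ** self._t
        c2 = 1.0 - beta2 ** self._t
        for i in range(len(self.W)):
            self._mW[i] = beta1 * self._mW[i] + (1 - beta1) * gW[i]
            self._vW[i] = beta2 * self._vW[i] + (1 - beta2) * gW[i] ** 2
            self._mb[i] = beta1 * self._mb[i] + (1 - beta1) * gb[i]
            self._vb[i] = beta2 * self._vb[i] + (1 - beta2) * gb[i] ** 2
            self.W[i] -= lr * (self._mW[i] / c1) / (np.sqrt(self._vW[i] / c2) + eps)
            self.b[i] -= lr * (self._mb[i] / c1) / (np.sqrt(self._vb[i] / c2) + eps)


def _forward(W, b, X, dropout_rate=0.0, rng=None):
    """Forward pass; returns output probabilities and cached activations."""
    a = X
    cache = [a]
    masks = []
    n_hidden = len(W) - 1
    for i in range(n_hidden):
        z = a @ W[i] + b[i]
        a = np.maximum(z, 0.0)
        if dropout_rate > 0.0 and rng is not None:
            keep = rng.uniform(size=a.shape) >= dropout_rate
            a = a * keep / (1.0 - dropout_rate)  # inverted dropout
            masks.append(keep)
        else:
            masks.append(None)
        cache.append(a)
    logits = (a @ W[-1] + b[-1]).ravel()
    return expit(logits), cache, masks


def _backward(W, b, cache, masks, p, y, dropout_rate):
    n = len(y)
    gW = [None] * len(W)
    gb = [None] * len(W)
    delta = ((p - y) / n)[:, None]  # d BCE / d logit
    gW[-1] = cache[-1].T @ delta
    gb[-1] = delta.sum(axis=0)
    grad_a = delta @ W[-1].T
    for i in range(len(W) - 2, -1, -1):
        if masks[i] is not None:
            grad_a = grad_a * masks[i] / (1.0 - dropout_rate)
        grad_z = grad_a * (cache[i + 1] > 0)
        gW[i] = cache[i].T @ grad_z
        gb[i] = grad_z.sum(axis=0)
        if i > 0:
            grad_a = grad_z @ W[i].T
    return gW, gb


@dataclass
class TrainedNet:
    """Fit results: parameters, config and training history.

    ``history`` has one row per epoch with train/valid loss; the retained
    parameters are those of the best validation epoch (``best_epoch``).
    """

    W: list[np.ndarray]
    b: list[np.ndarray]
    config: ModelConfig
    history: pd.DataFrame
    best_epoch: int
    feature_meta: FeatureMeta | None = None
    endpoint: str | None = None

    @property
    def dropout_rate(self) -> float:
        return self.config.dropout_rate

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Deterministic probabilities (dropout disabled)."""
        p, _, _ = _forward(self.W, self.b, np.asarray(X, dtype=float))
        return p

    def predict_stochastic(self, X: np.ndarray, seed: int | np.random.Generator) -> np.ndarray:
        """One forward pass with freshly sampled dropout masks."""
        if self.config.dropout_rate == 0.0:
            warnings.warn("dropout_rate is 0: stochastic pass collapses to deterministic")
            return self.predict(X)
        rng = seed if isinstance(seed, np.random.Generator) else derive_rng(seed, "mc_pass")
        p, _, _ = _forward(self.W, self.b, np.asarray(X, dtype=float),
                           dropout_rate=self.config.dropout_rate, rng=rng)
        return p

    def summary(self) -> str:
        lines = [
            "DropoutNet fit results",
            "======================",
            f"architecture        : {self.W[0].shape[0]} -> "
            + " -> ".join(str(w.shape[1]) for w in self.W),
            f"dropout rate        : {self.config.dropout_rate}",
            f"epochs run          : {len(self.history)} (max {self.config.max_epochs})",
            f"best valid epoch    : {self.best_epoch}",
            f"best valid BCE loss : {self.history['valid_loss'].min():.4f}",
            f"final train BCE loss: {self.history['train_loss'].iloc[-1]:.4f}",
        ]
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        """Serialise parameters + config to a single JSON file."""
        state = {
            "config": {**asdict(self.config),
                       "hidden_layer_sizes": list(self.config.hidden_layer_sizes)},
            "W": [w.tolist() for w in self.W],
            "b": [b.tolist() for b in self.b],
            "best_epoch": self.best_epoch,
            "endpoint": self.endpoint,
        }
        Path(path).write_text(json.dumps(state))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedNet":
        state = json.loads(Path(path).read_text())
        cfg = state["config"]
        cfg["hidden_layer_sizes"] = tuple(cfg["hidden_layer_sizes"])
        return cls(
            W=[np.asarray(w) for w in state["W"]],
            b=[np.asarray(b) for b in state["b"]],
            config=ModelConfig(**cfg),
            history=pd.DataFrame(columns=["epoch", "train_loss", "valid_loss"]),
            best_epoch=state["best_epoch"],
            endpoint=state.get("endpoint"),
        )


class DropoutNet:
    """Unfitted feed-forward classifier (model object).

    Parameters live in :class:`ModelConfig`; ``fit`` consumes raw arrays,
    :func:`train_model` is the cohort-level convenience wrapper.
    """

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()

    def fit(
        self,
        X_train: np.ndarray,
        y_train: np.ndarray,
        X_valid: np.ndarray,
        y_valid: np.ndarray,
        augmentation: AugmentationPolicy | None = None,
        feature_meta: FeatureMeta | None = None,
        seed: int | None = None,
    ) -> TrainedNet:
        X_train = np.asarray(X_train, dtype=float)
        y_train = np.asarray(y_train, dtype=float).ravel()
        X_valid = np.asarray(X_valid, dtype=float)
        y_valid = np.asarray(y_valid, dtype=float).ravel()
        if len(np.unique(y_train)) < 2:
            raise ValueError("training labels contain a single class")
        cfg = self.config
        seed = cfg.init_seed if seed is None else seed
        rng = derive_rng(seed, "fit")
        sizes = [X_train.shape[1], *cfg.hidden_layer_sizes, 1]
        params = _Params(sizes, rng)

        best = params.copy_weights()
        best_loss = np.inf
        best_epoch = 0
        since_best = 0
        hist = []
        n = X_train.shape[0]
        for epoch in range(1, cfg.max_epochs + 1):
            order = rng.permutation(n)
            Xe = X_train[order]
            ye = y_train[order]
            if augmentation is not None and not augmentation.is_identity():
                Xe = augment_features(Xe, augmentation, rng, feature_meta)
            for start in range(0, n, cfg.batch_size):
                xb = Xe[start:start + cfg.batch_size]
                yb = ye[start:start + cfg.batch_size]
                p, cache, masks = _forward(params.W, params.b, xb,
                                           dropout_rate=cfg.dropout_rate, rng=rng)
                gW, gb = _backward(params.W, params.b, cache, masks, p, yb, cfg.dropout_rate)
                params.adam_step(gW, gb, cfg.learning_rate)
            train_loss = _bce(y_train, _forward(params.W, params.b, X_train)[0])
            valid_loss = _bce(y_valid, _forward(params.W, params.b, X_valid)[0])
            hist.append((epoch, train_loss, valid_loss))
            if valid_loss < best_loss - 1e-9:
                best_loss = valid_loss
                best = params.copy_weights()
                best_epoch = epoch
                since_best = 0
            else:
                since_best += 1
                if since_best >= cfg.early_stopping_patience:
                    break
        history = pd.DataFrame(hist, columns=["epoch", "train_loss", "valid_loss"])
        return TrainedNet(W=best[0], b=best[1], config=cfg, history=history,
                          best_epoch=best_epoch, feature_meta=feature_meta)


def train_model(
    train: Cohort,
    valid: Cohort,
    endpoint: str,
    config: ModelConfig | None = None,
    augmentation: AugmentationPolicy | None = None,
    seed: int | None = None,
    check_overlap: bool = True,
) -> TrainedNet:
    """Train on a cohort pair with early stopping on the validation cohort."""
    for c in (train, valid):
        if endpoint not in c.endpoints:
            raise ValueError(f"endpoint {endpoint!r} missing from cohort")
    if check_overlap and set(train.patient_ids) & set(valid.patient_ids):
        raise ValueError("train and valid cohorts overlap")
    meta = FeatureMeta.from_cohort(train)
    net = DropoutNet(config)
    fitted = net.fit(
        train.feature_matrix, train.y(endpoint),
        valid.feature_matrix, valid.y(endpoint),
        augmentation=augmentation, feature_meta=meta, seed=seed,
    )
    fitted.endpoint = endpoint
    return fitted


def predict_deterministic(model: TrainedNet, X: np.ndarray) -> np.ndarray:
    """Single point prediction per patient (the deterministic baseline)."""
    return model.predict(X)


def predict_stochastic(model: TrainedNet, X: np.ndarray, seed: int | np.random.Generator) -> np.ndarray:
    """One dropout-perturbed forward pass."""
    return model.predict_stochastic(X, seed)
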