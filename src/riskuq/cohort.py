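"""Synthetic patient cohorts for NTCP/TCP-style binary outcome modelling.

Cohorts are generated from a logistic-linear model: standardized continuous
covariates and multinomial categorical covariates (one-hot encoded) enter a
linear predictor whose intercept is calibrated so the marginal event rate
matches a target prevalence.  The per-patient Bernoulli parameter
(``true_prob``) is retained, so the aleatoric component of prediction
uncertainty is known exactly and the Bayes-optimal predictor is available
as a reference.  Optional symmetric label flips model irreducible
assessment variability in patient- or physician-reported endpoints.

The default NTCP-style cohort emulates a 1,205-patient head-and-neck
radiotherapy toxicity dataset (6-month grade >=2 dysphagia, prevalence 22%;
moderate-to-severe xerostomia, 42%) and the default TCP-style cohort a
340-patient oropharyngeal tumour-control dataset (2-year death, 24%;
2-year locoregional control failure, 25%).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit

from riskuq._rng import derive_rng

_CAT_LEVEL_PROBS = (0.5, 0.3, 0.2)  # marginal distribution of each categorical covariate


@dataclass
class CovariateShift:
    """Affine shift of the continuous covariates (out-of-distribution probe).

    ``loc`` is added after multiplying by ``scale``; either may be a scalar
    or a vector with one entry per continuous feature.
    """

    loc: float | np.ndarray = 0.0
    scale: float | np.ndarray = 1.0

    def is_identity(self) -> bool:
        return bool(np.all(np.asarray(self.loc) == 0.0) and np.all(np.asarray(self.scale) == 1.0))


@dataclass
class CohortSpec:
    """Generative specification of a synthetic cohort.

    Parameters
    ----------
    n_patients
        Cohort size (>= 2).
    prevalences
        Mapping endpoint name -> target marginal event rate in (0, 1).
    n_continuous, n_categorical
        Number of standardized continuous and 3-level categorical covariates.
    effect_sizes
        Optional mapping endpoint -> log-odds coefficient vector over the
        encoded feature columns (continuous first, then one-hot categorical
        levels).  ``None`` uses moderate defaults giving a Bayes AUC around
        0.75-0.80, typical of clinical NTCP models.
    label_noise
        Probability of an independent symmetric label flip, in [0, 0.5).
    shift
        Optional covariate shift applied at generation time.
    seed
        Master seed; generation is bit-reproducible given the spec.
    """

    n_patients: int
    prevalences: dict[str, float]
    n_continuous: int = 6
    n_categorical: int = 2
    effect_sizes: dict[str, np.ndarray] | None = None
    label_noise: float = 0.0
    shift: CovariateShift | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not self.prevalences:
            raise ValueError("at least one endpoint is required")
        for name, p in self.prevalences.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"prevalence for {name!r} must be in (0,1), got {p}")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")
        if self.n_continuous < 0 or self.n_categorical < 0:
            raise ValueError("feature counts must be non-negative")
        if self.n_continuous + self.n_categorical == 0:
            raise ValueError("at least one feature is required")

    @property
    def endpoints(self) -> list[str]:
        return list(self.prevalences)

    @property
    def feature_columns(self) -> list[str]:
        cols = [f"cont_{i}" for i in range(self.n_continuous)]
        for j in range(self.n_categorical):
            cols.extend(f"cat_{j}_lvl{k}" for k in range(len(_CAT_LEVEL_PROBS)))
        return cols

    @property
    def continuous_columns(self) -> list[str]:
        return [f"cont_{i}" for i in range(self.n_continuous)]

    @property
    def categorical_groups(self) -> dict[str, list[str]]:
        return {
            f"cat_{j}": [f"cat_{j}_lvl{k}" for k in range(len(_CAT_LEVEL_PROBS))]
            for j in range(self.n_categorical)
        }

    def effects(self, endpoint: str) -> np.ndarray:
        """Log-odds coefficient vector for ``endpoint`` over encoded columns."""
        if self.effect_sizes is not None and endpoint in self.effect_sizes:
            beta = np.asarray(self.effect_sizes[endpoint], dtype=float)
            if beta.shape != (len(self.feature_columns),):
                raise ValueError(
                    f"effect_sizes[{endpoint!r}] must have length {len(self.feature_columns)}"
                )
            return beta
        return _default_effects(self, endpoint)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        if d["effect_sizes"] is not None:
            d["effect_sizes"] = {k: np.asarray(v).tolist() for k, v in d["effect_sizes"].items()}
        if self.shift is not None:
            d["shift"] = {
                "loc": np.asarray(self.shift.loc).tolist(),
                "scale": np.asarray(self.shift.scale).tolist(),
            }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        d = yaml.safe_load(Path(path).read_text())
        if d.get("effect_sizes") is not None:
            d["effect_sizes"] = {k: np.asarray(v, dtype=float) for k, v in d["effect_sizes"].items()}
        if d.get("shift") is not None:
            d["shift"] = CovariateShift(
                loc=np.asarray(d["shift"]["loc"], dtype=float),
                scale=np.asarray(d["shift"]["scale"], dtype=float),
            )
        return cls(**d)


def _default_effects(spec: CohortSpec, endpoint: str) -> np.ndarray:
    # Moderate, mixed-sign effects; rotated per endpoint so endpoints are
    # correlated but not identical, as clinical toxicity endpoints are.
    base = np.array([1.0, -0.8, 0.6, -0.4, 0.3, -0.2])
    k = spec.endpoints.index(endpoint) if endpoint in spec.endpoints else 0
    cont = np.resize(np.roll(base, k), spec.n_continuous)
    cat_levels = np.array([0.0, 0.5, -0.5])[: len(_CAT_LEVEL_PROBS)]
    cat = np.tile(cat_levels, spec.n_categorical)
    return np.concatenate([cont, cat])


def ntcp_cohort_spec(n_patients: int = 1205, seed: int = 0, **overrides) -> CohortSpec:
    """Default NTCP-style cohort: 6-month dysphagia (22%) and xerostomia (42%)."""
    kwargs = dict(
        n_patients=n_patients,
        prevalences={"dysphagia": 0.22, "xerostomia": 0.42},
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortSpec(**kwargs)


def tcp_cohort_spec(n_patients: int = 340, seed: int = 0, **overrides) -> CohortSpec:
    """Default TCP-style cohort: 2-year death (24%) and LRC failure (25%)."""
    kwargs = dict(
        n_patients=n_patients,
        prevalences={"death_2yr": 0.24, "lrc_failure_2yr": 0.25},
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortSpec(**kwargs)


@dataclass
class Cohort:
    """Patient-level data: features, binary labels, latent event probabilities.

    ``split`` holds one of ``train`` / ``valid`` / ``independent_validation``
    per patient.  ``linear_models`` retains the generative (intercept, beta)
    pair per endpoint when the cohort was synthesised, enabling label
    regeneration under covariate shift; it is ``None`` for cohorts read
    from CSV.
    """

    patient_ids: np.ndarray
    features: pd.DataFrame
    labels: pd.DataFrame
    true_prob: pd.DataFrame
    split: np.ndarray
    spec: CohortSpec | None = None
    linear_models: dict[str, tuple[float, np.ndarray]] | None = None
    # latent uniforms / flip masks kept so covariate shift regenerates labels
    # coherently (zero shift reproduces the cohort bit-for-bit)
    label_u: pd.DataFrame | None = field(default=None, repr=False)
    flip_mask: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return len(self.patient_ids)

    @property
    def endpoints(self) -> list[str]:
        return list(self.labels.columns)

    @property
    def feature_matrix(self) -> np.ndarray:
        return self.features.to_numpy(dtype=float)

    @property
    def continuous_columns(self) -> list[str]:
        return [c for c in self.features.columns if c.startswith("cont_")]

    @property
    def categorical_groups(self) -> dict[str, list[str]]:
        groups: dict[str, list[str]] = {}
        for c in self.features.columns:
            if c.startswith("cat_"):
                groups.setdefault(c.rsplit("_lvl", 1)[0], []).append(c)
        return groups

    def prevalence(self, endpoint: str) -> float:
        return float(self.labels[endpoint].mean())

    def y(self, endpoint: str) -> np.ndarray:
        return self.labels[endpoint].to_numpy(dtype=int)

    def subset(self, indices: np.ndarray, split_label: str | None = None) -> "Cohort":
        indices = np.sort(np.asarray(indices))
        split = self.split[indices].copy()
        if split_label is not None:
            split = np.full(len(indices), split_label, dtype=object)
        return Cohort(
            patient_ids=self.patient_ids[indices].copy(),
            features=self.features.iloc[indices].reset_index(drop=True),
            labels=self.labels.iloc[indices].reset_index(drop=True),
            true_prob=self.true_prob.iloc[indices].reset_index(drop=True),
            split=split,
            spec=self.spec,
            linear_models=self.linear_models,
            label_u=None if self.label_u is None else self.label_u.iloc[indices].reset_index(drop=True),
            flip_mask=None if self.flip_mask is None else self.flip_mask.iloc[indices].reset_index(drop=True),
        )

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"patient_id": self.patient_ids})
        df = pd.concat([df, self.features], axis=1)
        for ep in self.endpoints:
            df[ep] = self.labels[ep].to_numpy(dtype=int)
        for ep in self.endpoints:
            df[f"true_prob_{ep}"] = self.true_prob[ep].to_numpy()
        df["split"] = self.split
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Cohort":
        df = pd.read_csv(path)
        feat_cols = [c for c in df.columns if c.startswith(("cont_", "cat_"))]
        prob_cols = [c for c in df.columns if c.startswith("true_prob_")]
        endpoints = [c.removeprefix("true_prob_") for c in prob_cols]
        return cls(
            patient_ids=df["patient_id"].to_numpy(),
            features=df[feat_cols].copy(),
            labels=df[endpoints].astype(int).copy(),
            true_prob=df[prob_cols].rename(columns=dict(zip(prob_cols, endpoints))).copy(),
            split=df["split"].to_numpy(dtype=object),
        )


def _draw_features(spec: CohortSpec, n: int, rng: np.random.Generator) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}
    for i in range(spec.n_continuous):
        cols[f"cont_{i}"] = rng.standard_normal(n)
    probs = np.asarray(_CAT_LEVEL_PROBS)
    for j in range(spec.n_categorical):
        codes = rng.choice(len(probs), size=n, p=probs)
        for k in range(len(probs)):
            cols[f"cat_{j}_lvl{k}"] = (codes == k).astype(float)
    return pd.DataFrame(cols, columns=spec.feature_columns)


def _observed_prevalence(p_event: np.ndarray | float, label_noise: float) -> np.ndarray | float:
    # symmetric flips: P(label=1) = p(1-rho) + (1-p)rho
    return p_event * (1.0 - 2.0 * label_noise) + label_noise


def calibrate_intercept(
    spec: CohortSpec,
    endpoint: str,
    n_mc: int = 200_000,
    tol: float = 0.005,
) -> float:
    """Log-odds intercept matching the endpoint's target marginal prevalence.

    With all-zero effects the closed-form logit is returned; otherwise the
    intercept is found by root-finding on a fixed Monte Carlo draw of the
    covariates (``n_mc`` samples), which makes the calibration deterministic
    for a given spec.  Symmetric label noise is accounted for analytically.
    """
    target = spec.prevalences[endpoint]
    rho = spec.label_noise
    beta = spec.effects(endpoint)
    latent_target = (target - rho) / (1.0 - 2.0 * rho)
    if not 0.0 < latent_target < 1.0:
        raise ValueError(
            f"prevalence {target} unreachable under label_noise {rho} "
            f"(noise floor {rho}, ceiling {1 - rho})"
        )
    if np.all(beta == 0.0):
        return float(logit(latent_target))
    rng = derive_rng(spec.seed, "calibration", endpoint)
    eta = _draw_features(spec, n_mc, rng).to_numpy() @ beta

    def gap(b0: float) -> float:
        return float(np.mean(expit(b0 + eta))) - latent_target

    lo, hi = -40.0, 40.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError(f"prevalence {target} unreachable for endpoint {endpoint!r}")
    b0 = brentq(gap, lo, hi, xtol=1e-10)
    if abs(gap(b0)) > tol:
        raise ValueError(f"intercept calibration failed for {endpoint!r}")
    return float(b0)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a cohort under the logistic-linear model of ``spec``.

    ``true_prob`` is the per-patient Bernoulli parameter before label noise;
    labels are drawn from it and then flipped independently with probability
    ``spec.label_noise``.  Bit-reproducible given the spec (seed included).
    """
    n = spec.n_patients
    features = _draw_features(spec, n, derive_rng(spec.seed, "features"))
    if spec.shift is not None:
        features = _shift_features(features, spec.shift, spec.continuous_columns)
    labels: dict[str, np.ndarray] = {}
    true_prob: dict[str, np.ndarray] = {}
    label_u: dict[str, np.ndarray] = {}
    flip_mask: dict[str, np.ndarray] = {}
    linear_models: dict[str, tuple[float, np.ndarray]] = {}
    X = features.to_numpy(dtype=float)
    for ep in spec.endpoints:
        beta = spec.effects(ep)
        b0 = calibrate_intercept(spec, ep)
        p = expit(b0 + X @ beta)
        u = derive_rng(spec.seed, "labels", ep).uniform(size=n)
        y = (u < p).astype(int)
        flips = derive_rng(spec.seed, "noise", ep).uniform(size=n) < spec.label_noise
        y = np.where(flips, 1 - y, y)
        linear_models[ep] = (b0, beta)
        true_prob[ep] = p
        labels[ep] = y
        label_u[ep] = u
        flip_mask[ep] = flips
    return Cohort(
        patient_ids=np.arange(n),
        features=features,
        labels=pd.DataFrame(labels),
        true_prob=pd.DataFrame(true_prob),
        split=np.full(n, "train", dtype=object),
        spec=spec,
        linear_models=linear_models,
        label_u=pd.DataFrame(label_u),
        flip_mask=pd.DataFrame(flip_mask),
    )


def _round_half_even(x: float) -> int:
    # guard against float dust (0.8*1205 = 964.0000000000001)
    return int(round(round(x, 9)))


def _two_way_split(n: int, fraction: float, seed: int, tag: str) -> tuple[np.ndarray, np.ndarray]:
    if not 0.0 < fraction < 1.0:
        raise ValueError("split fraction must be in (0,1)")
    n_first = _round_half_even(fraction * n)
    if n_first == 0 or n_first == n:
        raise ValueError(f"fraction {fraction} yields an empty partition for n={n}")
    perm = derive_rng(seed, tag).permutation(n)
    return np.sort(perm[:n_first]), np.sort(perm[n_first:])


def split_cohort(cohort: Cohort, dev_fraction: float, seed: int) -> tuple[Cohort, Cohort]:
    """Random development / independent-validation split.

    The development size is ``round(dev_fraction * n)`` with round-half-to-
    even, matching e.g. 1205 -> 964/241 at 80/20 and 340 -> 255/85 at 75/25.
    """
    dev_idx, val_idx = _two_way_split(cohort.n, dev_fraction, seed, "dev_split")
    return cohort.subset(dev_idx, "train"), cohort.subset(val_idx, "independent_validation")


def inner_split(development: Cohort, train_fraction: float, seed: int) -> tuple[Cohort, Cohort]:
    """Split a development cohort into training and early-stopping validation."""
    tr_idx, va_idx = _two_way_split(development.n, train_fraction, seed, "inner_split")
    return development.subset(tr_idx, "train"), development.subset(va_idx, "valid")


def _shift_features(features: pd.DataFrame, shift: CovariateShift, cont_cols: list[str]) -> pd.DataFrame:
    out = features.copy()
    if cont_cols:
        loc = np.broadcast_to(np.asarray(shift.loc, dtype=float), (len(cont_cols),))
        scale = np.broadcast_to(np.asarray(shift.scale, dtype=float), (len(cont_cols),))
        out[cont_cols] = out[cont_cols].to_numpy() * scale + loc
    return out


def apply_covariate_shift(cohort: Cohort, shift: CovariateShift) -> Cohort:
    """Shift the continuous covariates and regenerate outcomes coherently.

    ``true_prob`` and labels are recomputed from the cohort's generative
    linear models on the shifted features, reusing the cohort's latent
    uniform draws so that a zero shift returns an identical cohort.
    """
    if cohort.linear_models is None or cohort.label_u is None:
        raise ValueError("covariate shift requires a synthetically generated cohort")
    cont_cols = cohort.continuous_columns
    loc = np.broadcast_to(np.asarray(shift.loc, dtype=float), (len(cont_cols),))
    scale = np.broadcast_to(np.asarray(shift.scale, dtype=float), (len(cont_cols),))
    if np.asarray(shift.loc).ndim > 1 or np.asarray(shift.scale).ndim > 1:
        raise ValueError("shift loc/scale must be scalar or 1-D")
    features = _shift_features(cohort.features, CovariateShift(loc, scale), cont_cols)
    X = features.to_numpy(dtype=float)
    labels = {}
    true_prob = {}
    for ep in cohort.endpoints:
        b0, beta = cohort.linear_models[ep]
        p = expit(b0 + X @ beta)
        y = (cohort.label_u[ep].to_numpy() < p).astype(int)
        if cohort.flip_mask is not None:
            y = np.where(cohort.flip_mask[ep].to_numpy(), 1 - y, y)
        true_prob[ep] = p
        labels[ep] = y
    return Cohort(
        patient_ids=cohort.patient_ids.copy(),
        features=features,
        labels=pd.DataFrame(labels),
        true_prob=pd.DataFrame(true_prob),
        split=cohort.split.copy(),
        spec=cohort.spec,
        linear_models=cohort.linear_models,
        label_u=cohort.label_u,
        flip_mask=cohort.flip_mask,
    )
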