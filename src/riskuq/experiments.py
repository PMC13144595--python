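"""End-to-end uncertainty-quantification experiments on synthetic cohorts.

Two experiment designs are orchestrated here:

* :func:`run_uq_comparison` — the method x measure comparison: train a
  deterministic baseline plus MC dropout (grid-selected rate), a deep
  ensemble and TTA on one development cohort; evaluate AUC/ACE with
  bootstrap CIs and DeLong tests against the baseline on the independent
  validation cohort; compute all nine method x measure certainty-accuracy
  calibration cells and sparsification curves.
* :func:`training_size_experiment` — retrain each UQ model on nested
  incremental training subsets (N more patients per step, stopping when
  fewer than N unsampled patients remain) with constant validation and
  independent-validation sets, repeated R times, recording the mean/SD of
  raw uncertainties and discrimination per cell.

Everything is driven by one master seed; rerunning with the same seed
reproduces every table bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from riskuq._rng import derive_int_seed, derive_rng
from riskuq.cohort import Cohort, CohortSpec, generate_cohort, inner_split, ntcp_cohort_spec, split_cohort
from riskuq.evaluation import (
    CalibrationResult,
    SparsificationCurve,
    auc,
    bootstrap_ci,
    delong_test,
    prediction_ace,
    sparsification,
    uncertainty_accuracy_calibration,
    youden_threshold,
)
from riskuq.measures import MEASURES, compute_measure, minmax_normalise
from riskuq.methods import (
    METHODS,
    PredictionSamples,
    UQConfig,
    ensemble_predict,
    mc_dropout_predict,
    select_dropout_rate,
    train_ensemble,
    tta_predict,
)
from riskuq.nnet import FeatureMeta, ModelConfig, predict_deterministic, train_model


@dataclass
class EvaluationSettings:
    """Evaluation-layer settings: threshold rule, binning, bootstrap."""

    threshold: float = 0.5
    threshold_mode: str = "fixed"  # "fixed" | "youden"
    min_per_bin: int = 25
    bootstrap_B: int = 1000
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("fixed", "youden"):
            raise ValueError("threshold_mode must be 'fixed' or 'youden'")


@dataclass
class ScalingSettings:
    """Training-set-size experiment settings.

    ``increment`` is N (100 for the NTCP-style cohort, 50 for the smaller
    TCP-style one) and ``repeats`` the number of independent sampling
    orders (10 by default).
    """

    increment: int = 100
    repeats: int = 10
    methods: tuple[str, ...] = METHODS

    def __post_init__(self) -> None:
        if self.increment < 1:
            raise ValueError("increment N must be >= 1")
        if self.repeats < 1:
            raise ValueError("repeats R must be >= 1")
        for m in self.methods:
            if m not in METHODS:
                raise ValueError(f"unknown UQ method {m!r}")


@dataclass
class ExperimentConfig:
    """Complete description of one experiment run."""

    cohort: CohortSpec = field(default_factory=ntcp_cohort_spec)
    dev_fraction: float = 0.8
    train_fraction: float = 0.8
    model: ModelConfig = field(default_factory=ModelConfig)
    uq: UQConfig = field(default_factory=UQConfig)
    evaluation: EvaluationSettings = field(default_factory=EvaluationSettings)
    scaling: ScalingSettings = field(default_factory=ScalingSettings)
    seed: int = 0
    out_dir: str | None = None

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["cohort"]["effect_sizes"] = (
            None if self.cohort.effect_sizes is None
            else {k: np.asarray(v).tolist() for k, v in self.cohort.effect_sizes.items()}
        )
        if self.cohort.shift is not None:
            d["cohort"]["shift"] = {
                "loc": np.asarray(self.cohort.shift.loc).tolist(),
                "scale": np.asarray(self.cohort.shift.scale).tolist(),
            }
        d["model"]["hidden_layer_sizes"] = list(self.model.hidden_layer_sizes)
        d["uq"]["dropout_grid"] = list(self.uq.dropout_grid)
        d["scaling"]["methods"] = list(self.scaling.methods)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        from riskuq.cohort import CovariateShift
        from riskuq.nnet import AugmentationPolicy

        d = yaml.safe_load(Path(path).read_text())
        cohort = d.get("cohort", {})
        if cohort.get("effect_sizes") is not None:
            cohort["effect_sizes"] = {k: np.asarray(v, float) for k, v in cohort["effect_sizes"].items()}
        if cohort.get("shift") is not None:
            cohort["shift"] = CovariateShift(**cohort["shift"])
        model = d.get("model", {})
        if "hidden_layer_sizes" in model:
            model["hidden_layer_sizes"] = tuple(model["hidden_layer_sizes"])
        uq = d.get("uq", {})
        if "dropout_grid" in uq:
            uq["dropout_grid"] = tuple(uq["dropout_grid"])
        if "augmentation" in uq and isinstance(uq["augmentation"], dict):
            uq["augmentation"] = AugmentationPolicy(**uq["augmentation"])
        scaling = d.get("scaling", {})
        if "methods" in scaling:
            scaling["methods"] = tuple(scaling["methods"])
        return cls(
            cohort=CohortSpec(**cohort),
            dev_fraction=d.get("dev_fraction", 0.8),
            train_fraction=d.get("train_fraction", 0.8),
            model=ModelConfig(**model),
            uq=UQConfig(**uq),
            evaluation=EvaluationSettings(**d.get("evaluation", {})),
            scaling=ScalingSettings(**scaling),
            seed=d.get("seed", 0),
            out_dir=d.get("out_dir"),
        )

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d["cohort"]["effect_sizes"] = (
            None if self.cohort.effect_sizes is None
            else {k: np.asarray(v).tolist() for k, v in self.cohort.effect_sizes.items()}
        )
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _cohort_hash(cohort: Cohort) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(cohort.feature_matrix).tobytes())
    h.update(cohort.labels.to_numpy(dtype=int).tobytes())
    return h.hexdigest()[:16]


def prepare_splits(config: ExperimentConfig) -> tuple[Cohort, Cohort, Cohort, Cohort]:
    """Generate the cohort and produce (development, ival, train, valid)."""
    spec = dataclasses.replace(config.cohort, seed=derive_int_seed(config.seed, "cohort"))
    cohort = generate_cohort(spec)
    dev, ival = split_cohort(cohort, config.dev_fraction, derive_int_seed(config.seed, "dev_split"))
    train, valid = inner_split(dev, config.train_fraction, derive_int_seed(config.seed, "inner_split"))
    return dev, ival, train, valid


@dataclass
class EndpointResult:
    """All artefacts for one endpoint of the method x measure comparison."""

    endpoint: str
    selected_dropout_rate: float
    rate_aucs: dict[float, float]
    thresholds: dict[str, float]
    samples: dict[str, PredictionSamples]
    baseline_prediction: np.ndarray
    table: pd.DataFrame
    calibration: dict[tuple[str, str], CalibrationResult]
    sparsification_curves: dict[tuple[str, str, str], SparsificationCurve]


@dataclass
class UQComparisonResult:
    """Results bundle of :func:`run_uq_comparison`."""

    config: ExperimentConfig
    cohort_sizes: dict[str, int]
    endpoints: dict[str, EndpointResult]

    def table(self) -> pd.DataFrame:
        return pd.concat([r.table for r in self.endpoints.values()], ignore_index=True)


def _evaluate_method(y, probs, settings: EvaluationSettings, seed: int) -> dict:
    thr = settings.threshold
    if settings.threshold_mode == "youden":
        thr = youden_threshold(y, probs)
    a = auc(y, probs)
    a_lo, a_hi = bootstrap_ci(auc, y, probs, B=settings.bootstrap_B,
                              alpha=settings.alpha, seed=derive_int_seed(seed, "auc_ci"))
    ace = prediction_ace(y, probs, settings.min_per_bin).ace
    ace_fn = lambda yy, pp: prediction_ace(yy, pp, settings.min_per_bin).ace
    e_lo, e_hi = bootstrap_ci(ace_fn, y, probs, B=settings.bootstrap_B,
                              alpha=settings.alpha, seed=derive_int_seed(seed, "ace_ci"))
    from riskuq.evaluation import accuracy as _accuracy
    return {
        "auc": a, "auc_lo": a_lo, "auc_hi": a_hi,
        "ace": ace, "ace_lo": e_lo, "ace_hi": e_hi,
        "accuracy": _accuracy(y, probs, thr), "threshold": thr,
    }


def run_uq_comparison(config: ExperimentConfig, endpoints: list[str] | None = None) -> UQComparisonResult:
    """Run the full baseline-vs-UQ comparison on one synthetic cohort.

    For each endpoint: trains the deterministic baseline, grid-selects the
    MC-dropout rate, trains the M-member ensemble, applies TTA; computes
    mean predictions, AUC/ACE with stratified bootstrap CIs, the DeLong
    test against the baseline, all nine method x measure certainty-accuracy
    calibration cells (variance and MI min-max normalised on the
    independent validation cohort) and AUC/accuracy sparsification curves.
    """
    seed = config.seed
    dev, ival, train, valid = prepare_splits(config)
    meta = FeatureMeta.from_cohort(train)
    X_ival = ival.feature_matrix
    results: dict[str, EndpointResult] = {}
    for ep in endpoints or config.cohort.endpoints:
        y = ival.y(ep)
        baseline = train_model(train, valid, ep, config.model,
                               augmentation=config.uq.augmentation,
                               seed=derive_int_seed(seed, "baseline", ep))
        baseline_pred = predict_deterministic(baseline, X_ival)

        rate, rate_aucs = select_dropout_rate(
            train, valid, ep, config.uq.dropout_grid, config.model,
            seed=derive_int_seed(seed, "rate_select", ep), T=config.uq.n_samples,
            augmentation=config.uq.augmentation,
        )
        mc_model = train_model(train, valid, ep, config.model.replace(dropout_rate=rate),
                               augmentation=config.uq.augmentation,
                               seed=derive_int_seed(seed, "rate_fit", rate))
        members = train_ensemble(
            train, valid, ep, config.uq.ensemble_size, config.model,
            seeds=[derive_int_seed(seed, "ensemble", ep, m) for m in range(config.uq.ensemble_size)],
            augmentation=config.uq.augmentation,
        )
        samples = {
            "mc_dropout": mc_dropout_predict(mc_model, X_ival, config.uq.n_samples,
                                             seed=derive_int_seed(seed, "mc", ep),
                                             patient_ids=ival.patient_ids),
            "deep_ensemble": ensemble_predict(members, X_ival, patient_ids=ival.patient_ids),
            "tta": tta_predict(baseline, X_ival, config.uq.augmentation, config.uq.n_samples,
                               seed=derive_int_seed(seed, "tta", ep), meta=meta,
                               patient_ids=ival.patient_ids),
        }

        rows = []
        thresholds = {}
        row = _evaluate_method(y, baseline_pred, config.evaluation, derive_int_seed(seed, "eval", ep, "baseline"))
        rows.append({"endpoint": ep, "method": "baseline", **row, "delong_p": np.nan})
        thresholds["baseline"] = row["threshold"]
        for method in METHODS:
            pm = samples[method].mean_prediction
            row = _evaluate_method(y, pm, config.evaluation, derive_int_seed(seed, "eval", ep, method))
            _, _, p_delong = delong_test(y, pm, baseline_pred)
            rows.append({"endpoint": ep, "method": method, **row, "delong_p": p_delong})
            thresholds[method] = row["threshold"]
        table = pd.DataFrame(rows)

        calibration: dict[tuple[str, str], CalibrationResult] = {}
        curves: dict[tuple[str, str, str], SparsificationCurve] = {}
        for method in METHODS:
            pm = samples[method].mean_prediction
            for measure in MEASURES:
                raw = compute_measure(samples[method], measure)
                norm = raw if measure == "entropy" else minmax_normalise(raw)
                calibration[(method, measure)] = uncertainty_accuracy_calibration(
                    y, pm, norm.values, thresholds[method], config.evaluation.min_per_bin)
                for metric in ("auc", "accuracy"):
                    curve = sparsification(y, pm, raw.values, metric,
                                           threshold=thresholds[method],
                                           patient_ids=ival.patient_ids)
                    curve.method, curve.measure = method, measure
                    curves[(method, measure, metric)] = curve

        results[ep] = EndpointResult(
            endpoint=ep, selected_dropout_rate=rate, rate_aucs=rate_aucs,
            thresholds=thresholds, samples=samples, baseline_prediction=baseline_pred,
            table=table, calibration=calibration, sparsification_curves=curves,
        )
    bundle = UQComparisonResult(
        config=config,
        cohort_sizes={"development": dev.n, "independent_validation": ival.n,
                      "train": train.n, "valid": valid.n},
        endpoints=results,
    )
    if config.out_dir:
        render_report(bundle, config.out_dir)
    return bundle


@dataclass
class ScalingResult:
    """Results of the training-set-size experiment.

    ``records`` holds one row per (endpoint, method, measure, size, repeat)
    with the mean/SD over independent-validation patients of the raw
    uncertainty, the independent-validation AUC and the certainty-accuracy
    calibration error; ``ival_hash`` per cell certifies the evaluation set
    never changed.
    """

    config: ExperimentConfig
    records: pd.DataFrame
    selected_dropout_rate: dict[str, float]

    def summary(self) -> pd.DataFrame:
        """Mean and SD across repeats for every (method, measure, size)."""
        g = self.records.groupby(["endpoint", "method", "measure", "size"], as_index=False)
        out = g.agg(
            unc_mean=("unc_mean", "mean"), unc_mean_sd=("unc_mean", "std"),
            auc_mean=("auc", "mean"), auc_sd=("auc", "std"),
            calib_mean=("calib_error", "mean"), calib_sd=("calib_error", "std"),
        )
        return out


def incremental_sizes(n_pool: int, increment: int) -> list[int]:
    """Training sizes N, 2N, ... until fewer than N patients remain unsampled."""
    if n_pool < 2 * increment:
        raise ValueError(f"pool of {n_pool} too small for two increments of {increment}")
    return [k * increment for k in range(1, n_pool // increment + 1)]


def training_size_experiment(
    config: ExperimentConfig,
    endpoints: list[str] | None = None,
) -> ScalingResult:
    """Retrain the UQ models on nested incremental training subsets.

    Per repeat, a fresh permutation of the development cohort defines the
    sampling order; the size-kN subset therefore contains the size-(k-1)N
    subset.  The early-stopping validation split and the independent
    validation cohort are fixed throughout (the evaluation set is hashed in
    every cell).  The MC-dropout rate is selected once per endpoint on the
    full development split and reused at every size.
    """
    seed = config.seed
    dev, ival, train, valid = prepare_splits(config)
    N = config.scaling.increment
    sizes = incremental_sizes(dev.n, N)
    meta = FeatureMeta.from_cohort(dev)
    X_ival = ival.feature_matrix
    ival_hash = _cohort_hash(ival)
    T, M = config.uq.n_samples, config.uq.ensemble_size

    selected: dict[str, float] = {}
    rows = []
    for ep in endpoints or config.cohort.endpoints:
        y = ival.y(ep)
        if "mc_dropout" in config.scaling.methods:
            selected[ep], _ = select_dropout_rate(
                train, valid, ep, config.uq.dropout_grid, config.model,
                seed=derive_int_seed(seed, "scale_rate", ep), T=T,
                augmentation=config.uq.augmentation)
        for r in range(config.scaling.repeats):
            perm = derive_rng(seed, "scaling_perm", ep, r).permutation(dev.n)
            for size in sizes:
                sub = dev.subset(perm[:size], "train")
                cell_seed = derive_int_seed(seed, "scale_cell", ep, r, size)
                for method in config.scaling.methods:
                    if method == "mc_dropout":
                        model = train_model(
                            sub, valid, ep, config.model.replace(dropout_rate=selected[ep]),
                            augmentation=config.uq.augmentation,
                            seed=derive_int_seed(cell_seed, "fit"), check_overlap=False)
                        ps = mc_dropout_predict(model, X_ival, T,
                                                seed=derive_int_seed(cell_seed, "mc"),
                                                patient_ids=ival.patient_ids)
                    elif method == "deep_ensemble":
                        members = train_ensemble(
                            sub, valid, ep, M, config.model,
                            seeds=[derive_int_seed(cell_seed, "member", m) for m in range(M)],
                            augmentation=config.uq.augmentation, check_overlap=False)
                        ps = ensemble_predict(members, X_ival, patient_ids=ival.patient_ids)
                    else:  # tta
                        model = train_model(sub, valid, ep, config.model,
                                            augmentation=config.uq.augmentation,
                                            seed=derive_int_seed(cell_seed, "fit"),
                                            check_overlap=False)
                        ps = tta_predict(model, X_ival, config.uq.augmentation, T,
                                         seed=derive_int_seed(cell_seed, "tta"), meta=meta,
                                         patient_ids=ival.patient_ids)
                    pm = ps.mean_prediction
                    cell_auc = auc(y, pm)
                    for measure in MEASURES:
                        raw = compute_measure(ps, measure)
                        norm = raw if measure == "entropy" else minmax_normalise(raw)
                        calib = uncertainty_accuracy_calibration(
                            y, pm, norm.values, config.evaluation.threshold,
                            config.evaluation.min_per_bin).ace
                        rows.append({
                            "endpoint": ep, "method": method, "measure": measure,
                            "size": size, "repeat": r,
                            "unc_mean": float(raw.values.mean()),
                            "unc_sd": float(raw.values.std()),
                            "auc": cell_auc, "calib_error": calib,
                            "ival_hash": ival_hash,
                        })
    result = ScalingResult(config=config, records=pd.DataFrame(rows), selected_dropout_rate=selected)
    if config.out_dir:
        render_report(result, config.out_dir)
    return result


# ---------------------------------------------------------------------------
# reporting


def _calibration_curves_frame(bundle: UQComparisonResult) -> pd.DataFrame:
    rows = []
    for ep, res in bundle.endpoints.items():
        for (method, measure), cal in res.calibration.items():
            df = cal.bin_stats.copy()
            df.insert(0, "endpoint", ep)
            df.insert(1, "method", method)
            df.insert(2, "measure", measure)
            rows.append(df)
    return pd.concat(rows, ignore_index=True)


def _sparsification_frame(bundle: UQComparisonResult) -> pd.DataFrame:
    rows = []
    for ep, res in bundle.endpoints.items():
        for (method, measure, metric), curve in res.sparsification_curves.items():
            df = pd.DataFrame({
                "endpoint": ep, "method": method, "measure": measure,
                "metric": metric, "fraction_removed": curve.fractions_removed,
                "value": curve.values,
            })
            rows.append(df)
    return pd.concat(rows, ignore_index=True)


def render_report(bundle, out_dir: str | Path) -> list[Path]:
    """Write tables (CSV + JSON) and figures (PNG) for a results bundle.

    Accepts a :class:`UQComparisonResult` or :class:`ScalingResult`.  File
    names are deterministic and CSV content is byte-identical across
    re-renders of the same bundle.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if isinstance(bundle, UQComparisonResult):
        if not bundle.endpoints:
            raise ValueError("empty results bundle")
        table = bundle.table()
        p = out / "comparison_table.csv"
        table.to_csv(p, index=False)
        written.append(p)
        p = out / "comparison_table.json"
        p.write_text(json.dumps(json.loads(table.to_json(orient="records")), indent=1))
        written.append(p)
        cal = _calibration_curves_frame(bundle)
        p = out / "calibration_curves.csv"
        cal.to_csv(p, index=False)
        written.append(p)
        spars = _sparsification_frame(bundle)
        p = out / "sparsification_curves.csv"
        spars.to_csv(p, index=False)
        written.append(p)
        for ep in bundle.endpoints:
            written.append(_plot_calibration_grid(cal[cal.endpoint == ep], ep, out, plt))
            written.append(_plot_sparsification(spars[(spars.endpoint == ep) & (spars.metric == "auc")], ep, out, plt))
    elif isinstance(bundle, ScalingResult):
        if bundle.records.empty:
            raise ValueError("empty results bundle")
        p = out / "scaling_records.csv"
        bundle.records.to_csv(p, index=False)
        written.append(p)
        summary = bundle.summary()
        p = out / "scaling_summary.csv"
        summary.to_csv(p, index=False)
        written.append(p)
        for (ep, method), df in summary.groupby(["endpoint", "method"]):
            written.append(_plot_scaling(df, ep, method, out, plt))
    else:
        raise TypeError(f"unsupported bundle type {type(bundle).__name__}")
    return written


def _plot_calibration_grid(cal: pd.DataFrame, endpoint: str, out: Path, plt) -> Path:
    fig, axes = plt.subplots(len(METHODS), len(MEASURES), figsize=(10, 9),
                             sharex=True, sharey=True, squeeze=False)
    for i, method in enumerate(METHODS):
        for j, measure in enumerate(MEASURES):
            ax = axes[i][j]
            df = cal[(cal.method == method) & (cal.measure == measure)]
            ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
            ax.plot(df["certainty"], df["accuracy"], marker="o")
            if i == 0:
                ax.set_title(measure)
            if j == 0:
                ax.set_ylabel(f"{method}\naccuracy")
            if i == len(METHODS) - 1:
                ax.set_xlabel("certainty (1 - uncertainty)")
    fig.suptitle(f"Certainty vs accuracy calibration — {endpoint}")
    fig.tight_layout()
    path = out / f"calibration_grid_{endpoint}.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def _plot_sparsification(spars: pd.DataFrame, endpoint: str, out: Path, plt) -> Path:
    fig, axes = plt.subplots(1, len(MEASURES), figsize=(12, 4), sharey=True, squeeze=False)
    for j, measure in enumerate(MEASURES):
        ax = axes[0][j]
        for method in METHODS:
            df = spars[(spars.method == method) & (spars.measure == measure)]
            ax.plot(df["fraction_removed"], df["value"], label=method)
        ax.set_title(measure)
        ax.set_xlabel("fraction removed")
        if j == 0:
            ax.set_ylabel("AUC on retained patients")
    axes[0][-1].legend(fontsize=8)
    fig.suptitle(f"Sparsification — {endpoint}")
    fig.tight_layout()
    path = out / f"sparsification_{endpoint}.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def _plot_scaling(summary: pd.DataFrame, endpoint: str, method: str, out: Path, plt) -> Path:
    # entropy lives on its own axis: raw variance/MI are typically an order
    # of magnitude smaller
    fig, ax_left = plt.subplots(figsize=(7, 4.5))
    ax_right = ax_left.twinx()
    for measure, ax in (("entropy", ax_left), ("variance", ax_right), ("mutual_information", ax_right)):
        df = summary[summary.measure == measure].sort_values("size")
        ax.errorbar(df["size"], df["unc_mean"], yerr=df["unc_mean_sd"].fillna(0.0),
                    marker="o", capsize=3, label=measure)
    ax_left.set_xlabel("training set size")
    ax_left.set_ylabel("mean binary entropy (bits)")
    ax_right.set_ylabel("mean variance / MI")
    h1, l1 = ax_left.get_legend_handles_labels()
    h2, l2 = ax_right.get_legend_handles_labels()
    ax_left.legend(h1 + h2, l1 + l2, fontsize=8)
    ax_left.set_title(f"Uncertainty vs training size — {endpoint}, {method}")
    fig.tight_layout()
    path = out / f"scaling_{endpoint}_{method}.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
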