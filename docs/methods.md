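# Methods

## Scope and design

`riskuq` evaluates three patient-level uncertainty-quantification (UQ)
methods and three uncertainty measures for binary clinical outcome
prediction models. The pipeline is model-agnostic: any probabilistic
binary classifier exposing a deterministic forward pass, a
dropout-perturbed forward pass and a training routine can be plugged in.
The bundled classifier is a small fully connected network; 3-D imaging
backbones used in clinical NTCP/TCP modelling are deliberately out of
scope, because every quantity studied here is a function of predicted
probabilities only.

## Synthetic cohorts

Real NTCP/TCP cohorts are private, so the package generates cohorts with
the same statistical skeleton and a known ground truth:

* Covariates: `n_continuous` standard-normal features (default 6) and
  `n_categorical` three-level multinomial features (default 2, level
  probabilities 0.5/0.3/0.2, one-hot encoded).
* Outcome model: logistic-linear, `P(y=1|x) = expit(b0 + x·beta)` —
  logistic because classical NTCP models are logistic. Default
  coefficients are moderate and mixed-sign (continuous pattern
  ±1.0…±0.2, categorical level offsets 0/±0.5, rotated per endpoint),
  giving a Bayes AUC around 0.75–0.80, typical of clinical toxicity
  models. They are free parameters of the generator, not estimates of any
  real cohort.
* Intercept calibration: `b0` is solved by Brent root-finding on a fixed
  200,000-draw Monte Carlo sample of the covariates so the marginal event
  rate hits the target prevalence (within 0.005; closed-form logit when
  all effects are zero). Default prevalences are 22% (dysphagia), 42%
  (xerostomia), 24% (2-year death) and 25% (2-year LRC failure).
* Label noise: optional independent symmetric flips with rate
  ρ ∈ [0, 0.5), modelling irreducible assessment variability in
  patient/physician-reported endpoints; the calibration accounts for it
  analytically (observed rate = π(1−2ρ) + ρ). Default 0.
* Splits: development/independent-validation 80/20 (NTCP-style) or 75/25
  (TCP-style), then train/valid 80/20 inside development. Split sizes use
  round-half-to-even on `fraction × n` (1205 → 964/241; 340 → 255/85).
* Covariate shift: affine offset/rescale of the continuous features, with
  labels regenerated from the shifted true probabilities through the
  cohort's stored latent uniforms, so the zero shift is exactly the
  identity.

The per-patient Bernoulli parameter is retained (`true_prob`), so the
aleatoric floor is known and the Bayes-optimal predictor is available as a
reference: no classifier should beat its AUC beyond sampling noise.

What the generator does **not** emulate: feature correlations and
interactions of real clinical data, informative missingness, imaging
information, calendar drift, or inter-institutional heterogeneity.
Passing results show the pipeline's statistical machinery behaves
correctly under a known generative model, not that any specific clinical
model is well calibrated.

## Classifier

Feed-forward network (default hidden sizes 16 and 8, ReLU), sigmoid
output, binary cross-entropy loss (no class reweighting), Adam
(lr 1e-3), mini-batches of 64, inverted dropout after every hidden layer
(default rate 0.2), max 500 epochs with early stopping on validation loss
(patience 20) and restoration of the best-validation parameters.
Probabilities are clamped to [1e-7, 1−1e-7] before any logarithm. One
integer seed drives initialisation, shuffling, dropout masks and
augmentation noise; fits are bit-reproducible. Training-time augmentation
uses the same policy as TTA.

## UQ methods

* **MC dropout**: dropout stays active at inference; T = 50 stochastic
  passes per patient. The dropout rate is selected from
  {0.1, 0.2, 0.3, 0.4, 0.5} by retraining one model per rate and scoring
  the AUC of the MC-mean prediction (T samples) on the validation split;
  ties go to the smaller rate. The same rate is used for training and
  inference.
* **Deep ensembles**: M = 10 models on identical train/valid splits,
  differing only in initialisation seed (which also drives mini-batch
  order — one knob per member); one deterministic prediction each.
* **TTA**: T = 50 augmented copies per patient through the baseline model
  with dropout off — TTA probes input randomness, not parameter
  randomness. Default policy: additive Gaussian noise σ = 0.3 on
  continuous features and category-preserving resampling with probability
  0.1 on categorical groups, chosen as perturbations comparable to
  measurement variability on standardized covariates.

For every method the final prediction is the mean of the samples.

## Uncertainty measures

Per patient, over the T samples with mean p̄:

* entropy: H(p̄) in bits (base 2, so the range is [0, 1]); the entropy of
  the mean is used, as the total-uncertainty companion of MI;
* variance: population form (divide by T — T is fixed by design, not an
  estimate of a larger sample); bounded by p̄(1−p̄) ≤ 0.25;
* mutual information: H(p̄) − (1/T) Σ H(p_t), non-negative by Jensen;
  values in (−1e-12, 0) from floating point are clamped to 0.

Variance and MI are min–max normalised to [0, 1] before calibration
analyses; the scaling bounds come from the cohort under evaluation (the
independent validation cohort), which makes those analyses comparative
rather than deployment calibrations. Entropy is used as-is.

## Evaluation conventions

* AUC via the Mann–Whitney formulation (ties count ½).
* Accuracy at threshold 0.5 by default; optionally at the Youden-J
  maximiser (candidate cuts are midpoints of consecutive distinct scores;
  ties resolve to the lowest threshold).
* DeLong test: structural-components covariance estimate for the paired
  AUC difference, two-sided normal p-value; a zero-variance, zero-difference
  comparison returns p = 1.
* ACE: equal-frequency bins over the predicted probability;
  the number of bins is min(15, ⌊n/25⌋) so every bin keeps at least 25
  patients on small cohorts while large cohorts use the conventional
  fixed number of adaptive ranges; bin confidence is the mean predicted
  probability (not the midpoint); ACE is the unweighted mean absolute
  confidence/observed gap; tied values never straddle a boundary.
* Certainty-vs-accuracy calibration: bins over certainty = 1 − normalised
  uncertainty, each bin's classification accuracy against its mean
  certainty, same ACE-style aggregate.
* Sparsification: patients sorted by descending uncertainty (ties broken
  by patient id for determinism), one removed per step, metric recomputed
  on the retained set, down to 50% removal; if AUC loses a class it is
  recorded as missing, never imputed.
* Bootstrap CIs: percentile, stratified by label, B = 1000 by default.

## Experiments

**Method × measure comparison** (`run_uq_comparison`): per endpoint,
trains baseline + the three UQ models, evaluates AUC/ACE with CIs and
DeLong tests on the independent validation cohort, then fills the nine
method × measure calibration cells and sparsification curves.

**Training-set-size experiment** (`training_size_experiment`): training
subsets grow by N patients at a time (N = 100 NTCP-style, N = 50
TCP-style), sampled without replacement from a per-repeat permutation of
the development cohort, so subsets are nested; sampling stops when fewer
than N unsampled patients remain (964 → 100…900; 255 → 50…250). The
early-stopping validation split and the independent validation cohort are
fixed throughout — the evaluation set is hashed in every cell. Because
the sampling pool is the whole development cohort, large subsets can
include early-stopping validation patients; early stopping is a training
heuristic and all reported metrics come from the untouched independent
validation cohort. The MC-dropout rate is selected once per endpoint on
the full development split and reused at every size (redoing the grid per
cell is configurable in principle but quadruples the cost for a
second-order effect). Reported per cell: mean/SD over patients of the raw
(un-normalised) uncertainty — scaling plots show raw scales, entropy on
its own axis — plus AUC and the certainty-accuracy calibration error;
R = 10 repeats by default.

Problem sizes used in the test suite and examples (1,200-patient cohorts,
hidden sizes 16/8, max 150 epochs, B = 200 bootstrap, R = 3 repeats) are
deliberately compact so a full run completes on a laptop CPU in seconds to
minutes; all defaults scale up through the config.

## Numerical and degenerate-input choices

* Exactly constant sample rows yield exactly zero variance (the naive
  two-pass variance leaves ~1e-34 residue, which would break the
  "no randomness ⇒ no uncertainty" contract).
* Degenerate min–max references (constant scores) normalise to all zeros
  with a warning rather than dividing by zero.
* MC dropout on a zero-dropout model warns and returns T identical
  deterministic columns.
* An unreachable prevalence under the requested label noise (target below
  the noise floor ρ or above 1−ρ) raises instead of silently mis-targeting.

## Known limitations

* The certainty-accuracy association is summarised over ~9 bins on
  240-patient validation cohorts; with so few bins, rank statistics have
  limited power, and the headline association is asserted for the entropy
  measure (bounded, no normalisation step) — variance and MI cells are
  reported but can be noisy or even inverted for MC dropout, as raw
  parameter-disagreement measures on small validation sets are unstable.
* Bootstrap CIs are percentile CIs; no BCa correction.
* The generator's effect sizes are package defaults, not clinical
  estimates; absolute AUC/ACE values on synthetic cohorts characterise
  the pipeline, not any clinical model.
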