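# Methods

This note documents the models implemented in `atnfuse`, the synthetic
data-generating process used to validate them, and the numerical and design
choices that were genuinely open.

## Supervised multimodal factorization

### Objective

For M modalities `X_m` (N subjects × P_m features) and a continuous target
`y`, the fitted decomposition minimizes

```
L = Σ_m a_m ‖X_m − Z diag(W_m) S_mᵀ‖²_F / (N P_m)
    + γ ‖y − Zβ − b₀‖² / N
    + λ₁ Σ_m ‖S_m‖₁ ,      a_m = 1/M.
```

The reconstruction terms are normalized per entry so modalities with
different feature counts contribute comparably; `γ` sets the
reconstruction/prediction trade-off and `λ₁` the map sparsity. `W` is
projected to nonnegativity after every optimizer step, so modality weights
remain interpretable as nonnegative energy shares. This squared-error +
L1 objective is a deliberately transparent surrogate for Bayesian linked
independent component analysis with an embedded supervision head: it
reproduces the same outputs (shared subject loadings, modality-specific
spatial maps, modality weights, prediction weights) with a fully testable
loss.

All features are z-scored per column on the **training split only**; the
stored means/SDs are reused for validation and test data. The target is
z-scored inside the optimizer (the head is returned in original target
units): without this, a target with variance ≫ 1 dominates the O(1)
standardized reconstruction terms and the free training loadings
interpolate target noise instead of staying anchored to the images.

### Identifiability and initialization

With modality-specific maps, the reconstruction term is invariant to any
invertible K × K mixing of `(Z, S)`; per-component identifiability comes
from map structure. Initialization is therefore: randomized truncated SVD
of the weighted concatenated training matrices, followed by a FastICA
unmixing of the concatenated maps, applied as an exact invertible
reparameterization (`S → S Cᵀ`, `Z → Z C⁻¹`) that leaves the initial
reconstruction untouched. Because realistic component maps are sparse and
heavy-tailed (hence non-Gaussian), the ICA rotation aligns the basis with
individual components where the plain SVD returns an arbitrary rotation of
the subspace. If ICA fails to converge the plain SVD basis is kept. The
prediction head is initialized by OLS of the training target on the initial
loadings.

### Optimization

Mini-batch Adam (batch `min(64, N_train)`, learning rate 0.01), up to 2,000
epochs with patience 50 by default (tests and the acceptance script use
smaller caps at their reduced problem sizes). Early stopping monitors the
validation prediction loss, computed on ridge-projected validation
loadings; when `γ = 0` or no validation split exists, the training total
loss is monitored instead. The best-metric snapshot is returned, and is
additionally guaranteed never to have a higher training loss than the
initialization (falling back to the initial snapshot otherwise). After
every epoch the loading columns are re-standardized (mean 0, variance 1 on
the training split), absorbing the scale into the maps and head and the
mean into the intercept, so predictions are unchanged.

Sign-flip equivalence holds exactly: negating a loading column together
with its map columns and β entry changes no loss term and no prediction.

### Projection of new subjects

Held-out loadings solve
`argmin_Z Σ_m (a_m/P_m) ‖X_m − Z diag(W_m) S_mᵀ‖²_F + ρ‖Z‖²_F`
in closed form (ρ = 1e-6). The per-feature weighting matches the training
objective so modalities with unequal feature counts keep the same relative
influence. Degenerate components (zero total map energy) are retained and
flagged, never silently dropped.

## Synthetic cohort generator

The generator emulates the structure of a multimodal Alzheimer's imaging
study and stores its full ground truth:

- **Latent structure**: `Z_true` iid standard normal; per-modality maps with
  a hard-zeroed uniform support (20% nonzero per column by default) and
  two-sided Gamma(3, 1) values — the signed heavy-tailed signal class the
  thresholding module is built to detect. Each component's modality-weight
  column is normalized to equal total energy (‖W[:,k]‖² = 2), so the
  nominal SNR applies to every component; components differ in how their
  energy is distributed across modalities (uni- vs multi-modal), not in
  overall strength.
- **Noise**: Gaussian, scaled per modality so the empirical
  var(signal)/var(noise) equals the requested `snr` exactly.
- **Sites and scanners**: site sizes from a symmetric Dirichlet-multinomial
  (12 sites by default); each site is assigned one scanner manufacturer
  round-robin (3 by default), so scanner is nested in site — the confound
  structure harmonization must remove. Batch effects are additive
  (per-feature Gaussian, SD 0.3 × noise SD) and multiplicative (log-normal,
  σ = 0.1) per scanner.
- **Target**: linear in a 3-component subset of the loadings plus Gaussian
  noise fixing the pre-clipping R² at 0.85, then rescaled so half the cohort
  clips to 0, clipped to [0, 18] and rounded to half points — reproducing
  the CDR-SOB banding arithmetic with a realistic cognitively-normal mass
  and a known prediction ceiling (population correlation between the latent
  signal and the observed banded score ≈ 0.79).
- **Diagnosis**: the CDR-SOB band of the stored target (0 → CN; 0.5–4 →
  MCI/SCD; 4.5–9 → mild; 9.5–15.5 → moderate; 16–18 → severe dementia).
- **Carrier label**: Bernoulli with logistic probability (slope 4.0) in one
  designated target-relevant component, intercept solved so the marginal
  prevalence is 40.5%; the implied Bayes-optimal AUROC of the true loading
  is ≈ 0.95, a strong single-component genetic-risk driver.
- **CSF biomarkers**: A-beta-42 and p-tau-181 correlated with the carrier
  component's loading (ρ = −0.40 and +0.50), plausible assay scales, draw
  offsets uniform in ±540 days, 23% missingness.
- **Demographics**: age mildly tracks the latent severity axis (ρ = 0.25);
  sex is independent.

Identical config + seed reproduces the dataset bit for bit.

What the generator does **not** emulate: spatial autocorrelation and surface
geometry (features are exchangeable columns), non-Gaussian imaging noise,
site-by-biology confounding, longitudinal structure, and missing modalities.
Passing tests therefore demonstrate correctness of the estimation machinery
under the stated generative assumptions, not performance on real cohorts.

## Site-grouped splitting

Sites are shuffled (seeded) and assigned greedily to the
train/validation/test split whose subject count is furthest below its
70/15/15 target; ties resolve train → val → test. All subjects of a site
share a split by construction. For 20 equal sites the realized train
fraction is always within [0.65, 0.75].

## ComBat harmonization

Parametric empirical-Bayes location–scale model: per-feature OLS of the
data on batch indicators (plus optional covariates), standardization by the
pooled residual SD, per-batch location γ̂ and scale δ̂² estimates, normal and
inverse-gamma method-of-moments hyperpriors, and iterated conditional
posterior updates of (γ*, δ*²) to 1e-6. Adjustment subtracts γ*, divides by
δ*, and restores the grand location/scale and covariate structure. Batch
variable: scanner manufacturer. The model is fit on training-split loadings
only and applied to all splits; an unseen batch level at apply time is an
error. γ* is parameterized relative to the weighted grand mean, so a ±2
planted shift appears as a between-batch γ* difference of ≈ 2 standardized
units. `tau_sq_scale` exposes the location-prior strength; shrinkage of γ*
toward the prior mean is monotone in it. Residual batch information is
quantified as stratified cross-validated AUROC of an L1-logistic batch
classifier (near 0.5 ⇒ harmonized).

## Mixture-model map thresholding

Each component map (internally standardized to zero mean, unit variance) is
modeled as Gaussian noise plus up to two offset-Gamma signal classes (one
positive, one mirrored negative — maps carry signed weights). For each
candidate structure {noise}, {noise+pos}, {noise+neg}, {noise+both}, EM runs
to convergence (tolerance 1e-7 on the relative log-likelihood) and the
structure with the lowest BIC is selected; this prevents spurious signal
classes on pure-noise maps. Numerical choices:

- initialization by quantile split: central 80% → noise moments, tails →
  Gamma moments;
- the Gamma offset is fixed at the initial noise-mean estimate so every
  update is a true M-step and the log-likelihood trace is monotone
  (the invariant is asserted in tests);
- Gamma shape is floored at 1.0 (bounded density at the offset); weighted
  shape MLE by Newton on `log α − ψ(α)`;
- after selection, a signal side is dropped (proportion → 0) when its
  support collapses (π < 1e-3 or < 5 effective features) **or** its fitted
  Gamma mean lies within 2 noise SDs of the noise mean — such a class
  models the noise flank, not signal.

A feature is retained when its total signal posterior exceeds `mmthresh`
(0.5 by default; 0 keeps every feature with nonzero posterior, 1 keeps
none; masks are monotone in the threshold and invariant to positive
rescaling of the map).

## Transfer classification and evaluation

Lasso-logistic classifiers (liblinear L1 path) with the penalty chosen by
stratified inner-CV minimum mean deviance over a log-spaced grid
(λ = 1/(C·n)); features are z-scored on the fitting data; the intercept is
refit unpenalized at the selected weights (the lasso convention — at full
shrinkage the classifier returns exactly the base-rate log-odds).
Diagnosis is handled as three one-vs-one pairwise tasks (CN vs MCI/SCD,
CN vs mild, MCI/SCD vs mild) whose metrics are macro-averaged; carrier
status is a fourth binary task. For each feature set × task: fit on the
training split, report pooled out-of-fold cross-validated training metrics
and held-out test AUROC/AUPRC, all with stratified nonparametric bootstrap
percentile CIs (resampling within class, so no resample is degenerate).
Tasks with an empty class in a split are reported as skipped. Thresholded
metrics use 0.5 on predicted probability. AUROC/AUPRC use the standard
rank/step-integration estimators and are verified in tests against
exhaustive pair-counting and manual step-integration oracles.

Comparator feature sets (all training-fit, applied to every subject, and
harmonized the same way as the fused loadings): demographics (age, sex),
per-modality PCA and FastICA scores, concatenated-modality PCs, and the ten
pooled per-modality PCs most correlated with the training target.

## Validation statistics

Per-component Pearson correlations with the target use t-distribution
two-sided p-values and Benjamini–Hochberg adjustment across the K
components; the significance flag is q < 0.05 (the conventional level).
CSF eligibility: draws within 365 days (inclusive) of the imaging visit;
nearest draw wins; exact ties go to the earlier draw — deterministic and
auditable.

## Problem sizes in the test and acceptance batteries

The reference-scale study uses N = 400 subjects, five modalities of 2,000
features, rank-6 truth at SNR 5 — large enough that subspace recovery is
stable while a full fit takes seconds. The stability grid (9
dimensionalities × 5 seeds) and the 20-replicate carrier-transfer study run
at reduced sizes (N = 160–260, 120–300 features) chosen so the full battery
completes in minutes on one CPU; the properties they check (determinism,
grid completeness, selection of the planted component, permutation-null
behavior) are size-insensitive.

## Known limitations

- The fusion loss is a surrogate: it shares the outputs and the
  semi-supervised structure of Bayesian linked-ICA-with-supervision
  approaches but not their priors, dropout, or automatic relevance
  determination; K must be chosen by the user (the stability harness
  supports sensitivity analysis).
- Free training loadings can drift toward target noise on long runs if the
  validation signal is weak; early stopping and the scale-balanced
  objective mitigate but do not eliminate this.
- ComBat assumes location–scale batch effects with exchangeable features;
  nonparametric and longitudinal variants are out of scope.
- The mixture model treats features as exchangeable; no spatial smoothing
  or cluster-extent inference.
- With few subjects per class in a split, bootstrap CIs and thresholded
  metrics are noisy; the machinery reports them but cannot rescue tiny
  samples.
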