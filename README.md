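# atnfuse

Semi-supervised multimodal neuroimaging fusion for studying the
amyloid–tau–neurodegeneration (A–T–N) framework in Alzheimer's disease.

Clinical severity in cognitive aging is shaped by processes that different
imaging modalities see only partially: structural MRI measures
neurodegeneration (gray matter density, cortical thickness, pial surface
area), while PET measures molecular pathology (amyloid Centiloid, tau SUVR).
`atnfuse` jointly decomposes several subject-by-feature modality matrices
into latent components that are simultaneously good at reconstructing the
images and at predicting a continuous clinical score (CDR-SOB, the Clinical
Dementia Rating Sum of Boxes, 0–18), then carries the resulting subject
loadings through batch harmonization, spatial-map thresholding, transfer
classification of diagnosis and *APOE* ε4 carrier status, and CSF-biomarker
validation. A synthetic-cohort generator with known ground truth makes every
stage testable end to end.

It is written for neuroimaging methodologists who want a transparent,
fully linear, auditable alternative to black-box multimodal predictors.

## The model

Given M modality matrices `X_m` (subjects × features, z-scored per feature
on the training split) and a target `y`, the fusion model minimizes

```
L = Σ_m a_m ‖X_m − Z diag(W_m) S_mᵀ‖²_F / (N P_m)
    + γ ‖y − Z β − b₀‖² / N
    + λ₁ Σ_m ‖S_m‖₁ ,        a_m = 1/M
```

over shared subject loadings `Z` (N × K, column-standardized), per-modality
sparse spatial maps `S_m` (P_m × K), nonnegative modality weights `W_m`
(how uni- or multi-modal each component is), and a linear prediction head
(β, b₀). Optimization is mini-batch Adam from a randomized-SVD + ICA-unmixed
initialization, with early stopping on validation prediction loss.
Held-out subjects get loadings by closed-form ridge projection — the whole
mapping from images to prediction stays linear and inspectable.

Around this core:

- **site-grouped splits** (70/15/15) keep all subjects of an imaging site in
  one split;
- **ComBat** (parametric empirical-Bayes location–scale model) removes
  scanner-manufacturer effects from the loadings;
- **mixture-model thresholding** fits a Gaussian noise class plus offset-Gamma
  signal classes to each spatial map by EM and keeps features with signal
  posterior > `mmthresh` (0.5 by default);
- **lasso-logistic transfer classifiers** predict pairwise diagnosis bands
  and carrier status from the harmonized loadings, benchmarked against
  demographics, per-modality PCA/ICA, concatenated PCs and a
  target-correlated top-10-PC combo, with the full macro-averaged metric
  battery and stratified bootstrap CIs;
- **a correlation screen** relates every component to the clinical score
  with Benjamini–Hochberg FDR control, and CSF A-beta-42 / p-tau-181
  associations use only draws within one year of the imaging visit.

## Worked example

```python
import atnfuse as af
from scipy.stats import pearsonr

cfg = af.SimulationConfig(n_subjects=400, n_modalities=5,
                          features_per_modality=2000, k_true=6,
                          snr=5.0, seed=1)
ds = af.generate_dataset(cfg)                       # known ground truth
sp = af.grouped_split(ds.site, seed=1)              # site-grouped 70/15/15
res = af.SupervisedFusion(ds, sp, 6,
                          af.FusionHyperparams(max_epochs=150, patience=25,
                                               seed=1)).fit()
print(res.summary())

perm, vals = af.match_components(res.Z, ds.truth.loadings_true[sp.train])
print("mean matched |r|:", round(vals.mean(), 3))
pred = res.predict(Z=res.loadings_for("test"))
print("held-out r:", round(pearsonr(pred, ds.target[sp.test])[0], 3))
```

prints (abridged):

```
Supervised multimodal fusion results
====================================================
components (K):        6
modalities:            GM, CT, PSA, AMY, TAU
subjects (train/val/test): 270/77/53
...
predicted-vs-observed target r (test): 0.740
mean matched |r|: 0.996
held-out r: 0.74
```

The matched correlation (0.996) says the six estimated subject-loading
columns are essentially the planted ones; the held-out r (0.74) sits near
the simulation's design ceiling (≈ 0.79 in expectation, with spread from
the ~50-subject test split), i.e. the model recovers nearly all
recoverable signal. Downstream:

```python
Z = res.loadings_all()
cb = af.fit_combat(Z[sp.train], ds.scanner[sp.train])
Zh = cb.transform(Z, ds.scanner)                    # harmonized loadings
print(af.correlation_screen(Zh, ds.target).summary())
```

A command-line interface mirrors the library
(`atnfuse simulate | split | fit | project | harmonize | threshold |
classify | validate | run | report`); `atnfuse run --config cfg.yaml
--out-dir out/` executes the whole pipeline and writes a checksummed
manifest.

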