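# Methods note

This note records the statistical model, the parameter defaults and their
rationale, what the synthetic data generator does and does not emulate, and
the numerical conventions the implementation commits to. No claim here goes
beyond what the test suite and `scripts/acceptance.py` compute.

## 1. Spectral binning (`binning`)

A spectrum is a finite, strictly monotone ppm axis with intensities
(descending axes are accepted and flipped). Features are integrals of the
piecewise-linear interpolant over fixed bins:

- **Regions** [0.80, 4.20) ∪ [5.20, 8.50) ppm, **bin width** 0.02 ppm →
  170 + 165 = **335 bins**. The 4.20–5.20 ppm gap excludes residual water
  signal; the outer limits bracket the usual CSF metabolite window.
- Integration uses a precomputed trapezoid quadrature weight matrix, so the
  result is *exact* (to rounding) for piecewise-linear spectra whose
  breakpoints lie on the grid, and binning a cohort on a shared grid is a
  single matrix product. The spectrum must cover every region; coverage and
  grid-resolution failures abort with the offending interval named.
- **Normalisation** `unit_total` divides each row by its total so profiles
  are comparable across acquisition scaling; a zero-total row is an error
  naming the sample. `none` keeps raw integrals.

## 2. Synthetic cohort generator (`synth`)

Spectra are sums of Lorentzian lines A·w²/((x−c)² + w²) over a 12-peak
table spanning 1.33–8.45 ppm (half-width 0.005 ppm), plus a flat baseline
(0.05) and i.i.d. Gaussian noise (sd 0.05) on a 0.001-ppm grid covering
0.78–8.52 ppm. Defaults:

- **n_per_class = (34, 74)** — the unbalanced two-cohort design the
  validation machinery is built for.
- **Planted effects**: class 0 multiplies the amplitudes of the
  myo-inositol-like peak (3.61 ppm) and the formate-like peak (8.45 ppm) by
  1.5. After binning and unit-total normalisation this produces a
  well-over-1-pooled-SD effect in the two corresponding bins at the default
  noise level.

The generator emulates *structure*, not physics: there is no chemical-shift
jitter, phase/baseline distortion, peak overlap beyond Lorentzian tails, or
correlated noise. It exists to give the pipeline a ground truth (which bins
carry signal, which labels are exchangeable), not to simulate an instrument.

Binary phenotype profiles are Bernoulli draws from per-cluster probability
profiles: 41 patients in clusters of **6 / 14 / 21** over **36 features**
(12 MS-typical at 0.85 in the MS cluster, 12 NMOSD-typical at 0.85, 12
shared at 0.40/0.40/0.15, off-block 0.10). The cluster sizes fix the ANOVA
degrees of freedom (2, 38) used downstream.

## 3. Phenotype PCA (`phenotype_pca`)

PCA is the SVD of the centered, column-scaled (ddof = 1) matrix. Constant
columns are an error naming the features. Sign convention: each component's
largest-magnitude loading is made positive, so results are deterministic.
Explained variance fractions are s²/Σs². New profiles are projected with the
*training* means and scales. A k-means surrogate (first two score
dimensions, `n_init=10`, fixed seed) yields cluster labels renumbered by
descending cluster size so output labels are stable.

## 4. OPLS-DA and VIP (`oplsda_core`)

Implemented from scratch via NIPALS (one predictive + `n_orthogonal`
orthogonal components; default 1, appropriate when a single systematic
nuisance direction dominates). Column scaling: `unit_variance` (default),
`pareto`, or `center`. The class code is y ∈ {0, 1}; prediction thresholds
fitted ŷ at **0.5**, the midpoint of the codes. Degenerate cases abort:
fewer or more than two classes, constant columns under scaling, and
‖Xᵀy_c‖ ≈ 0 ("no predictive direction"). A structural identity the tests
rely on: orthogonal deflation leaves Xᵀy unchanged, so the predictive
weights satisfy w ⊥ w_o exactly, and the fitted values equal those of a
(k+1)-component PLS1 model — an independently coded oracle.

VIP uses the standard weighted-sum-of-squares form; because orthogonal
components carry essentially zero y-variance, the `total` and
`predictive_only` variants coincide (asserted in tests). The reporting
cutoff is **VIP ≥ 1.75**, a conservative choice above the conventional 1.0;
ties are broken by ascending bin position for determinism.

## 5. Validation (`validation_suite`)

- `balance_classes` undersamples the majority to the minority size
  (seeded, sorted indices) — preferable to reweighting at these sample
  sizes because it keeps the classifier and its CV folds symmetric.
- `cv_ensemble`: each iteration draws a fresh balanced subsample and a
  fresh stratified k-fold split, fits OPLS-DA per fold, and records
  held-out accuracy → k_folds × n_iterations accuracies (default 10 × 100 =
  1,000). `permutation_ensemble` is identical except labels are permuted
  once per iteration *before* balancing, so the null preserves every other
  aspect of the procedure.
- `compare_ensembles` reports a Welch t-test plus a distribution-free
  summary (fraction of null accuracies ≥ the observed mean). Note the
  accuracies within one dataset are correlated; the ensemble mean of a
  single pure-noise dataset fluctuates around 0.5 with sd ≈ 0.05, so
  calibration claims are made about averages over replicate datasets, and
  the distribution-free rejection rate — not the t-test — is the guarded
  error rate.
- `roc_auc` computes AUC by midranks (identical to Mann–Whitney
  U/(n⁺n⁻)), with a DeLong confidence interval by default and a stratified
  bootstrap option (seeded).

## 6. Group statistics (`group_stats`)

Two-group comparison with `auto` gating: Shapiro–Wilk at α = 0.05 in both
groups selects pooled t, otherwise Mann–Whitney (zero-range groups go
straight to the rank test). Mann–Whitney is exact by full enumeration when
both groups have ≤ 8 observations (two-sided by distance of U from its
center, valid under ties), otherwise a tie-corrected normal approximation
*without* continuity correction. Three-group analysis: one-way ANOVA from
explicit sums of squares with Tukey–Kramer adjusted pairwise contrasts
(studentized-range distribution), or Kruskal–Wallis. Categorical tables use
chi-square without Yates correction, or Fisher's exact test (2×2,
point-probability rule); `auto` picks Fisher when a 2×2 table has any
expected count < 5. `confounder_screen` runs the appropriate test per
covariate, reports non-evaluable rows instead of aborting, and optionally
adds Benjamini–Hochberg adjusted p-values. Degenerate inputs (identical
groups) return statistic 0 and p = 1 rather than NaN.

## 7. Pipeline and determinism (`pipeline_io`)

Configuration is a validated dataclass tree, round-trippable through
YAML/JSON; unknown keys are rejected by name. All randomness flows from one
integer seed; each stage derives an independent substream seed as
`SeedSequence([seed mod 2³¹, crc32(stage_name)])`, so stages are decoupled
and all derived seeds stay below 2³¹. Reruns with the same seed are
byte-identical for every numeric artifact (the run record additionally
stores a wall-clock timestamp, config snapshot, seeds, and SHA-256 digests
of all outputs). Workflow errors are wrapped with the failing stage named.

## Limitations

- The generator's simplifications (no shift jitter, no peak overlap beyond
  tails, flat baseline) make recovery easier than on real spectra; recovery
  rates reported by the acceptance script are upper bounds in that sense.
- OPLS-DA here is binary-only with a single y; multi-class and multi-block
  variants are out of scope.
- The DeLong interval is asymptotic and degenerates (zero width) at
  AUC = 1; the bootstrap option is preferable near the boundary.
- Exact Mann–Whitney enumeration is limited to ≤ 8 per group for cost; the
  normal approximation beyond that omits continuity correction by design
  (matching the tie-corrected asymptotic convention).
- Repeated-CV accuracies are not independent; treat the Welch p-value as
  descriptive and rely on the distribution-free comparison for inference.
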