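# chemoclass

Multivariate classification and validation tools for small-cohort
CSF metabolomics, motivated by the problem of distinguishing
antibody-negative neuromyelitis-optica-spectrum-disorder (NMOSD) syndromes
from relapsing-remitting multiple sclerosis (RRMS).

## The scientific problem

A minority of patients with an NMO-like syndrome test negative for both
AQP4 and MOG antibodies, and misclassifying them against RRMS has real
treatment consequences. Two complementary data types can help:

1. **¹H-NMR spectra of cerebrospinal fluid.** Spectra are reduced to
   0.02-ppm bins over [0.80, 4.20) ∪ [5.20, 8.50) ppm (335 bins, the
   water-suppression region excluded), normalised to unit total per sample,
   and classified with orthogonal partial least squares discriminant
   analysis (OPLS-DA). Discriminatory bins are ranked by
   variable importance in projection (VIP), with 1.75 as the reporting
   cutoff.
2. **Binary clinical phenotype profiles.** A small patient-by-feature 0/1
   matrix is explored with PCA on the scaled data; new patients are placed
   by projecting into the trained component space, and a k-means surrogate
   on the score plane recovers phenotype groups.

Because cohorts are small and unbalanced (e.g. 34 vs 74), validation is the
core of the package: classes are rebalanced by undersampling, performance is
summarised over repeated stratified k-fold cross-validation
(k_folds × n_iterations held-out accuracies), and the identical machinery is
re-run on permuted labels to give an honest chance-level reference.

## The model in brief

OPLS-DA is fit by NIPALS: the predictive weight vector is
w ∝ Xᵀy (unit norm); each orthogonal component captures X-variation
uncorrelated with y (loading p, orthogonal weight w_o ∝ p − (wᵀp)w) and is
deflated from X before the final predictive component t = Xw,
q = yᵀt / tᵀt. Predicted class is 1 when ŷ = q·(x_new·w) + ȳ ≥ 0.5 after
stripping orthogonal variation from x_new. VIP for feature j is

VIP_j = sqrt( p · Σ_a SS_a (w_aj / ‖w_a‖)² / Σ_a SS_a ),  SS_a = q_a² t_aᵀt_a,

so mean(VIP²) = 1 by construction. See `docs/methods.md` for assumptions,
parameter defaults, and numerical choices.

## Worked example

The package ships a synthetic spectrum generator whose defaults mirror the
study conditions (34 vs 74 samples; class 0 carries a 1.5-fold boost of a
myo-inositol-like peak at 3.61 ppm and a formate-like peak at 8.45 ppm):

```python
from chemoclass import (SpectraConfig, generate_feature_matrix,
                        balance_classes, fit_oplsda, vip_scores, rank_vip,
                        cv_ensemble, permutation_ensemble, compare_ensembles)

fm, labels = generate_feature_matrix(SpectraConfig(seed=0))   # 108 x 335
idx = balance_classes(labels, seed=1)                         # 68 samples
model = fit_oplsda(fm.values[idx], labels[idx], n_orthogonal=1)
for i, _, v in rank_vip(vip_scores(model), threshold=1.75)[:2]:
    print(f"{fm.bin_centers[i]:.2f} ppm: VIP = {v:.2f}")

obs = cv_ensemble(fm.values, labels, k_folds=10, n_iterations=25, seed=1)
null = permutation_ensemble(fm.values, labels, k_folds=10, n_iterations=25, seed=2)
cmp = compare_ensembles(obs, null)
print(f"observed {obs.mean:.1%} [{obs.sd:.1%}] vs null {null.mean:.1%}, "
      f"Welch p = {cmp.p_value:.3g}")
```

Output:

```
3.61 ppm: VIP = 5.43
8.45 ppm: VIP = 5.36
observed 98.5% [4.7%] vs null 48.6%, Welch p = 3.97e-110
```

The two planted bins rank first and second, and the cross-validated
accuracy separates cleanly from the permutation null. The `examples/`
directory contains one short script per capability (simulation, binning,
phenotype PCA, OPLS-DA/VIP, validation ensembles, group statistics, and the
full file-based pipeline); each prints the numbers it computes. A thin CLI
mirrors the pipeline: `chemoclass run-all --seed 7 --out-dir out/`.

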