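"""Fit OPLS-DA on the binned cohort and rank bins by VIP.

The classes are balanced by undersampling the majority before fitting; the
variable-importance-in-projection score flags the bins that drive the
predictive component (VIP >= 1.75 is the reporting cutoff).
"""

from chemoclass import (
    SpectraConfig,
    balance_classes,
    fit_oplsda,
    generate_feature_matrix,
    predict,
    rank_vip,
    vip_scores,
)

fm, labels = generate_feature_matrix(SpectraConfig(seed=0))
idx = balance_classes(labels, seed=1)
model = fit_oplsda(fm.values[idx], labels[idx], n_orthogonal=1)

yhat, assigned = predict(model, fm.values)
print(f"Trained on {idx.size} balanced samples; "
      f"training-cohort accuracy {(assigned == labels).mean():.1%}")

vip = vip_scores(model)
print(f"sum(VIP^2) = {float((vip.vip ** 2).sum()):.4f} "
      f"(always equals the number of bins, {vip.vip.size})")
print("Bins above the VIP cutoff of 1.75:")
for bin_index, _, score in rank_vip(vip, threshold=1.75)[:5]:
    print(f"  bin {bin_index:3d} at {fm.bin_centers[bin_index]:.2f} ppm: "
          f"VIP = {score:.2f}")
print("  ... (planted discriminators at 3.61 and 8.45 ppm rank first)")
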