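"""Reduce spectra to a 335-bin feature matrix.

Bins are 0.02-ppm trapezoid integrals over [0.80, 4.20) and [5.20, 8.50),
skipping the water-suppression gap, then row-normalised to unit total.
"""

import numpy as np

from chemoclass import (
    SpectraConfig,
    build_feature_matrix,
    default_binspec,
    generate_spectra,
)

spectra, labels = generate_spectra(SpectraConfig(seed=0))
binspec = default_binspec()
fm = build_feature_matrix(spectra, binspec, normalization="unit_total")

print(f"Feature matrix: {fm.values.shape[0]} samples x {fm.values.shape[1]} bins")
print(f"Bin centers span {fm.bin_centers.min():.2f}-{fm.bin_centers.max():.2f} ppm; "
      "nothing between 4.20 and 5.20 ppm (water gap)")
print(f"Every row sums to 1 after unit-total normalisation: "
      f"max deviation {abs(fm.values.sum(axis=1) - 1).max():.2e}")
lactate_bin = int(np.argmin(abs(fm.bin_centers - 1.33)))
print(f"The lactate-like bin at 1.33 ppm carries the largest share: "
      f"{fm.values[0, lactate_bin]:.4f} of sample 0's total signal")
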