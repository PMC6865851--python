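"""Synthetic NMR-like spectra and binary phenotype matrices with known truth.

Spectra are sums of Lorentzian lines at metabolite-like chemical shifts, a
constant baseline, and i.i.d. Gaussian noise on the intensity grid.  A small
set of "planted" peaks is multiplicatively shifted in chosen classes so that
discriminant models have a known answer to recover.  The defaults emulate a
two-class plasma cohort of 34 vs 74 samples with two discriminatory peaks
(a myoinositol-like line near 3.60 ppm and a formate-like line near 8.45 ppm)
elevated 1.5-fold in the smaller class.

Binary phenotype matrices are Bernoulli draws from per-cluster probability
profiles over 36 indicator features; the defaults emulate a 41-patient cohort
with latent clusters of sizes 6 / 14 / 21.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .binning import BinSpec, FeatureMatrix, Spectrum, build_feature_matrix
from .pca import BinaryPhenotypeMatrix

__all__ = [
    "SpectraConfig",
    "PhenotypeConfig",
    "DEFAULT_PEAK_TABLE",
    "DEFAULT_PLANTED_EFFECTS",
    "default_cluster_profiles",
    "generate_spectra",
    "generate_feature_matrix",
    "generate_binary_phenotypes",
]

# (center_ppm, half-width-at-half-max ppm, base amplitude); widths of 0.005 ppm
# keep each line essentially inside a single 0.02-ppm bin.
DEFAULT_PEAK_TABLE: tuple[tuple[float, float, float], ...] = (
    (1.330, 0.005, 2.0),   # lactate-like
    (1.480, 0.005, 0.8),   # alanine-like
    (1.690, 0.005, 0.5),   # arginine/lysine/leucine-like
    (1.920, 0.005, 0.6),   # acetate-like
    (2.690, 0.005, 0.5),   # citrate-like
    (3.050, 0.005, 0.9),   # creatinine-like
    (3.210, 0.005, 0.7),   # choline-like
    (3.410, 0.005, 1.2),   # glucose-like
    (3.610, 0.005, 0.8),   # myoinositol-like  (planted discriminator)
    (3.770, 0.005, 0.9),   # glucose/alanine-like
    (7.050, 0.005, 0.3),   # histidine-like
    (8.450, 0.005, 0.4),   # formate-like      (planted discriminator)
)

# (peak_index, class_index, multiplicative_shift): both discriminators are
# elevated in class 0, the smaller class, mirroring metabolites higher in the
# smaller disease group.
DEFAULT_PLANTED_EFFECTS: tuple[tuple[int, int, float], ...] = (
    (8, 0, 1.5),
    (11, 0, 1.5),
)

MYOINOSITOL_PEAK_INDEX = 8
FORMATE_PEAK_INDEX = 11


@dataclass
class SpectraConfig:
    """Ground-truth recipe for a simulated two-or-more-class spectral cohort."""

    n_per_class: tuple[int, ...] = (34, 74)
    ppm_grid_step: float = 0.001
    ppm_min: float = 0.78
    ppm_max: float = 8.52
    peak_table: tuple[tuple[float, float, float], ...] = DEFAULT_PEAK_TABLE
    planted_effects: tuple[tuple[int, int, float], ...] = DEFAULT_PLANTED_EFFECTS
    noise_sd: float = 0.05
    baseline_level: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.n_per_class = tuple(int(n) for n in self.n_per_class)
        if not self.n_per_class or any(n <= 0 for n in self.n_per_class):
            raise ValueError("n_per_class must be a nonempty list of positive counts")
        if not self.peak_table:
            raise ValueError("peak_table must not be empty")
        for c, w, a in self.peak_table:
            if w <= 0:
                raise ValueError(f"peak at {c} ppm has nonpositive width {w}")
        for pk, cls, shift in self.planted_effects:
            if not 0 <= pk < len(self.peak_table):
                raise ValueError(f"planted effect references unknown peak index {pk}")
            if not 0 <= cls < len(self.n_per_class):
                raise ValueError(f"planted effect references unknown class index {cls}")
            if shift <= 0:
                raise ValueError("multiplicative_shift must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.ppm_grid_step <= 0:
            raise ValueError("ppm_grid_step must be positive")

    @property
    def n_classes(self) -> int:
        return len(self.n_per_class)

    def class_amplitudes(self) -> np.ndarray:
        """Per-class peak amplitudes after applying planted shifts."""
        amp = np.tile([a for _, _, a in self.peak_table], (self.n_classes, 1))
        for pk, cls, shift in self.planted_effects:
            amp[cls, pk] *= shift
        return amp


def _lorentzian_basis(ppm: np.ndarray, peak_table) -> np.ndarray:
    """Unit-amplitude Lorentzian lines A=1: w^2 / ((x - c)^2 + w^2), one row per peak."""
    basis = np.empty((len(peak_table), ppm.size))
    for i, (c, w, _a) in enumerate(peak_table):
        basis[i] = w * w / ((ppm - c) ** 2 + w * w)
    return basis


def generate_spectra(config: SpectraConfig) -> tuple[list[Spectrum], np.ndarray]:
    """Simulate spectra; returns (spectra, integer class labels).

    Each spectrum is sum_k A_k * w_k^2 / ((x - c_k)^2 + w_k^2) with A_k scaled
    by the sample's class shift, plus the constant baseline and N(0, noise_sd)
    noise per grid point.  Reproducible given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_steps = int(round((config.ppm_max - config.ppm_min) / config.ppm_grid_step))
    ppm = config.ppm_min + config.ppm_grid_step * np.arange(n_steps + 1)
    basis = _lorentzian_basis(ppm, config.peak_table)
    clean = config.class_amplitudes() @ basis + config.baseline_level

    spectra: list[Spectrum] = []
    labels: list[int] = []
    i = 0
    for cls, n in enumerate(config.n_per_class):
        for _ in range(n):
            intensity = clean[cls]
            if config.noise_sd > 0:
                intensity = intensity + rng.normal(0.0, config.noise_sd, size=ppm.size)
            spectra.append(Spectrum(ppm=ppm, intensity=np.asarray(intensity, dtype=float).copy(),
                                    sample_id=f"S{i:03d}"))
            labels.append(cls)
            i += 1
    return spectra, np.array(labels)


def generate_feature_matrix(
    config: SpectraConfig,
    binspec: BinSpec | None = None,
    normalization: str = "unit_total",
) -> tuple[FeatureMatrix, np.ndarray]:
    """generate_spectra composed with binning; labels are attached to the matrix."""
    spectra, labels = generate_spectra(config)
    fm = build_feature_matrix(spectra, binspec=binspec, normalization=normalization,
                              labels=labels)
    return fm, labels


def default_cluster_profiles(n_features: int = 36) -> tuple[np.ndarray, ...]:
    """Block Bernoulli profiles for three latent clusters.

    Features split into an "MS-like" block, an "NMOSD-like" block, and a
    background block; each disease-like cluster is enriched (p=0.85) in its
    own block, and the third cluster is globally sparse (the low-lesion-load
    pattern).
    """
    third = n_features // 3
    ms = np.full(n_features, 0.10)
    ms[:third] = 0.85
    ms[2 * third:] = 0.40
    nmo = np.full(n_features, 0.10)
    nmo[third: 2 * third] = 0.85
    nmo[2 * third:] = 0.40
    lbl = np.full(n_features, 0.10)
    lbl[2 * third:] = 0.15
    return ms, nmo, lbl


@dataclass
class PhenotypeConfig:
    """Recipe for a clustered binary clinico-radiologic matrix."""

    cluster_sizes: tuple[int, ...] = (6, 14, 21)
    n_features: int = 36
    cluster_probability_profiles: tuple[np.ndarray, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.cluster_sizes = tuple(int(n) for n in self.cluster_sizes)
        if not self.cluster_sizes or any(n <= 0 for n in self.cluster_sizes):
            raise ValueError("cluster_sizes must be positive")
        if self.cluster_probability_profiles is None:
            self.cluster_probability_profiles = tuple(
                default_cluster_profiles(self.n_features)[: len(self.cluster_sizes)]
            )
            if len(self.cluster_probability_profiles) != len(self.cluster_sizes):
                raise ValueError(
                    "default profiles cover 3 clusters; pass explicit profiles "
                    f"for {len(self.cluster_sizes)} clusters"
                )
        profiles = tuple(np.asarray(p, dtype=float) for p in self.cluster_probability_profiles)
        if len(profiles) != len(self.cluster_sizes):
            raise ValueError("one probability profile per cluster is required")
        for p in profiles:
            if p.shape != (self.n_features,):
                raise ValueError("each probability profile must have length n_features")
            if np.any(p < 0) or np.any(p > 1):
                raise ValueError("Bernoulli probabilities must lie in [0, 1]")
        self.cluster_probability_profiles = profiles


def generate_binary_phenotypes(
    config: PhenotypeConfig,
) -> tuple[BinaryPhenotypeMatrix, np.ndarray]:
    """Draw a patients x features 0/1 matrix; returns (matrix, cluster labels)."""
    rng = np.random.default_rng(config.seed)
    rows = []
    labels = []
    for cls, (n, p) in enumerate(zip(config.cluster_sizes, config.cluster_probability_profiles)):
        rows.append((rng.random((n, config.n_features)) < p).astype(float))
        labels.extend([cls] * n)
    values = np.vstack(rows)
    third = config.n_features // 3
    names = (
        [f"ms_feat_{i + 1:02d}" for i in range(third)]
        + [f"nmosd_feat_{i + 1:02d}" for i in range(third)]
        + [f"shared_feat_{i + 1:02d}" for i in range(config.n_features - 2 * third)]
    )
    matrix = BinaryPhenotypeMatrix(
        values=values,
        patient_ids=[f"P{i:03d}" for i in range(values.shape[0])],
        feature_names=names,
    )
    return matrix, np.array(labels)
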