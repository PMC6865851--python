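"""Spectral binning: turn processed 1D NMR spectra into a feature matrix.

A spectrum is an (ppm, intensity) curve; features are trapezoidal integrals
of the curve over fixed-width chemical-shift bins, expressed in arbitrary
units (AU).  The default bin layout covers 0.80-4.20 and 5.20-8.50 ppm in
0.02-ppm bins (335 bins); the 4.20-5.20 ppm gap excludes the residual water
resonance.  Integrals may optionally be normalized per spectrum to unit
total area, which makes features scale-free across samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "BinSpec",
    "FeatureMatrix",
    "default_binspec",
    "bin_spectrum",
    "build_feature_matrix",
    "read_spectrum_csv",
    "read_spectra_wide_csv",
    "write_spectrum_csv",
]

_MULT_TOL = 1e-9


@dataclass
class Spectrum:
    """One sample's 1D spectrum: a strictly monotone ppm axis plus intensities."""

    ppm: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("ppm and intensity must be 1-D arrays")
        if self.ppm.size != self.intensity.size:
            raise ValueError(
                f"ppm and intensity lengths differ ({self.ppm.size} vs {self.intensity.size})"
            )
        if self.ppm.size < 2:
            raise ValueError("a spectrum needs at least two grid points")
        if not (np.isfinite(self.ppm).all() and np.isfinite(self.intensity).all()):
            raise ValueError("spectrum contains non-finite values")
        d = np.diff(self.ppm)
        if np.all(d > 0):
            pass
        elif np.all(d < 0):  # stored high-field last; normalize to ascending
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        else:
            raise ValueError(f"ppm axis of sample {self.sample_id!r} is not strictly monotone")


@dataclass(frozen=True)
class BinSpec:
    """Disjoint ppm regions split into fixed-width bins.

    Regions are half-open ``[start, end)`` intervals whose lengths must be
    integer multiples of ``bin_width``.  Bins are ordered by ascending ppm
    within each region, with regions concatenated in ascending order.
    """

    regions: tuple[tuple[float, float], ...] = ((0.80, 4.20), (5.20, 8.50))
    bin_width: float = 0.02

    def __post_init__(self) -> None:
        regions = tuple(sorted((float(a), float(b)) for a, b in self.regions))
        if not regions:
            raise ValueError("at least one region is required")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        for a, b in regions:
            if not a < b:
                raise ValueError(f"region ({a}, {b}) must have start < end")
            n = (b - a) / self.bin_width
            if abs(n - round(n)) * self.bin_width > _MULT_TOL:
                raise ValueError(
                    f"region ({a}, {b}) length is not an integer multiple of "
                    f"bin_width={self.bin_width}"
                )
        for (a1, b1), (a2, b2) in zip(regions, regions[1:]):
            if b1 > a2 + _MULT_TOL:
                raise ValueError(f"regions ({a1}, {b1}) and ({a2}, {b2}) overlap")
        object.__setattr__(self, "regions", regions)

    def _region_counts(self) -> list[int]:
        return [int(round((b - a) / self.bin_width)) for a, b in self.regions]

    @property
    def n_bins(self) -> int:
        return sum(self._region_counts())

    def bin_edges(self) -> list[np.ndarray]:
        """Per region, the ``n+1`` bin edge positions."""
        return [
            a + self.bin_width * np.arange(n + 1)
            for (a, _), n in zip(self.regions, self._region_counts())
        ]

    def bin_centers(self) -> np.ndarray:
        """Centers of all bins, concatenated in bin order."""
        return np.concatenate(
            [
                a + self.bin_width * (np.arange(n) + 0.5)
                for (a, _), n in zip(self.regions, self._region_counts())
            ]
        )


def default_binspec() -> BinSpec:
    """The standard plasma layout: [0.80, 4.20) and [5.20, 8.50), 0.02-ppm bins."""
    return BinSpec()


def _check_coverage(ppm: np.ndarray, binspec: BinSpec) -> None:
    tol = 1e-9
    for a, b in binspec.regions:
        if ppm[0] > a + tol or ppm[-1] < b - tol:
            raise ValueError(
                f"spectrum ppm range [{ppm[0]:g}, {ppm[-1]:g}] does not cover "
                f"region [{a:g}, {b:g}]"
            )
        i0 = max(np.searchsorted(ppm, a, side="right") - 1, 0)
        i1 = min(int(np.searchsorted(ppm, b, side="left")), ppm.size - 1)
        if i1 > i0:
            step = np.max(np.diff(ppm[i0 : i1 + 1]))
            if step > binspec.bin_width / 2 + tol:
                raise ValueError(
                    f"ppm grid spacing {step:g} exceeds bin_width/2 = "
                    f"{binspec.bin_width / 2:g} inside region [{a:g}, {b:g}]"
                )


def _bin_weights(ppm: np.ndarray, binspec: BinSpec) -> np.ndarray:
    """Trapezoid quadrature weights: ``W @ intensity`` gives all bin integrals.

    For each bin [a, b], every grid segment [x_i, x_{i+1}] overlapping the bin
    contributes the exact trapezoid integral of the linear interpolant over
    the overlap, so the result is exact for piecewise-linear spectra and
    invariant under grid refinement.
    """
    x = ppm
    n = x.size
    edges_all: list[tuple[float, float]] = []
    for e in binspec.bin_edges():
        edges_all.extend(zip(e[:-1], e[1:]))
    W = np.zeros((len(edges_all), n))
    for k, (a, b) in enumerate(edges_all):
        s0 = max(int(np.searchsorted(x, a, side="right")) - 1, 0)
        s1 = min(int(np.searchsorted(x, b, side="left")), n - 1)
        idx = np.arange(s0, s1)
        if idx.size == 0:
            continue
        xl, xr = x[idx], x[idx + 1]
        lo = np.clip(xl, a, b)
        hi = np.clip(xr, a, b)
        dx = xr - xl
        span = hi - lo
        W[k, idx] += span * (2 * xr - lo - hi) / (2 * dx)
        W[k, idx + 1] += span * (lo + hi - 2 * xl) / (2 * dx)
    return W


def bin_spectrum(spectrum: Spectrum, binspec: BinSpec | None = None) -> np.ndarray:
    """Integrate one spectrum over every bin; returns a vector of length n_bins."""
    if binspec is None:
        binspec = default_binspec()
    _check_coverage(spectrum.ppm, binspec)
    return _bin_weights(spectrum.ppm, binspec) @ spectrum.intensity


@dataclass
class FeatureMatrix:
    """Samples x spectral-bin integrals (AU), with ids and optional class labels."""

    values: np.ndarray
    bin_centers: np.ndarray
    sample_ids: list[str]
    labels: np.ndarray | None = None
    normalization: str = "none"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x bins)")
        if self.values.shape[1] != self.bin_centers.size:
            raise ValueError("bin_centers length must equal the number of columns")
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length must equal the number of rows")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.values.shape[0]:
                raise ValueError("labels length must equal the number of rows")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=[f"{c:.4f}" for c in self.bin_centers],
        )
        if self.labels is not None:
            df.insert(0, "label", self.labels)
        return df

    def to_csv(self, path: str | Path) -> None:
        """Write the matrix as CSV plus a small sidecar JSON recording metadata."""
        path = Path(path)
        self.to_dataframe().to_csv(path)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(
            json.dumps({"normalization": self.normalization, "n_bins": self.n_features})
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        df = pd.read_csv(path, index_col=0)
        labels = None
        if "label" in df.columns:
            labels = df["label"].to_numpy()
            df = df.drop(columns=["label"])
        normalization = "none"
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        if sidecar.exists():
            normalization = json.loads(sidecar.read_text()).get("normalization", "none")
        return cls(
            values=df.to_numpy(dtype=float),
            bin_centers=np.array([float(c) for c in df.columns]),
            sample_ids=[str(s) for s in df.index],
            labels=labels,
            normalization=normalization,
        )


def build_feature_matrix(
    spectra: Sequence[Spectrum] | Iterable[Spectrum],
    binspec: BinSpec | None = None,
    normalization: str = "unit_total",
    labels: Sequence | None = None,
) -> FeatureMatrix:
    """Bin every spectrum and stack the integral vectors into a FeatureMatrix.

    ``normalization="unit_total"`` divides each row by its own sum (total-area
    normalization, rows then sum to 1); ``"none"`` keeps raw integrals.
    """
    if binspec is None:
        binspec = default_binspec()
    if normalization not in ("none", "unit_total"):
        raise ValueError(f"unknown normalization {normalization!r}")
    spectra = list(spectra)
    if not spectra:
        raise ValueError("no spectra supplied")

    shared = all(
        s.ppm.size == spectra[0].ppm.size and np.array_equal(s.ppm, spectra[0].ppm)
        for s in spectra[1:]
    )
    if shared:
        _check_coverage(spectra[0].ppm, binspec)
        W = _bin_weights(spectra[0].ppm, binspec)
        values = np.stack([s.intensity for s in spectra]) @ W.T
    else:
        values = np.stack([bin_spectrum(s, binspec) for s in spectra])

    if normalization == "unit_total":
        totals = values.sum(axis=1)
        bad = np.where(totals == 0)[0]
        if bad.size:
            ids = ", ".join(spectra[i].sample_id or str(i) for i in bad)
            raise ValueError(f"unit_total normalization with zero-total row(s): {ids}")
        values = values / totals[:, None]

    sample_ids = [s.sample_id or f"S{i:03d}" for i, s in enumerate(spectra)]
    return FeatureMatrix(
        values=values,
        bin_centers=binspec.bin_centers(),
        sample_ids=sample_ids,
        labels=None if labels is None else np.asarray(labels),
        normalization=normalization,
    )


def read_spectrum_csv(path: str | Path, sample_id: str | None = None) -> Spectrum:
    """Read a two-column (ppm, intensity) CSV as one Spectrum."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (ppm, intensity)")
    return Spectrum(
        ppm=df.iloc[:, 0].to_numpy(dtype=float),
        intensity=df.iloc[:, 1].to_numpy(dtype=float),
        sample_id=sample_id or path.stem,
    )


def read_spectra_wide_csv(path: str | Path) -> list[Spectrum]:
    """Read a wide CSV (first column ppm, one column per sample) as Spectra."""
    df = pd.read_csv(path)
    ppm = df.iloc[:, 0].to_numpy(dtype=float)
    return [
        Spectrum(ppm=ppm, intensity=df[c].to_numpy(dtype=float), sample_id=str(c))
        for c in df.columns[1:]
    ]


def write_spectrum_csv(spectrum: Spectrum, path: str | Path) -> None:
    pd.DataFrame({"ppm": spectrum.ppm, "intensity": spectrum.intensity}).to_csv(
        path, index=False
    )
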