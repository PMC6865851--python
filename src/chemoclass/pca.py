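"""PCA of binary clinico-radiologic matrices with supplementary projection.

The model is fitted by singular value decomposition of the column-centered
(and, by default, unit-variance autoscaled) 0/1 matrix.  New patients with
known diagnoses can then be projected into the fitted score space as a
"predictive set" without refitting, the convention used to corroborate
unsupervised phenotype clusters against reference cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "BinaryPhenotypeMatrix",
    "PCAModel",
    "fit_pca",
    "project",
    "loadings_table",
    "assign_clusters",
]


@dataclass
class BinaryPhenotypeMatrix:
    """Patients x indicator features, entries strictly 0/1, no missing values."""

    values: np.ndarray
    patient_ids: list[str]
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (patients x features)")
        bad = ~np.isin(self.values, (0.0, 1.0))
        if bad.any():
            cells = list(zip(*np.nonzero(bad)))[:10]
            raise ValueError(f"non-binary entries at (row, col): {cells}")
        if len(self.patient_ids) != self.values.shape[0]:
            raise ValueError("patient_ids length mismatch")
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length mismatch")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.values.astype(int),
            index=pd.Index(self.patient_ids, name="patient_id"),
            columns=self.feature_names,
        ).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BinaryPhenotypeMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(
            values=df.to_numpy(dtype=float),
            patient_ids=[str(i) for i in df.index],
            feature_names=[str(c) for c in df.columns],
        )


@dataclass
class PCAModel:
    """A fitted PCA carrying its scaling so new rows can be projected."""

    column_means: np.ndarray
    column_scales: np.ndarray
    loadings: np.ndarray  # features x components, orthonormal columns
    scores: np.ndarray  # patients x components
    explained_variance_fraction: np.ndarray
    feature_names: list[str]
    scaling: str

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def _scale_params(X: np.ndarray, scaling: str, feature_names) -> tuple[np.ndarray, np.ndarray]:
    means = X.mean(axis=0)
    if scaling == "unit_variance":
        scales = X.std(axis=0, ddof=1)
        const = np.where(scales == 0)[0]
        if const.size:
            names = [feature_names[i] for i in const]
            raise ValueError(f"constant column(s) under unit_variance scaling: {names}")
    elif scaling == "center":
        scales = np.ones(X.shape[1])
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    return means, scales


def fit_pca(
    matrix: BinaryPhenotypeMatrix | np.ndarray,
    n_components: int = 2,
    scaling: str = "unit_variance",
) -> PCAModel:
    """Fit PCA by SVD of the scaled, centered matrix.

    Component signs are fixed so that each loading column's largest-magnitude
    entry is positive, making results stable across runs and libraries.
    """
    if isinstance(matrix, BinaryPhenotypeMatrix):
        X = matrix.values
        feature_names = matrix.feature_names
    else:
        X = np.asarray(matrix, dtype=float)
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    n, p = X.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} must be in [1, min(n_samples - 1, "
            f"n_features)] = [1, {min(n - 1, p)}]"
        )
    means, scales = _scale_params(X, scaling, feature_names)
    Xs = (X - means) / scales
    _u, s, vt = np.linalg.svd(Xs, full_matrices=False)
    total = float((s**2).sum())
    loadings = vt[:n_components].T.copy()
    # sign convention: largest-|loading| entry of each component positive
    for j in range(n_components):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    scores = Xs @ loadings
    evr = (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    return PCAModel(
        column_means=means,
        column_scales=scales,
        loadings=loadings,
        scores=scores,
        explained_variance_fraction=evr,
        feature_names=list(feature_names),
        scaling=scaling,
    )


def project(model: PCAModel, new_rows: BinaryPhenotypeMatrix | np.ndarray) -> np.ndarray:
    """Score supplementary observations in the fitted model; training data untouched."""
    X = new_rows.values if isinstance(new_rows, BinaryPhenotypeMatrix) else np.asarray(
        new_rows, dtype=float
    )
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.loadings.shape[0]:
        raise ValueError(
            f"new rows have {X.shape[1]} features; model expects {model.loadings.shape[0]}"
        )
    return (X - model.column_means) / model.column_scales @ model.loadings


def loadings_table(model: PCAModel) -> pd.DataFrame:
    """All features per component, ordered by |loading| descending.

    Ties are broken by original feature order (stable sort).
    """
    frames = []
    for j in range(model.n_components):
        col = model.loadings[:, j]
        order = np.argsort(-np.abs(col), kind="stable")
        frames.append(
            pd.DataFrame(
                {
                    "component": j + 1,
                    "feature_name": [model.feature_names[i] for i in order],
                    "loading": col[order],
                    "rank": np.arange(1, col.size + 1),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def assign_clusters(scores: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """k-means labels on the first two score dimensions.

    An optional, reproducible surrogate for visual cluster identification on a
    score plot.  Label ids are renumbered by cluster size descending (ties by
    smallest original id), so output is deterministic given the seed.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    n = scores.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must be in [1, n={n}]")
    pts = scores[:, : min(2, scores.shape[1])]
    raw = KMeans(n_clusters=k, n_init=10, random_state=int(seed)).fit_predict(pts)
    counts = np.bincount(raw, minlength=k)
    order = np.lexsort((np.arange(k), -counts))  # size desc, then original id
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return remap[raw]
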