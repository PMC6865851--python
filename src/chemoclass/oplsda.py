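"""Two-class OPLS-DA (orthogonal projections to latent structures) from scratch.

The NIPALS-style algorithm splits predictor variation into a single
y-predictive component and ``n_orthogonal`` components orthogonal to the
class contrast.  Class membership is dummy-coded {0, 1}; a fitted model
predicts a continuous score ŷ and assigns class 1 at ŷ >= 0.5.

Variable importance in projection (VIP) scores summarise each feature's
contribution, normalized so the mean squared VIP is 1; features are ranked by
VIP and a cutoff (1.75 in the reference workflow) selects the discriminators.

Algorithm (X scaled, y centered):
    w  ∝ Xᵀy (unit norm)                      — predictive weight
    repeat for each orthogonal component:
        t = Xw;  p = Xᵀt / tᵀt
        w_o ∝ p − (wᵀp) w   (unit norm)       — y-orthogonal direction
        t_o = X w_o;  p_o = Xᵀ t_o / t_oᵀ t_o
        X ← X − t_o p_oᵀ;  recompute w
    t = Xw (deflated X);  q = yᵀt / tᵀt

Fitted values q·t + ȳ are identical to those of a (n_orthogonal + 1)-component
NIPALS PLS1 on the same data — a standard equivalence used as a test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binning import FeatureMatrix

__all__ = ["OPLSDAModel", "VIPResult", "fit_oplsda", "predict", "vip_scores", "rank_vip"]

_SCALINGS = ("unit_variance", "pareto", "center")


@dataclass
class OPLSDAModel:
    """A fitted two-class OPLS model with its scaling and all components."""

    column_means: np.ndarray
    column_scales: np.ndarray
    classes: tuple  # (class encoded 0, class encoded 1)
    w: np.ndarray  # predictive weight, unit norm (features,)
    p_load: np.ndarray  # predictive loading (features,)
    t: np.ndarray  # predictive scores (samples,)
    W_o: np.ndarray  # orthogonal weights (features, n_orthogonal)
    P_o: np.ndarray  # orthogonal loadings (features, n_orthogonal)
    T_o: np.ndarray  # orthogonal scores (samples, n_orthogonal)
    q: float  # y loading on the predictive score
    y_mean: float
    n_orthogonal: int
    scaling: str
    component_y_ss: np.ndarray  # explained y sum-of-squares, predictive first
    feature_ids: np.ndarray | None = None  # bin centers or names, if known

    @property
    def n_features(self) -> int:
        return self.w.size


def _extract_xy(X, y):
    feature_ids = None
    if isinstance(X, FeatureMatrix):
        feature_ids = X.bin_centers
        if y is None:
            y = X.labels
        X = X.values
    X = np.asarray(X, dtype=float)
    if y is None:
        raise ValueError("labels are required (none attached to the feature matrix)")
    return X, np.asarray(y), feature_ids


def _scale_params(X: np.ndarray, scaling: str) -> tuple[np.ndarray, np.ndarray]:
    if scaling not in _SCALINGS:
        raise ValueError(f"unknown scaling {scaling!r}; choose from {_SCALINGS}")
    means = X.mean(axis=0)
    if scaling == "center":
        return means, np.ones(X.shape[1])
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        cols = np.where(sd == 0)[0].tolist()
        raise ValueError(f"constant column(s) {cols} under {scaling} scaling")
    return means, sd if scaling == "unit_variance" else np.sqrt(sd)


def fit_oplsda(
    X,
    y=None,
    n_orthogonal: int = 1,
    scaling: str = "unit_variance",
) -> OPLSDAModel:
    """Fit a two-class OPLS-DA model.

    ``X`` may be a FeatureMatrix (labels taken from it if ``y`` is None) or a
    plain samples x features array.  ``y`` may hold any two distinct values;
    the lexicographically smaller one is encoded 0.
    """
    X, y, feature_ids = _extract_xy(X, y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"exactly two classes required, got {classes.size}")
    if n_orthogonal < 0:
        raise ValueError("n_orthogonal must be >= 0")
    n = X.shape[0]
    if n <= n_orthogonal + 1:
        raise ValueError("need more samples than n_orthogonal + 1")

    yenc = (y == classes[1]).astype(float)
    y_mean = float(yenc.mean())
    yc = yenc - y_mean

    means, scales = _scale_params(X, scaling)
    E = (X - means) / scales

    def predictive_weight(E):
        w = E.T @ yc
        nrm = np.linalg.norm(w)
        if nrm <= 1e-10 * max(1.0, np.linalg.norm(E) * np.linalg.norm(yc)):
            raise ValueError("no predictive direction: X carries no covariance with y")
        return w / nrm

    w = predictive_weight(E)
    W_o, P_o, T_o, orth_ss = [], [], [], []
    for _ in range(n_orthogonal):
        t = E @ w
        p = E.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        nrm = np.linalg.norm(w_o)
        if nrm < 1e-12:
            break  # no orthogonal variation left
        w_o = w_o / nrm
        t_o = E @ w_o
        p_o = E.T @ t_o / (t_o @ t_o)
        E = E - np.outer(t_o, p_o)
        q_o = (yc @ t_o) / (t_o @ t_o)
        orth_ss.append(q_o**2 * (t_o @ t_o))
        W_o.append(w_o)
        P_o.append(p_o)
        T_o.append(t_o)
        w = predictive_weight(E)

    t = E @ w
    tt = float(t @ t)
    q = float((yc @ t) / tt)
    p_load = E.T @ t / tt

    k = len(W_o)
    p_feat = X.shape[1]
    return OPLSDAModel(
        column_means=means,
        column_scales=scales,
        classes=(classes[0], classes[1]),
        w=w,
        p_load=p_load,
        t=t,
        W_o=np.column_stack(W_o) if k else np.zeros((p_feat, 0)),
        P_o=np.column_stack(P_o) if k else np.zeros((p_feat, 0)),
        T_o=np.column_stack(T_o) if k else np.zeros((n, 0)),
        q=q,
        y_mean=y_mean,
        n_orthogonal=k,
        scaling=scaling,
        component_y_ss=np.array([q**2 * tt] + orth_ss),
        feature_ids=feature_ids,
    )


def predict(model: OPLSDAModel, X_new) -> tuple[np.ndarray, np.ndarray]:
    """Continuous score ŷ and class label per row of ``X_new``.

    New rows are scaled with the training parameters, stripped of the stored
    orthogonal variation, then scored; class 1 is assigned at ŷ >= 0.5.
    """
    if isinstance(X_new, FeatureMatrix):
        X_new = X_new.values
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.n_features:
        raise ValueError(
            f"feature mismatch: {X_new.shape[1]} columns vs model's {model.n_features}"
        )
    E = (X_new - model.column_means) / model.column_scales
    for j in range(model.n_orthogonal):
        t_o = E @ model.W_o[:, j]
        E = E - np.outer(t_o, model.P_o[:, j])
    yhat = model.q * (E @ model.w) + model.y_mean
    labels = np.where(yhat >= 0.5, model.classes[1], model.classes[0])
    return yhat, labels


@dataclass
class VIPResult:
    """Per-feature VIP scores with the descending ranking."""

    vip: np.ndarray
    ranking: np.ndarray  # feature indices, VIP descending
    feature_ids: np.ndarray | None = None

    def threshold_set(self, theta: float) -> np.ndarray:
        """Indices of features with VIP >= theta, in ranking order."""
        return self.ranking[self.vip[self.ranking] >= theta]


def vip_scores(model: OPLSDAModel, variant: str = "total") -> VIPResult:
    """VIP over the model's components, weighted by explained y-variance.

    VIP_j = sqrt( p * Σ_a SS_a (w_aj / ||w_a||)^2 / Σ_a SS_a ), with SS_a the
    y sum-of-squares explained by component a.  Orthogonal components explain
    no y-variance by construction, so the "total" and "predictive_only"
    variants coincide for this model family; both satisfy mean(VIP^2) = 1.
    """
    if variant not in ("total", "predictive_only"):
        raise ValueError(f"unknown VIP variant {variant!r}")
    p = model.n_features
    if variant == "predictive_only":
        W = model.w[:, None]
        ss = model.component_y_ss[:1]
    else:
        W = np.column_stack([model.w, model.W_o]) if model.n_orthogonal else model.w[:, None]
        ss = model.component_y_ss
    vip = np.sqrt(p * (W**2 @ ss) / ss.sum())
    if model.feature_ids is not None:
        order = np.lexsort((np.asarray(model.feature_ids, dtype=float), -vip))
    else:
        order = np.lexsort((np.arange(p), -vip))
    return VIPResult(vip=vip, ranking=order, feature_ids=model.feature_ids)


def rank_vip(vip: VIPResult, threshold: float = 1.75):
    """Features at or above the VIP cutoff, descending; ties by ascending bin center.

    Returns a list of (feature_index, feature_id, vip) tuples.
    """
    idx = vip.threshold_set(threshold)
    ids = vip.feature_ids if vip.feature_ids is not None else np.arange(vip.vip.size)
    return [(int(i), ids[int(i)], float(vip.vip[int(i)])) for i in idx]
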