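"""Model validation: balanced repeated cross-validation, permutation null, ROC.

The reference workflow corrects unequal class sizes by undersampling the
majority class, then runs stratified 10-fold cross-validation for 100
iterations, giving an ensemble of 1,000 held-out fold accuracies.  A twin
ensemble built after randomly permuting the class labels estimates chance
performance; the two ensembles are compared with a Welch t-test (and a
distribution-free summary, since fold accuracies are not independent).
Per-feature discrimination is quantified by ROC AUC with a DeLong (default)
or stratified-bootstrap confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .binning import FeatureMatrix
from .oplsda import fit_oplsda, predict

__all__ = [
    "CVEnsemble",
    "EnsembleComparison",
    "ROCResult",
    "balance_classes",
    "cv_ensemble",
    "permutation_ensemble",
    "compare_ensembles",
    "roc_auc",
]


def balance_classes(labels, seed: int = 0) -> np.ndarray:
    """Indices of a class-size-balanced subset.

    All samples of the minority class are kept together with a uniformly
    random (seeded) equal-sized subset of the majority class.  Indices are
    returned sorted.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size != 2:
        raise ValueError(f"exactly two classes required, got {classes.size}")
    if counts.min() == 0:
        raise ValueError("a class is empty")
    if counts[0] == counts[1]:
        return np.arange(labels.size)
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    rng = np.random.default_rng(seed)
    keep_major = rng.choice(np.where(labels == majority)[0], size=counts.min(), replace=False)
    return np.sort(np.concatenate([np.where(labels == minority)[0], keep_major]))


@dataclass
class CVEnsemble:
    """A repeated-CV accuracy ensemble (observed or permutation-null)."""

    accuracies: np.ndarray
    k_folds: int
    n_iterations: int
    seed: int
    permuted: bool = False

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd(self) -> float:
        return float(self.accuracies.std(ddof=1))


def _cv_accuracies(
    X: np.ndarray,
    y: np.ndarray,
    k_folds: int,
    n_iterations: int,
    model_config: dict,
    seed: int,
    permute: bool,
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    accs = np.empty(k_folds * n_iterations)
    pos = 0
    for _ in range(n_iterations):
        yy = rng.permutation(y) if permute else y
        idx = balance_classes(yy, seed=int(rng.integers(2**31)))
        Xb, yb = X[idx], yy[idx]
        if np.min(np.bincount((yb == np.unique(yb)[1]).astype(int))) < k_folds:
            raise ValueError(
                f"fewer than k_folds={k_folds} samples per class after balancing"
            )
        skf = StratifiedKFold(
            n_splits=k_folds, shuffle=True, random_state=int(rng.integers(2**31))
        )
        for tr, te in skf.split(Xb, yb):
            model = fit_oplsda(Xb[tr], yb[tr], **model_config)
            _, pred = predict(model, Xb[te])
            accs[pos] = np.mean(pred == yb[te])
            pos += 1
    return accs


def _as_xy(X, y):
    if isinstance(X, FeatureMatrix):
        if y is None:
            y = X.labels
        X = X.values
    if y is None:
        raise ValueError("labels are required")
    return np.asarray(X, dtype=float), np.asarray(y)


def cv_ensemble(
    X,
    y=None,
    k_folds: int = 10,
    n_iterations: int = 100,
    model_config: dict | None = None,
    seed: int = 0,
) -> CVEnsemble:
    """Observed accuracy ensemble: k_folds x n_iterations held-out accuracies.

    Each iteration re-balances the classes with a fresh seeded majority
    subsample and draws fresh stratified folds; each fold trains the OPLS-DA
    model on the remaining ~90% of the balanced data and scores the ~10%
    held-out fold.
    """
    X, y = _as_xy(X, y)
    cfg = dict(model_config or {})
    accs = _cv_accuracies(X, y, k_folds, n_iterations, cfg, seed, permute=False)
    return CVEnsemble(accs, k_folds, n_iterations, seed, permuted=False)


def permutation_ensemble(
    X,
    y=None,
    k_folds: int = 10,
    n_iterations: int = 100,
    model_config: dict | None = None,
    seed: int = 0,
) -> CVEnsemble:
    """Null ensemble: labels are uniformly permuted once per iteration."""
    X, y = _as_xy(X, y)
    cfg = dict(model_config or {})
    accs = _cv_accuracies(X, y, k_folds, n_iterations, cfg, seed, permute=True)
    return CVEnsemble(accs, k_folds, n_iterations, seed, permuted=True)


@dataclass
class EnsembleComparison:
    """Welch-t comparison of observed vs null ensembles, plus a rank-free summary."""

    observed_mean: float
    observed_sd: float
    null_mean: float
    null_sd: float
    t_statistic: float
    p_value: float
    frac_null_ge_observed_mean: float


def compare_ensembles(observed, null) -> EnsembleComparison:
    """Compare the two accuracy ensembles.

    Returns the Welch two-sample t-test on the accuracy vectors together with
    the distribution-free fraction of null accuracies at or above the observed
    ensemble mean (reported because fold accuracies within an ensemble are
    correlated, so the t-test's independence assumption is optimistic).
    """
    a = observed.accuracies if isinstance(observed, CVEnsemble) else np.asarray(observed, float)
    b = null.accuracies if isinstance(null, CVEnsemble) else np.asarray(null, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both ensembles must be nonempty")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        tstat, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    else:
        tstat, p = stats.ttest_ind(a, b, equal_var=False)
    return EnsembleComparison(
        observed_mean=float(a.mean()),
        observed_sd=float(a.std(ddof=1)),
        null_mean=float(b.mean()),
        null_sd=float(b.std(ddof=1)),
        t_statistic=float(tstat),
        p_value=float(p),
        frac_null_ge_observed_mean=float(np.mean(b >= a.mean())),
    )


@dataclass
class ROCResult:
    """AUC with a 95% confidence interval for one feature."""

    auc: float
    ci_low: float
    ci_high: float
    positive_class: object
    ci_method: str = "delong"

    def __post_init__(self) -> None:
        if not self.ci_low <= self.auc <= self.ci_high:
            raise ValueError("CI must bracket the AUC")


def _auc_rank(pos: np.ndarray, neg: np.ndarray) -> float:
    # AUC = (concordant pairs + half ties) / (n_pos * n_neg), via midranks
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    n_pos, n_neg = pos.size, neg.size
    return float((ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _delong_ci(pos: np.ndarray, neg: np.ndarray, auc: float) -> tuple[float, float]:
    # structural components: per-positive and per-negative placement values
    cmp_mat = (pos[:, None] > neg[None, :]).astype(float)
    cmp_mat += 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp_mat.mean(axis=1)
    v01 = cmp_mat.mean(axis=0)
    var = 0.0
    if pos.size > 1:
        var += v10.var(ddof=1) / pos.size
    if neg.size > 1:
        var += v01.var(ddof=1) / neg.size
    half = 1.959963984540054 * np.sqrt(var)
    return float(np.clip(auc - half, 0, 1)), float(np.clip(auc + half, 0, 1))


def roc_auc(
    feature_values,
    labels,
    positive_class,
    ci_method: str = "delong",
    n_bootstrap: int = 2000,
    seed: int = 0,
) -> ROCResult:
    """AUC of one feature for separating the positive class, with 95% CI.

    AUC counts the fraction of (positive, negative) pairs ranked correctly,
    ties half-weighted — the Mann-Whitney U statistic divided by
    n_pos * n_neg.  CI by DeLong's asymptotic variance (default) or a
    seeded stratified bootstrap.
    """
    x = np.asarray(feature_values, dtype=float)
    labels = np.asarray(labels)
    pos = x[labels == positive_class]
    neg = x[labels != positive_class]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present (and positive_class observed)")
    auc = _auc_rank(pos, neg)
    if ci_method == "delong":
        lo, hi = _delong_ci(pos, neg, auc)
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            boots[b] = _auc_rank(
                pos[rng.integers(0, pos.size, pos.size)],
                neg[rng.integers(0, neg.size, neg.size)],
            )
        lo, hi = np.percentile(boots, [2.5, 97.5])
        lo, hi = float(min(lo, auc)), float(max(hi, auc))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return ROCResult(auc=auc, ci_low=lo, ci_high=hi, positive_class=positive_class,
                     ci_method=ci_method)
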