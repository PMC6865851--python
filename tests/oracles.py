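"""Independent brute-force oracles used by the test suite.

Each oracle is coded directly from the textbook definition, independently of
the implementation paths it checks.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def nipals_pls1(X: np.ndarray, y: np.ndarray, n_components: int):
    """Plain NIPALS PLS1 on pre-scaled X and centered y.

    Returns the fitted y values (without re-adding any mean).  Deflates both
    X and y each round.
    """
    E = X.copy().astype(float)
    f = y.copy().astype(float)
    fitted = np.zeros_like(f)
    for _ in range(n_components):
        w = E.T @ f
        w = w / np.linalg.norm(w)
        t = E @ w
        tt = t @ t
        p = E.T @ t / tt
        q = (f @ t) / tt
        E = E - np.outer(t, p)
        f = f - q * t
        fitted = fitted + q * t
    return fitted


def vip_brute(W: np.ndarray, ss: np.ndarray) -> np.ndarray:
    """VIP from first principles: loop over features and components."""
    p, a = W.shape
    out = np.empty(p)
    denom = ss.sum()
    for j in range(p):
        acc = 0.0
        for k in range(a):
            wk = W[:, k]
            acc += ss[k] * (wk[j] / np.linalg.norm(wk)) ** 2
        out[j] = np.sqrt(p * acc / denom)
    return out


def auc_pairs(values: np.ndarray, labels: np.ndarray, positive) -> float:
    """AUC by counting all (positive, negative) pairs, ties half-weighted."""
    pos = values[labels == positive]
    neg = values[labels != positive]
    wins = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (pos.size * neg.size)


def t_pooled(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Pooled-variance two-sample t from the textbook formula."""
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), na + nb - 2)
    return float(t), float(p)


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch's t with Welch-Satterthwaite degrees of freedom."""
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1) / na, b.var(ddof=1) / nb
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def anova_f_ss(groups: list[np.ndarray]) -> tuple[float, int, int]:
    """One-way ANOVA F by explicit sum-of-squares decomposition."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    k, n = len(groups), allv.size
    f = (ssb / (k - 1)) / (ssw / (n - k))
    return float(f), k - 1, n - k


def kruskal_h(groups: list[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H from rank sums."""
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start : start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1 - (counts**3 - counts).sum() / (n**3 - n)
    return float(h / correction)


def fisher_2x2_enumeration(table: np.ndarray) -> float:
    """Two-sided Fisher p for a 2x2 table by full hypergeometric enumeration.

    Point-probability rule: sum the probabilities of all tables with the same
    margins whose probability does not exceed the observed table's.
    """
    a, b = int(table[0, 0]), int(table[0, 1])
    c, d = int(table[1, 0]), int(table[1, 1])
    row1, col1, n = a + b, a + c, a + b + c + d
    rv = stats.hypergeom(n, col1, row1)
    p_obs = rv.pmf(a)
    p = 0.0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        px = rv.pmf(x)
        if px <= p_obs * (1 + 1e-9):
            p += px
    return float(min(p, 1.0))
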