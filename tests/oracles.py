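"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — O(n^2) rank counting, explicit
normal equations — and shares no code path with the package.
"""

from __future__ import annotations

import numpy as np


def midranks_bruteforce(x: np.ndarray) -> np.ndarray:
    """Average ranks by direct counting: rank_i = #less + (#equal + 1) / 2."""
    x = np.asarray(x, float)
    ranks = np.empty(len(x))
    for i, xi in enumerate(x):
        less = np.sum(x < xi)
        equal = np.sum(x == xi)
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


def spearman_bruteforce(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation of brute-force midranks, via explicit sums."""
    ru = midranks_bruteforce(u)
    rv = midranks_bruteforce(v)
    n = len(ru)
    mu, mv = ru.sum() / n, rv.sum() / n
    num = float(((ru - mu) * (rv - mv)).sum())
    den = float(np.sqrt(((ru - mu) ** 2).sum() * ((rv - mv) ** 2).sum()))
    return num / den


def spearman_no_ties(u: np.ndarray, v: np.ndarray) -> float:
    """Classic 1 - 6*sum(d^2)/(n(n^2-1)) formula; valid only without ties."""
    ru = midranks_bruteforce(u)
    rv = midranks_bruteforce(v)
    n = len(ru)
    d = ru - rv
    return 1.0 - 6.0 * float((d * d).sum()) / (n * (n * n - 1))


def ols_oracle(x: np.ndarray, y: np.ndarray):
    """Simple-regression slope, its standard error and two-sided t p-value
    from the explicit normal equations on the design [1, x]."""
    from scipy import stats

    X = np.column_stack([np.ones_like(x, dtype=float), np.asarray(x, float)])
    xtx_inv = np.linalg.inv(X.T @ X)
    coef = xtx_inv @ X.T @ np.asarray(y, float)
    resid = y - X @ coef
    dof = len(y) - 2
    sigma2 = float(resid @ resid) / dof
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    t = coef[1] / se
    p = 2.0 * stats.t.sf(abs(t), dof)
    return float(coef[1]), se, float(p)


def exceedance_oracle(observed: float, values) -> int:
    """Sort-and-count: number of values >= observed."""
    s = sorted(float(v) for v in values)
    count = 0
    for v in reversed(s):
        if v >= observed:
            count += 1
        else:
            break
    return count
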