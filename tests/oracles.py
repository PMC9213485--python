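"""Independent reference implementations used to cross-check the package.

These deliberately avoid the code paths of the package itself: the ANOVA
F-test is computed by first-principles sum-of-squares arithmetic with
modified Gram-Schmidt residualization (no lstsq), and the BH adjustment is
the literal step-up formula.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def _residualize(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, int]:
    """Residual of y after projecting out columns of X via modified
    Gram-Schmidt; returns (residual, rank of X)."""
    basis = []
    for j in range(X.shape[1]):
        v = X[:, j].astype(float).copy()
        for b in basis:
            v -= (b @ X[:, j]) * b
        norm = np.sqrt(v @ v)
        if norm > 1e-10 * max(1.0, np.sqrt((X[:, j] ** 2).sum())):
            basis.append(v / norm)
    r = y.astype(float).copy()
    for b in basis:
        r -= (b @ y) * b
    return r, len(basis)


def anova_f_test(y: np.ndarray, genotype: np.ndarray,
                 covariates: np.ndarray | None = None) -> tuple[float, float]:
    """F-test of the genotype-class factor over a covariates-only null.

    Returns (F, p).  Sum-of-squares arithmetic from first principles:
    SSE from Gram-Schmidt residuals, df from basis sizes.
    """
    n = len(y)
    Z = np.ones((n, 1)) if covariates is None else np.hstack(
        [np.ones((n, 1)), covariates])
    classes = np.unique(genotype)
    G = np.stack([(genotype == g).astype(float) for g in classes], axis=1)
    r_null, rank_null = _residualize(y, Z)
    r_full, rank_full = _residualize(y, np.hstack([Z, G]))
    sse_null, sse_full = r_null @ r_null, r_full @ r_full
    df1 = rank_full - rank_null
    df2 = n - rank_full
    F = ((sse_null - sse_full) / df1) / (sse_full / df2)
    return F, float(stats.f.sf(F, df1, df2))


def bh_step_up(p: np.ndarray) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up: adj_(i) = min_{j>=i} m*p_(j)/j,
    capped at 1, mapped back to the input order."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, m * p[order[i]] / (i + 1))
        adj_sorted[i] = running
    out = np.empty(m)
    out[order] = adj_sorted
    return out
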