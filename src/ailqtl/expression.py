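"""Two-group differential expression for array-style intensities.

Raw probe intensities are log2-transformed and quantile-normalized across
all samples (both groups pooled), then each gene is tested with a
two-tailed two-sample t-test (equal-variance Student by default, Welch by
flag) and Benjamini-Hochberg adjusted.  The fold change is reported on the
log2 scale as mean(group 1) - mean(group 2), so a negative value means the
gene is down in the BFMI-like line relative to the reference line; a
linear-ratio column (2**log2FC) is available by flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GROUP_LINE1, GROUP_LINE2, logger

_P_FLOOR = 1e-300


def normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2 transform (if still raw) then quantile-normalize all samples.

    Quantile normalization replaces the value of rank i in each sample by
    the mean of the i-th order statistics across samples; tied values
    receive the mean of the quantile means their ranks span.  Non-positive
    raw intensities are an error naming the offending cell.
    """
    vals = matrix.values.to_numpy(float)
    if not matrix.log2_transformed:
        bad = ~(vals > 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-positive intensity at feature {matrix.values.index[i]!r}, "
                f"sample {matrix.values.columns[j]!r}"
            )
        vals = np.log2(vals)
    mean_quantiles = np.sort(vals, axis=0).mean(axis=1)
    csum = np.concatenate([[0.0], np.cumsum(mean_quantiles)])
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        lo = rankdata(vals[:, j], method="min").astype(int) - 1
        hi = rankdata(vals[:, j], method="max").astype(int)
        out[:, j] = (csum[hi] - csum[lo]) / (hi - lo)
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        matrix.groups.copy(), log2_transformed=True, quantile_normalized=True,
    )


@dataclass
class DEResult:
    """Per-gene differential-expression table.

    Columns: mean_group1, mean_group2 (log2 scale), log2_fc, t_statistic,
    p_value, bh_adjusted_p, significant; optionally fc_linear.
    """

    table: pd.DataFrame
    de_alpha: float
    equal_var: bool

    def bh_p(self, gene: str) -> float:
        return float(self.table.loc[gene, "bh_adjusted_p"])

    def is_significant(self, gene: str) -> bool:
        return bool(self.table.loc[gene, "significant"])


def de_test(matrix: ExpressionMatrix, de_alpha: float = 0.05,
            equal_var: bool = True, linear_ratio: bool = False) -> DEResult:
    """Per-gene two-tailed t-tests with BH adjustment.

    Expects a log2, quantile-normalized matrix (a raw one is accepted but
    logged).  Genes with zero variance in both groups and equal means get
    p = 1 by convention (logged).
    """
    if not matrix.log2_transformed:
        logger.warning("de_test on a matrix not marked log2-transformed")
    a = matrix.values[matrix.samples_in(GROUP_LINE1)].to_numpy(float)
    b = matrix.values[matrix.samples_in(GROUP_LINE2)].to_numpy(float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need at least 2 samples per group")

    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    with warnings.catch_warnings():
        # degenerate zero-variance genes are handled by convention below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    t, p = np.asarray(res.statistic, float), np.asarray(res.pvalue, float)

    degenerate = ~np.isfinite(p)
    if degenerate.any():
        diff = mean_a[degenerate] - mean_b[degenerate]
        same = np.isclose(diff, 0.0)
        p[degenerate] = np.where(same, 1.0, _P_FLOOR)
        t[degenerate] = np.where(same, 0.0,
                                 np.where(diff > 0, np.inf, -np.inf))
        logger.info("%d genes with zero within-group variance handled by "
                    "convention", int(degenerate.sum()))
    p = np.clip(p, _P_FLOOR, 1.0)
    _, bh, _, _ = multipletests(p, method="fdr_bh")

    table = pd.DataFrame(
        {
            "mean_group1": mean_a,
            "mean_group2": mean_b,
            "log2_fc": mean_a - mean_b,
            "t_statistic": t,
            "p_value": p,
            "bh_adjusted_p": bh,
            "significant": bh < de_alpha,
        },
        index=matrix.values.index,
    )
    if linear_ratio:
        table["fc_linear"] = 2.0 ** table.log2_fc
    return DEResult(table, de_alpha, equal_var)
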