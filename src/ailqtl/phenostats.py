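"""Per-trait covariate screening, trait correlation, and covariate-adjusted
genotype-class means.

Covariates (sex, subfamily, litter size) are screened marginally — one
linear model per covariate per trait — mirroring how per-covariate p-values
are reported for intercross studies.  Sex and subfamily are categorical
factors tested by a one-way F-test; litter size is a linear slope.  A
covariate is selected when its p-value falls below ``alpha_covariate``.

Spearman correlations use midrank ties handling and pairwise-complete
observations; family-wise significance uses a per-test Bonferroni threshold
``alpha / n_tests``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    GenotypeMatrix,
    PhenotypeTable,
    MISSING,
    GENOTYPE_CLASSES,
    CLASS_NAMES,
    logger,
)


@dataclass
class CovariateSelection:
    """Per-trait, per-covariate screening p-values and selection flags."""

    table: pd.DataFrame  # columns: trait, covariate, p_value, selected
    alpha: float

    def selected_for(self, trait: str) -> list[str]:
        t = self.table
        sel = t[(t.trait == trait) & t.selected]
        # fixed covariate order: sex, subfamily, litter_size
        order = {c: i for i, c in enumerate(PhenotypeTable.COVARIATES)}
        return sorted(sel.covariate, key=order.get)

    def p_value(self, trait: str, covariate: str) -> float:
        t = self.table
        row = t[(t.trait == trait) & (t.covariate == covariate)]
        return float(row.p_value.iloc[0])


def screen_covariates(phenotypes: PhenotypeTable,
                      alpha_covariate: float = 0.05) -> CovariateSelection:
    """Marginal covariate screen for every trait.

    A constant covariate has an undefined p-value and is reported
    not-selected with a warning.
    """
    rows = []
    data = phenotypes.data
    for trait in phenotypes.trait_names:
        y = data[trait]
        for cov in PhenotypeTable.COVARIATES:
            x = data[cov]
            ok = y.notna() & x.notna()
            p = _marginal_p(y[ok], x[ok], categorical=(cov != "litter_size"))
            if np.isnan(p):
                logger.warning("covariate %s constant for trait %s; not selected",
                               cov, trait)
            rows.append({"trait": trait, "covariate": cov, "p_value": p,
                         "selected": bool(p < alpha_covariate)})
    return CovariateSelection(pd.DataFrame(rows), alpha_covariate)


def _marginal_p(y: pd.Series, x: pd.Series, categorical: bool) -> float:
    if len(y) < 3 or x.nunique() < 2:
        return float("nan")
    if categorical:
        groups = [y[x == level].to_numpy() for level in x.unique()]
        groups = [g for g in groups if len(g) > 0]
        if len(groups) < 2:
            return float("nan")
        return float(stats.f_oneway(*groups).pvalue)
    res = stats.linregress(x.astype(float), y.astype(float))
    return float(res.pvalue)


@dataclass
class CorrelationMatrix:
    rho: pd.DataFrame
    p: pd.DataFrame
    n_tests: int
    threshold: float
    significant: pd.DataFrame

    def __post_init__(self) -> None:
        r = self.rho.to_numpy(dtype=float)
        assert np.allclose(r, r.T, equal_nan=True)
        assert np.nanmax(np.abs(r)) <= 1 + 1e-12


def spearman_matrix(phenotypes: PhenotypeTable,
                    n_tests: int | str = "all-pairs",
                    alpha: float = 0.05,
                    method: str = "asymptotic") -> CorrelationMatrix:
    """All-pairs Spearman correlation with Bonferroni flags.

    p-values use the t approximation ``t = rho*sqrt((n-2)/(1-rho^2))`` on
    midranked, pairwise-complete observations; ``method="exact"`` switches
    to a permutation p-value (recommended only for n < 10).  ``n_tests``
    defaults to the number of distinct trait pairs.
    """
    traits = phenotypes.trait_names
    k = len(traits)
    if k < 2:
        raise ValueError("correlation needs at least two traits")
    rho = pd.DataFrame(np.eye(k), index=traits, columns=traits)
    pval = pd.DataFrame(np.zeros((k, k)), index=traits, columns=traits)
    np.fill_diagonal(pval.values, np.nan)
    data = phenotypes.data

    for a, b in itertools.combinations(traits, 2):
        x, y = data[a], data[b]
        ok = x.notna() & y.notna()
        n = int(ok.sum())
        if n < 3 or x[ok].nunique() < 2 or y[ok].nunique() < 2:
            r, p = np.nan, np.nan
        elif method == "exact":
            r, p = _exact_spearman(x[ok].to_numpy(float), y[ok].to_numpy(float))
        else:
            r = float(stats.spearmanr(x[ok], y[ok]).statistic)
            p = _t_approx_p(r, n)
        rho.loc[a, b] = rho.loc[b, a] = r
        pval.loc[a, b] = pval.loc[b, a] = p

    m = k * (k - 1) // 2 if n_tests == "all-pairs" else int(n_tests)
    threshold = alpha / m
    sig = pval < threshold
    np.fill_diagonal(sig.values, False)
    return CorrelationMatrix(rho, pval, m, threshold, sig)


def _t_approx_p(r: float, n: int) -> float:
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def _exact_spearman(x: np.ndarray, y: np.ndarray,
                    n_resamples: int = 100_000) -> tuple[float, float]:
    r = float(stats.spearmanr(x, y).statistic)
    res = stats.permutation_test(
        (x, y), lambda a, b: stats.spearmanr(a, b).statistic,
        permutation_type="pairings", alternative="two-sided",
        n_resamples=n_resamples, rng=np.random.default_rng(0),
    )
    return r, float(res.pvalue)


# ---------------------------------------------------------------------------
# Covariate-adjusted genotype-class means
# ---------------------------------------------------------------------------


@dataclass
class ClassMeans:
    """Least-squares genotype-class means (NaN for absent classes)."""

    means: dict[str, float]
    n_per_class: dict[str, int]
    testable: bool  # fewer than 2 observed classes -> not testable


def covariate_design(data: pd.DataFrame, selected: list[str]) -> pd.DataFrame:
    """Numeric covariate columns (no intercept): a male indicator for sex,
    drop-first dummies for subfamily, litter_size as-is."""
    cols = {}
    for cov in selected:
        if cov == "sex":
            cols["sex[M]"] = (data["sex"] == "M").astype(float)
        elif cov == "subfamily":
            dummies = pd.get_dummies(data["subfamily"].astype(str),
                                     prefix="subfam", drop_first=True)
            for c in dummies.columns:
                cols[c] = dummies[c].astype(float)
        elif cov == "litter_size":
            cols["litter_size"] = data["litter_size"].astype(float)
        else:
            raise KeyError(f"unknown covariate {cov!r}")
    out = pd.DataFrame(cols, index=data.index)
    # carry covariate missingness so callers can listwise-delete
    for cov in selected:
        out.loc[data[cov].isna(), :] = np.nan
    return out


def ls_class_means(y: np.ndarray, calls: np.ndarray,
                   covariates: np.ndarray | None) -> tuple[dict[int, float], dict[int, int]]:
    """Least-squares class means from a one-factor model with covariates.

    The design uses one indicator column per observed genotype class plus
    the (uncentred) covariate columns; the reported mean for class c is the
    class coefficient plus the covariate contribution evaluated at the
    sample means, i.e. classes are compared at identical covariate values.
    With no covariates this reduces exactly to the raw within-class means.
    """
    observed = [g for g in GENOTYPE_CLASSES if (calls == g).any()]
    ind = np.stack([(calls == g).astype(float) for g in observed], axis=1)
    if covariates is not None and covariates.shape[1] > 0:
        X = np.hstack([ind, covariates])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        shift = covariates.mean(axis=0) @ beta[len(observed):]
        means = {g: float(beta[i] + shift) for i, g in enumerate(observed)}
    else:
        means = {g: float(y[calls == g].mean()) for g in observed}
    counts = {g: int((calls == g).sum()) for g in observed}
    return means, counts


def adjusted_class_means(trait: str, genotypes: GenotypeMatrix, marker_id: str,
                         phenotypes: PhenotypeTable,
                         selection: CovariateSelection | list[str]) -> ClassMeans:
    """Covariate-adjusted phenotype means per genotype class at one marker.

    Individuals missing the trait, a selected covariate, or the genotype
    call are dropped listwise.  Classes absent after deletion are NaN;
    with fewer than two observed classes the means are reported but flagged
    non-testable.
    """
    pheno = phenotypes.aligned_to(genotypes)
    selected = (selection.selected_for(trait) if isinstance(selection, CovariateSelection)
                else list(selection))
    y = pheno.data[trait].to_numpy(float)
    calls = genotypes.calls[:, genotypes.marker_index(marker_id)]
    Z = covariate_design(pheno.data, selected).to_numpy(float)
    ok = np.isfinite(y) & (calls != MISSING)
    if Z.shape[1]:
        ok &= np.isfinite(Z).all(axis=1)
    mraw, craw = ls_class_means(y[ok], calls[ok], Z[ok] if Z.shape[1] else None)
    means = {CLASS_NAMES[g]: mraw.get(g, float("nan")) for g in GENOTYPE_CLASSES}
    counts = {CLASS_NAMES[g]: craw.get(g, 0) for g in GENOTYPE_CLASSES}
    return ClassMeans(means, counts, testable=len(mraw) >= 2)
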