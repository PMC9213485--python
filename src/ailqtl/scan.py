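"""Single-marker QTL scans with genomic control, simpleM-Bonferroni
thresholds, 1.5-LOD-drop support intervals and cofactor MQM.

Model
-----
For each marker the trait is regressed on the selected fixed covariates
plus the marker's genotype class as a categorical factor (2 df with three
observed classes, 1 df with two — an additive coding would miss the
overdominant signals a three-class factor can detect).  The marker p-value
is the F-test of the genotype factor against the covariates-only null on
the same individuals (listwise deletion per marker), and

    LOD = -log10(p).

Genomic control
---------------
Population structure inflates the test statistics.  Each per-trait scan's
p-values are converted to 1-df chi-square quantiles; the genomic inflation
factor is

    lambda = median(q) / 0.4549364  (the 1-df chi-square median),

and when lambda exceeds the trigger (default 1.05) every quantile is
deflated by lambda before being converted back to a p-value.  lambda is
reported either way.

Multiple testing
----------------
The effective number of independent tests M_eff is estimated per
chromosome by the eigenvalue method: the smallest k such that the top k
eigenvalues of the marker-marker correlation matrix carry >= 99.5% of the
total variance, summed over chromosomes.  Bonferroni thresholds are then
LOD = -log10(alpha / M_eff), displayed to one decimal.

Support intervals
-----------------
A QTL region runs from the first marker upstream of the top marker whose
LOD falls ``lod_drop`` (default 1.5) below the top LOD, to the symmetric
marker downstream; chromosome ends cap the interval.

MQM
---
The cofactor scan re-runs the genome with a known QTL's top-marker
genotype added as a categorical covariate, revealing loci masked by the
large effect.  The cofactor marker itself (and markers genotypically
identical to it) carry no remaining genotype degrees of freedom and are
emitted with NA statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    GenotypeMatrix,
    PhenotypeTable,
    RunConfig,
    MISSING,
    GENOTYPE_CLASSES,
    CLASS_NAMES,
    logger,
)
from .phenostats import CovariateSelection, covariate_design, ls_class_means

_P_FLOOR = 1e-300  # guard: p stays in (0, 1]


@dataclass
class ScanResult:
    trait: str
    table: pd.DataFrame  # one row per marker, see scan() for columns
    lambda_: float
    lambda_applied: bool
    lod_sig: float
    lod_highsig: float
    meff: int
    covariates: list[str] = field(default_factory=list)
    cofactors: list[str] = field(default_factory=list)


@dataclass
class QTLRegion:
    trait: str
    chromosome: str
    start_bp: int
    top_bp: int
    stop_bp: int
    top_marker: str
    top_lod: float
    percent_variance: float
    class_means: dict[str, float]

    def __post_init__(self) -> None:
        assert self.start_bp <= self.top_bp <= self.stop_bp


# ---------------------------------------------------------------------------
# Genomic control
# ---------------------------------------------------------------------------


def lambda_correct(p_values, trigger: float = 1.05, df: int = 1
                   ) -> tuple[float, np.ndarray]:
    """Genomic-control inflation factor and (possibly) corrected p-values.

    p-values are mapped to chi-square(df) quantiles; lambda is the ratio of
    their median to the null chi-square median.  When lambda > trigger the
    quantiles are divided by lambda and mapped back; otherwise the input is
    returned unchanged (lambda is reported either way).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    finite = np.isfinite(p)
    if not finite.any():
        raise ValueError("no finite p-values")
    if (p[finite] <= 0).any() or (p[finite] > 1).any():
        raise ValueError("p-values must be in (0, 1]")
    q = stats.chi2.isf(p[finite], df)
    lam = float(np.median(q) / stats.chi2.ppf(0.5, df))
    corrected = p.copy()
    if lam > trigger:
        corrected[finite] = np.maximum(stats.chi2.sf(q / lam, df), _P_FLOOR)
    return lam, corrected


# ---------------------------------------------------------------------------
# simpleM effective number of tests
# ---------------------------------------------------------------------------


def simpleM_effective_tests(genotypes: GenotypeMatrix,
                            variance_fraction: float = 0.995,
                            per_chromosome: bool = True) -> int:
    """Eigenvalue-based effective number of independent markers.

    Per chromosome (the LD structure only spans linked markers; a
    genome-wide matrix is available via ``per_chromosome=False``): compute
    the pairwise-complete marker correlation matrix on 0/1/2 dosages, clip
    negative eigenvalues to zero, and take the smallest k whose leading
    eigenvalues reach ``variance_fraction`` of the eigenvalue total.
    """
    if not 0 < variance_fraction <= 1:
        raise ValueError("variance_fraction must be in (0, 1]")
    dosage = genotypes.dosage()
    if per_chromosome:
        groups = [np.flatnonzero((genotypes.markers.chromosome == c).to_numpy())
                  for c in genotypes.markers.chromosome.unique()]
    else:
        groups = [np.arange(genotypes.n_markers)]
    total = 0
    for idx in groups:
        total += _meff_block(dosage[:, idx], variance_fraction)
    return total


def _meff_block(block: np.ndarray, variance_fraction: float) -> int:
    if block.shape[1] == 1:
        return 1
    corr = pd.DataFrame(block).corr(min_periods=2).to_numpy()
    if not np.isfinite(corr).all():
        raise RuntimeError(
            "undefined marker correlation (zero-variance or non-overlapping "
            "markers) — matrix should have passed marker QC first"
        )
    eig = np.linalg.eigvalsh(corr)[::-1]
    eig = np.clip(eig, 0.0, None)
    frac = np.cumsum(eig) / eig.sum()
    return int(np.searchsorted(frac, variance_fraction - 1e-12) + 1)


def lod_thresholds(meff: int, alpha_sig: float = 0.05,
                   alpha_highsig: float = 0.01) -> tuple[float, float]:
    """Bonferroni LOD thresholds -log10(alpha / M_eff), full precision.

    Display values round to one decimal (``display_lod``); comparisons use
    the unrounded values.
    """
    if meff < 1:
        raise ValueError("meff must be >= 1")
    return (-np.log10(alpha_sig / meff), -np.log10(alpha_highsig / meff))


def display_lod(lod: float) -> str:
    return f"{lod:.1f}"


# ---------------------------------------------------------------------------
# The scan proper
# ---------------------------------------------------------------------------


def _sse_rank(X: np.ndarray, y: np.ndarray) -> tuple[float, int, np.ndarray]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank), beta


def scan(trait: str, genotypes: GenotypeMatrix, phenotypes: PhenotypeTable,
         selection: CovariateSelection | list[str],
         config: RunConfig | None = None,
         cofactor_marker: str | None = None,
         meff: int | None = None) -> ScanResult:
    """Genome scan of one trait over all markers.

    ``genotypes`` should already be quality-controlled.  ``selection``
    supplies the fixed covariates (a screening result or an explicit list).
    ``cofactor_marker`` adds that marker's genotype factor to every model
    (the MQM variant); ``meff`` overrides the simpleM computation when the
    caller has it cached.
    """
    cfg = config or RunConfig()
    pheno = phenotypes.aligned_to(genotypes)
    selected = (selection.selected_for(trait)
                if isinstance(selection, CovariateSelection) else list(selection))
    y = pheno.data[trait].to_numpy(float)
    Z = covariate_design(pheno.data, selected).to_numpy(float)
    if Z.ndim == 1:
        Z = Z.reshape(len(y), 0)

    cof_idx = None
    if cofactor_marker is not None:
        cof_idx = genotypes.marker_index(cofactor_marker)
        cof_calls = genotypes.calls[:, cof_idx].astype(float)
        cof_calls[cof_calls == MISSING] = np.nan
        observed = [g for g in GENOTYPE_CLASSES if (cof_calls == g).any()]
        # drop-first dummies; missing cofactor calls propagate NaN -> listwise
        dummies = np.stack([(cof_calls == g).astype(float) for g in observed[1:]],
                           axis=1) if len(observed) > 1 else np.empty((len(y), 0))
        dummies[np.isnan(cof_calls)] = np.nan
        Z = np.hstack([Z, dummies])

    base_ok = np.isfinite(y)
    if Z.shape[1]:
        base_ok &= np.isfinite(Z).all(axis=1)

    null_cache: dict[bytes, tuple[float, int, float, np.ndarray]] = {}
    rows = []
    for j in range(genotypes.n_markers):
        calls = genotypes.calls[:, j]
        ok = base_ok & (calls != MISSING)
        rec = {
            "marker_id": genotypes.markers.marker_id.iat[j],
            "chromosome": genotypes.markers.chromosome.iat[j],
            "position_bp": int(genotypes.markers.position_bp.iat[j]),
        }
        stats_na = dict(p_raw=np.nan, lod_raw=np.nan, p_corrected=np.nan,
                        lod_corrected=np.nan, partial_r2=np.nan)
        y0, Z0, c0 = y[ok], Z[ok], calls[ok]
        observed = [g for g in GENOTYPE_CLASSES if (c0 == g).any()]
        for g in GENOTYPE_CLASSES:
            rec[f"n_{CLASS_NAMES[g]}"] = int((c0 == g).sum())
        means, _ = (ls_class_means(y0, c0, Z0 if Z0.shape[1] else None)
                    if len(observed) else ({}, {}))
        for g in GENOTYPE_CLASSES:
            rec[f"mean_{CLASS_NAMES[g]}"] = means.get(g, np.nan)
        if len(observed) < 2 or (cof_idx is not None and j == cof_idx):
            rows.append({**rec, **stats_na})
            continue

        key = ok.tobytes()
        if key not in null_cache:
            Xn = np.hstack([np.ones((len(y0), 1)), Z0])
            sse_n, rank_n, _ = _sse_rank(Xn, y0)
            sst = float(((y0 - y0.mean()) ** 2).sum())
            null_cache[key] = (sse_n, rank_n, sst, Xn)
        sse_null, rank_null, sst, _ = null_cache[key]

        ind = np.stack([(c0 == g).astype(float) for g in observed], axis=1)
        Xf = np.hstack([ind, Z0])
        sse_full, rank_full, _ = _sse_rank(Xf, y0)
        df1 = rank_full - rank_null
        df2 = len(y0) - rank_full
        if df1 < 1 or df2 < 1:
            rows.append({**rec, **stats_na})  # collinear with covariates/cofactor
            continue
        if sse_full <= 0:
            p_raw = _P_FLOOR
        else:
            F = ((sse_null - sse_full) / df1) / (sse_full / df2)
            p_raw = max(float(stats.f.sf(max(F, 0.0), df1, df2)), _P_FLOOR)
        partial_r2 = ((sse_null - sse_full) / sst * 100.0) if sst > 0 else np.nan
        rows.append({**rec, **stats_na, "p_raw": p_raw,
                     "lod_raw": -np.log10(p_raw),
                     "partial_r2": float(np.clip(partial_r2, 0.0, 100.0))})

    table = pd.DataFrame(rows)
    lam, corrected = lambda_correct(table.p_raw.to_numpy(), cfg.lambda_trigger,
                                    cfg.lambda_df)
    applied = lam > cfg.lambda_trigger
    table["p_corrected"] = corrected
    table["lod_corrected"] = -np.log10(table.p_corrected)

    if meff is None:
        meff = simpleM_effective_tests(genotypes, cfg.simpleM_variance_fraction,
                                       cfg.simpleM_per_chromosome)
    lod_sig, lod_highsig = lod_thresholds(meff, cfg.alpha_sig, cfg.alpha_highsig)
    logger.info("scan %s: lambda=%.3f (applied=%s), Meff=%d, LOD thresholds %s/%s",
                trait, lam, applied, meff, display_lod(lod_sig),
                display_lod(lod_highsig))
    return ScanResult(
        trait=trait, table=table, lambda_=lam, lambda_applied=applied,
        lod_sig=float(lod_sig), lod_highsig=float(lod_highsig), meff=int(meff),
        covariates=selected,
        cofactors=[cofactor_marker] if cofactor_marker else [],
    )


def mqm_scan(trait: str, genotypes: GenotypeMatrix, phenotypes: PhenotypeTable,
             selection: CovariateSelection | list[str], cofactor_marker: str,
             config: RunConfig | None = None,
             meff: int | None = None) -> ScanResult:
    """Cofactor (multiple-QTL-mapping) scan: the single-marker scan with a
    known QTL's top-marker genotype as an extra categorical covariate."""
    if cofactor_marker not in set(genotypes.markers.marker_id):
        raise ValueError(f"cofactor marker {cofactor_marker!r} not in matrix")
    return scan(trait, genotypes, phenotypes, selection, config,
                cofactor_marker=cofactor_marker, meff=meff)


# ---------------------------------------------------------------------------
# LOD-drop support intervals
# ---------------------------------------------------------------------------


def lod_drop_region(result: ScanResult, chromosome: str,
                    lod_drop: float = 1.5,
                    threshold: float | None = None) -> QTLRegion | None:
    """Support interval around the chromosome's top marker.

    The top marker maximises the corrected LOD (ties -> smallest bp).  The
    interval runs to the first flanking markers whose LOD drops by
    ``lod_drop`` below the top, or to the chromosome ends.  When a
    ``threshold`` is given and no marker reaches it, no region is called
    (returns None).
    """
    if lod_drop <= 0:
        raise ValueError("lod_drop must be > 0")
    sub = (result.table[result.table.chromosome == str(chromosome)]
           .sort_values("position_bp").reset_index(drop=True))
    lods = sub.lod_corrected.to_numpy(float)
    if sub.empty or not np.isfinite(lods).any():
        return None
    top = int(np.nanargmax(lods))  # first max = smallest bp after the sort
    top_lod = float(lods[top])
    if threshold is not None and top_lod < threshold:
        return None
    cut = top_lod - lod_drop
    start = int(sub.position_bp.iat[0])
    for i in range(top - 1, -1, -1):
        if np.isfinite(lods[i]) and lods[i] <= cut:
            start = int(sub.position_bp.iat[i])
            break
    stop = int(sub.position_bp.iat[len(sub) - 1])
    for i in range(top + 1, len(sub)):
        if np.isfinite(lods[i]) and lods[i] <= cut:
            stop = int(sub.position_bp.iat[i])
            break
    means = {name: float(sub[f"mean_{name}"].iat[top])
             for name in CLASS_NAMES.values()}
    return QTLRegion(
        trait=result.trait, chromosome=str(chromosome), start_bp=start,
        top_bp=int(sub.position_bp.iat[top]), stop_bp=stop,
        top_marker=str(sub.marker_id.iat[top]), top_lod=top_lod,
        percent_variance=float(sub.partial_r2.iat[top]), class_means=means,
    )


def call_regions(result: ScanResult, lod_drop: float = 1.5,
                 use_highsig: bool = False) -> list[QTLRegion]:
    """All QTL regions whose top marker passes the scan's own threshold."""
    thr = result.lod_highsig if use_highsig else result.lod_sig
    regions = []
    for chrom in result.table.chromosome.unique():
        r = lod_drop_region(result, chrom, lod_drop, threshold=thr)
        if r is not None:
            regions.append(r)
    return regions
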