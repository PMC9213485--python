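"""Core data types, file formats, configuration and logging.

The pipeline operates on four in-memory containers: a :class:`GenotypeMatrix`
(marker calls for an intercross population plus a physical marker map), a
:class:`PhenotypeTable` (covariates and quantitative traits per individual),
a variant-annotation table (one row per variant/feature per gene, VEP-style
categories) and an :class:`ExpressionMatrix` (two-group array intensities).

All in-memory genomic coordinates are 1-based inclusive (MM10-style bp);
BED output converts to 0-based half-open on write and back on read.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("ailqtl")
if not logger.handlers:  # library default: warnings+ to stderr, quiet otherwise
    logger.addHandler(logging.NullHandler())


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


# ---------------------------------------------------------------------------
# Genotype coding
# ---------------------------------------------------------------------------
# Calls are stored as the dosage of the line-1 (BFMI-like founder) allele:
#   2 = homozygous line 1, 1 = heterozygous, 0 = homozygous line 2 (reference
#   founder, B6N-like), -1 = missing.
HOM_LINE1: int = 2
HET: int = 1
HOM_LINE2: int = 0
MISSING: int = -1

GENOTYPE_CLASSES = (HOM_LINE1, HET, HOM_LINE2)
CLASS_NAMES = {HOM_LINE1: "HOM_LINE1", HET: "HET", HOM_LINE2: "HOM_LINE2"}

#: default call-symbol dialect for genotype files (A = line-1 homozygote)
DEFAULT_CALL_SYMBOLS: Mapping[str, int] = {
    "A": HOM_LINE1,
    "H": HET,
    "B": HOM_LINE2,
    "NA": MISSING,
}

_CHROMOSOMES = [str(c) for c in range(1, 20)] + ["X"]


def _chrom_sort_key(label: str) -> tuple[int, str]:
    s = str(label)
    return (int(s), "") if s.isdigit() else (1000, s)


def make_marker_map(
    marker_id: Sequence[str],
    chromosome: Sequence[str],
    position_bp: Sequence[int],
    position_cM: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Build and validate a marker map DataFrame.

    Columns: ``marker_id``, ``chromosome`` (string label "1".."19","X"),
    ``position_bp`` (1-based), optional ``position_cM``.  Markers are sorted
    by (chromosome, position_bp).
    """
    df = pd.DataFrame(
        {
            "marker_id": pd.Series(marker_id, dtype=str),
            "chromosome": pd.Series(chromosome, dtype=str),
            "position_bp": pd.Series(position_bp, dtype=np.int64),
        }
    )
    if position_cM is not None:
        df["position_cM"] = pd.Series(position_cM, dtype=float)
    validate_marker_map(df)
    order = sorted(
        range(len(df)),
        key=lambda i: (_chrom_sort_key(df.chromosome.iat[i]), df.position_bp.iat[i]),
    )
    return df.iloc[order].reset_index(drop=True)


def validate_marker_map(df: pd.DataFrame) -> None:
    if df.marker_id.duplicated().any():
        dup = df.marker_id[df.marker_id.duplicated()].iloc[0]
        raise FormatError(f"duplicate marker id {dup!r}")
    if (df.position_bp < 1).any():
        raise FormatError("position_bp must be >= 1 (1-based coordinates)")
    if df.duplicated(subset=["chromosome", "position_bp"]).any():
        raise FormatError("duplicate (chromosome, position_bp) pair in marker map")
    if "position_cM" in df.columns:
        for _, grp in df.groupby("chromosome", sort=False):
            g = grp.sort_values("position_bp")
            cm = g.position_cM.dropna()
            if not cm.is_monotonic_increasing:
                raise FormatError("position_cM must be non-decreasing with position_bp")


@dataclass
class GenotypeMatrix:
    """Marker calls (individuals x markers) plus the marker map.

    ``calls`` is an int8 array with values in {2, 1, 0, -1} (line-1 dosage,
    -1 missing).  ``markers`` is the map DataFrame described in
    :func:`make_marker_map`, row-aligned with the call columns.
    """

    individuals: list[str]
    markers: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individuals), len(self.markers)):
            raise ValueError(
                f"call matrix shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.markers)} markers"
            )
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("individual ids must be unique")
        bad = ~np.isin(self.calls, [HOM_LINE1, HET, HOM_LINE2, MISSING])
        if bad.any():
            raise ValueError("calls outside {2,1,0,-1}")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def class_counts(self, marker_index: int) -> dict[int, int]:
        """Non-missing genotype-class counts at one marker."""
        col = self.calls[:, marker_index]
        return {g: int((col == g).sum()) for g in GENOTYPE_CLASSES}

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            list(self.individuals),
            self.markers.iloc[keep].reset_index(drop=True),
            self.calls[:, keep].copy(),
        )

    def marker_index(self, marker_id: str) -> int:
        hits = np.flatnonzero((self.markers.marker_id == marker_id).to_numpy())
        if len(hits) == 0:
            raise KeyError(f"marker {marker_id!r} not in matrix")
        return int(hits[0])

    def dosage(self) -> np.ndarray:
        """Calls as float with NaN for missing (for correlation work)."""
        d = self.calls.astype(float)
        d[self.calls == MISSING] = np.nan
        return d


@dataclass
class PhenotypeTable:
    """Per-individual covariates and quantitative traits.

    ``data`` holds one row per individual with columns ``individual_id``,
    ``sex`` ("M"/"F"), ``subfamily`` (dam label), ``litter_size`` and one
    column per trait.  Missing trait values are NaN, never silently zero.
    """

    data: pd.DataFrame
    trait_names: list[str] = field(default_factory=list)

    COVARIATES = ("sex", "subfamily", "litter_size")

    def __post_init__(self) -> None:
        required = {"individual_id", "sex", "subfamily", "litter_size"}
        missing = required - set(self.data.columns)
        if missing:
            raise FormatError(f"phenotype table missing columns {sorted(missing)}")
        if self.data.individual_id.duplicated().any():
            raise FormatError("duplicate individual ids in phenotype table")
        if not set(self.data.sex.dropna()) <= {"M", "F"}:
            raise FormatError("sex must be coded M/F")
        if not self.trait_names:
            self.trait_names = [
                c for c in self.data.columns if c not in required
            ]
        self.data = self.data.reset_index(drop=True)

    def trait(self, name: str) -> pd.Series:
        if name not in self.trait_names:
            raise KeyError(f"unknown trait {name!r}")
        return self.data[name]

    def aligned_to(self, genotypes: GenotypeMatrix) -> "PhenotypeTable":
        """Rows reordered to match genotype individuals (must be a subset)."""
        idx = self.data.set_index("individual_id")
        missing = [i for i in genotypes.individuals if i not in idx.index]
        if missing:
            raise ValueError(f"individuals missing from phenotype table: {missing[:5]}")
        out = idx.loc[genotypes.individuals].reset_index()
        return PhenotypeTable(out, list(self.trait_names))


# ---------------------------------------------------------------------------
# Variant annotations
# ---------------------------------------------------------------------------

CODING_CONSEQUENCES = ("stop_gain", "stop_loss", "missense", "none")
SIFT_CLASSES = ("deleterious", "tolerated", "n/a")
REGULATORY_FEATURES = (
    "promoter",
    "splice_site",
    "utr",
    "enhancer",
    "ctcf_binding_site",
    "none",
)

ANNOTATION_COLUMNS = [
    "gene_id",
    "gene_symbol",
    "chromosome",
    "position_bp",
    "coding_consequence",
    "sift_class",
    "in_functional_domain",
    "regulatory_feature",
]

#: mapping from VEP consequence terms to the scoring categories
#: (coding_consequence, regulatory_feature); unmapped terms become
#: ("none", "none") and are counted in the skip log.
VEP_CONSEQUENCE_MAP: Mapping[str, tuple[str, str]] = {
    "stop_gained": ("stop_gain", "none"),
    "stop_lost": ("stop_loss", "none"),
    "missense_variant": ("missense", "none"),
    "splice_acceptor_variant": ("none", "splice_site"),
    "splice_donor_variant": ("none", "splice_site"),
    "splice_region_variant": ("none", "splice_site"),
    "5_prime_UTR_variant": ("none", "utr"),
    "3_prime_UTR_variant": ("none", "utr"),
    "promoter_variant": ("none", "promoter"),
    "enhancer_variant": ("none", "enhancer"),
    "TF_binding_site_variant": ("none", "enhancer"),
    "CTCF_binding_site_variant": ("none", "ctcf_binding_site"),
}

#: VEP regulatory-feature biotypes, used when a consequence term is generic
#: ("regulatory_region_variant") but the feature biotype is informative.
VEP_BIOTYPE_MAP: Mapping[str, str] = {
    "promoter": "promoter",
    "promoter_flanking_region": "promoter",
    "enhancer": "enhancer",
    "CTCF_binding_site": "ctcf_binding_site",
}


def validate_annotations(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"annotation table missing columns {sorted(missing)}")
    bad = ~df.coding_consequence.isin(CODING_CONSEQUENCES)
    if bad.any():
        raise FormatError(
            f"unknown coding_consequence {df.coding_consequence[bad].iloc[0]!r}"
        )
    bad = ~df.sift_class.isin(SIFT_CLASSES)
    if bad.any():
        raise FormatError(f"unknown sift_class {df.sift_class[bad].iloc[0]!r}")
    bad = ~df.regulatory_feature.isin(REGULATORY_FEATURES)
    if bad.any():
        raise FormatError(
            f"unknown regulatory_feature {df.regulatory_feature[bad].iloc[0]!r}"
        )
    nonmiss = (df.coding_consequence != "missense") & (df.sift_class != "n/a")
    if nonmiss.any():
        raise FormatError("sift_class must be n/a unless coding_consequence is missense")
    return df[ANNOTATION_COLUMNS].copy()


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

GROUP_LINE1 = "LINE1"
GROUP_LINE2 = "LINE2"


@dataclass
class ExpressionMatrix:
    """Array intensities, genes x samples, with a two-level group label.

    ``log2_transformed`` tracks whether values are on the log2 scale;
    ``quantile_normalized`` whether samples share a common distribution.
    """

    values: pd.DataFrame  # index = feature ids, columns = sample ids
    groups: pd.Series  # sample id -> GROUP_LINE1 / GROUP_LINE2
    log2_transformed: bool = False
    quantile_normalized: bool = False

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            raise ValueError("every sample needs a group label")
        if not set(self.groups) <= {GROUP_LINE1, GROUP_LINE2}:
            raise ValueError(f"group labels must be {GROUP_LINE1}/{GROUP_LINE2}")
        # >= 2 samples per group is required for testing (enforced in de_test)

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Analysis constants for the whole pipeline.

    Defaults encode the study conventions: genotype groups need 10
    observations, genomic-control kicks in above lambda = 1.05, simpleM keeps
    99.5% of the per-chromosome genotype-correlation variance, QTL support
    intervals use a 1.5 LOD drop, and significance is tested at 5% / 1%
    after Bonferroni over the effective number of tests.
    """

    group_min: int = 10
    alpha_covariate: float = 0.05
    lambda_trigger: float = 1.05
    lambda_df: int = 1
    simpleM_variance_fraction: float = 0.995
    simpleM_per_chromosome: bool = True
    alpha_sig: float = 0.05
    alpha_highsig: float = 0.01
    lod_drop: float = 1.5
    de_alpha: float = 0.05
    kegg_gene_set: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_covariate", "simpleM_variance_fraction", "alpha_sig",
                     "alpha_highsig", "de_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.group_min < 1:
            raise ValueError("group_min must be >= 1")
        if self.lod_drop <= 0:
            raise ValueError("lod_drop must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, dtype=str)


def read_genotypes(
    path: str | Path,
    map_path: str | Path | None = None,
    call_symbols: Mapping[str, int] = DEFAULT_CALL_SYMBOLS,
) -> GenotypeMatrix:
    """Read a wide marker-by-individual genotype file plus a marker map.

    The genotype file has one row per marker; its first column is
    ``marker_id`` and the remaining columns are individuals, with calls in
    the symbol dialect (default A/H/B/NA).  The map is either a separate
    file (``marker_id``, ``chromosome``, ``position_bp`` [, ``position_cM``])
    or embedded as ``chromosome``/``position_bp`` columns of the genotype
    file itself.
    """
    wide = _read_table(path)
    if "marker_id" not in wide.columns:
        raise FormatError("genotype file needs a marker_id column")
    embedded = [c for c in ("chromosome", "position_bp", "position_cM") if c in wide.columns]
    if map_path is not None:
        mp = _read_table(map_path)
        if not {"marker_id", "chromosome", "position_bp"} <= set(mp.columns):
            raise FormatError("map file needs marker_id, chromosome, position_bp")
        mp = mp.set_index("marker_id")
        try:
            mp = mp.loc[wide.marker_id]
        except KeyError as exc:
            raise FormatError(f"marker missing from map file: {exc}") from exc
        marker_map = make_marker_map(
            wide.marker_id,
            mp.chromosome.to_numpy(),
            mp.position_bp.astype(np.int64).to_numpy(),
            mp.position_cM.astype(float).to_numpy() if "position_cM" in mp.columns else None,
        )
    elif {"chromosome", "position_bp"} <= set(embedded):
        marker_map = make_marker_map(
            wide.marker_id,
            wide.chromosome,
            wide.position_bp.astype(np.int64),
            wide.position_cM.astype(float) if "position_cM" in wide.columns else None,
        )
    else:
        raise FormatError("no map: pass map_path or embed chromosome/position_bp columns")

    ind_cols = [c for c in wide.columns if c not in ("marker_id", *embedded)]
    if not ind_cols:
        raise FormatError("genotype file has no individual columns")

    lut = dict(call_symbols)
    calls = np.empty((len(ind_cols), len(wide)), dtype=np.int8)
    for j, col in enumerate(ind_cols):
        raw = wide[col]
        for i, sym in enumerate(raw):
            sym = "NA" if pd.isna(sym) else str(sym)
            if sym not in lut:
                raise FormatError(
                    f"unknown call symbol {sym!r} at marker {wide.marker_id.iat[i]!r}, "
                    f"individual {col!r}"
                )
            calls[j, i] = lut[sym]

    # re-align call columns to the sorted marker map
    pos = {m: k for k, m in enumerate(wide.marker_id)}
    order = [pos[m] for m in marker_map.marker_id]
    gm = GenotypeMatrix(ind_cols, marker_map, calls[:, order])
    logger.info("read %d markers x %d individuals from %s",
                gm.n_markers, gm.n_individuals, path)
    return gm


def write_genotypes(
    gm: GenotypeMatrix,
    path: str | Path,
    map_path: str | Path | None = None,
    call_symbols: Mapping[str, int] = DEFAULT_CALL_SYMBOLS,
) -> None:
    """Inverse of :func:`read_genotypes` (round-trip identity)."""
    rev = {v: k for k, v in call_symbols.items()}
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    wide = pd.DataFrame(
        {ind: [rev[int(v)] for v in gm.calls[i]] for i, ind in enumerate(gm.individuals)}
    )
    wide.insert(0, "marker_id", gm.markers.marker_id.to_numpy())
    if map_path is None:
        wide.insert(1, "chromosome", gm.markers.chromosome.to_numpy())
        wide.insert(2, "position_bp", gm.markers.position_bp.to_numpy())
        if "position_cM" in gm.markers.columns:
            wide.insert(3, "position_cM", gm.markers.position_cM.to_numpy())
    else:
        gm.markers.to_csv(map_path, sep="\t" if str(map_path).endswith((".tsv", ".txt")) else ",",
                          index=False)
    wide.to_csv(path, sep=sep, index=False)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    df["individual_id"] = df["individual_id"].astype(str)
    df["subfamily"] = df["subfamily"].astype(str)
    return PhenotypeTable(df)


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    pheno.data.to_csv(path, sep=sep, index=False)


def read_variant_annotations(path: str | Path) -> pd.DataFrame:
    """Read a variant-annotation table (TSV/CSV, or VCF with VEP CSQ field).

    Tabular input must carry the canonical columns (see
    ``ANNOTATION_COLUMNS``).  VCF input is parsed through the consequence
    mapping tables; terms outside the mapping become ("none", "none") and
    are counted in the skip log.
    """
    p = str(path)
    if p.endswith(".vcf") or p.endswith(".vcf.gz"):
        return _read_annotations_vcf(path)
    df = _read_table(path)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"annotation file missing columns {sorted(missing)}")
    df = df.copy()
    df["sift_class"] = df["sift_class"].fillna("n/a")  # "n/a" parses as NaN
    df["position_bp"] = df["position_bp"].astype(np.int64)
    df["in_functional_domain"] = df["in_functional_domain"].astype(str).str.lower().isin(
        ["true", "1", "yes"]
    )
    return validate_annotations(df)


def _read_annotations_vcf(path: str | Path) -> pd.DataFrame:
    import pysam  # optional dependency, only needed for VCF input

    vf = pysam.VariantFile(str(path))
    try:
        csq_header = vf.header.info["CSQ"].description
    except KeyError as exc:
        raise FormatError("VCF lacks a CSQ (VEP) INFO field") from exc
    fields = csq_header.split("Format: ")[-1].split("|")
    idx = {name: i for i, name in enumerate(fields)}
    for needed in ("Gene", "SYMBOL", "Consequence"):
        if needed not in idx:
            raise FormatError(f"CSQ format lacks field {needed}")

    rows = []
    skipped: dict[str, int] = {}
    for rec in vf:
        for csq in rec.info.get("CSQ", ()):  # type: ignore[union-attr]
            parts = csq.split("|")

            def get(fieldname: str) -> str:
                i = idx.get(fieldname)
                return parts[i] if i is not None and i < len(parts) else ""

            sift_raw = get("SIFT").split("(")[0]
            biotype = get("BIOTYPE")
            domains = get("DOMAINS")
            for term in get("Consequence").split("&"):
                if term in VEP_CONSEQUENCE_MAP:
                    coding, reg = VEP_CONSEQUENCE_MAP[term]
                elif term == "regulatory_region_variant" and biotype in VEP_BIOTYPE_MAP:
                    coding, reg = "none", VEP_BIOTYPE_MAP[biotype]
                else:
                    coding, reg = "none", "none"
                    skipped[term] = skipped.get(term, 0) + 1
                sift = sift_raw if (coding == "missense" and sift_raw in
                                    ("deleterious", "tolerated")) else "n/a"
                rows.append(
                    {
                        "gene_id": get("Gene"),
                        "gene_symbol": get("SYMBOL") or get("Gene"),
                        "chromosome": str(rec.chrom),
                        "position_bp": int(rec.pos),
                        "coding_consequence": coding,
                        "sift_class": sift,
                        "in_functional_domain": coding == "missense" and bool(domains),
                        "regulatory_feature": reg,
                    }
                )
    if skipped:
        logger.info("VCF consequence terms outside the mapping (skipped): %s", skipped)
    if not rows:
        return pd.DataFrame(columns=ANNOTATION_COLUMNS)
    return validate_annotations(pd.DataFrame(rows))


def write_variant_annotations(df: pd.DataFrame, path: str | Path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    validate_annotations(df).to_csv(path, sep=sep, index=False)


def read_expression(path: str | Path, groups_path: str | Path,
                    log2_transformed: bool = False) -> ExpressionMatrix:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    values = pd.read_csv(path, sep=sep, index_col=0)
    gsep = "\t" if str(groups_path).endswith((".tsv", ".txt")) else ","
    gdf = pd.read_csv(groups_path, sep=gsep, dtype=str)
    if not {"sample_id", "group"} <= set(gdf.columns):
        raise FormatError("groups file needs sample_id and group columns")
    groups = gdf.set_index("sample_id")["group"]
    return ExpressionMatrix(values, groups, log2_transformed=log2_transformed)


def write_expression(mat: ExpressionMatrix, path: str | Path,
                     groups_path: str | Path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    mat.values.to_csv(path, sep=sep)
    pd.DataFrame({"sample_id": mat.groups.index, "group": mat.groups.to_numpy()}).to_csv(
        groups_path, sep="\t" if str(groups_path).endswith((".tsv", ".txt")) else ",",
        index=False)


# ---------------------------------------------------------------------------
# Writers for analysis results
# ---------------------------------------------------------------------------


def regions_to_bed(regions: Iterable, path: str | Path) -> None:
    """Write QTL regions as BED (0-based half-open, converted from 1-based
    inclusive bp).  An empty region list yields a valid empty file."""
    lines = []
    for r in regions:
        name = f"{r.trait}:{r.top_marker}"
        lines.append(
            f"{r.chromosome}\t{r.start_bp - 1}\t{r.stop_bp}\t{name}\t{r.top_lod:.4f}"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def bed_to_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    """Read BED back to 1-based inclusive (chromosome, start_bp, stop_bp)."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("track", "browser", "#")):
            continue
        f = line.split("\t")
        out.append((f[0], int(f[1]) + 1, int(f[2])))
    return out


def write_run_log(path: str | Path, config: RunConfig, scans: Iterable = (),
                  extra: Mapping | None = None) -> None:
    """JSON provenance record: configuration, seed, and per-scan lambda and
    thresholds."""
    payload: dict = {"config": config.to_dict(), "seed": config.seed, "scans": []}
    for s in scans:
        payload["scans"].append(
            {
                "trait": s.trait,
                "lambda": s.lambda_,
                "lambda_applied": s.lambda_applied,
                "lod_sig": s.lod_sig,
                "lod_highsig": s.lod_highsig,
                "meff": s.meff,
                "covariates": list(s.covariates),
                "cofactors": list(s.cofactors),
            }
        )
    if extra:
        payload.update(dict(extra))
    Path(path).write_text(json.dumps(payload, indent=2, default=float) + "\n")


def write_scan_tsv(scan_result, path: str | Path) -> None:
    """Per-marker scan table as TSV (marker, position, class counts and
    means, raw and corrected p/LOD, partial R^2)."""
    scan_result.table.to_csv(path, sep="\t", index=False)


def write_gene_scores(ranked: pd.DataFrame, path: str | Path) -> None:
    """Ranked gene-score table as TSV, descending by total."""
    ranked.to_csv(path, sep="\t", index=False)


def write_correlation(corr, path_prefix: str | Path) -> None:
    """Correlation outputs: rho, p and significance-flag TSVs."""
    prefix = str(path_prefix)
    corr.rho.to_csv(prefix + ".rho.tsv", sep="\t")
    corr.p.to_csv(prefix + ".p.tsv", sep="\t")
    corr.significant.to_csv(prefix + ".sig.tsv", sep="\t")


# ---------------------------------------------------------------------------
# Reporting helpers (class-mean contrasts as printed in results tables)
# ---------------------------------------------------------------------------


def percent_increase(mean_a: float, mean_b: float) -> float:
    """Relative increase of class mean A over class mean B, in percent."""
    if mean_b == 0:
        raise ZeroDivisionError("reference class mean is zero")
    return (mean_a - mean_b) / mean_b * 100.0


def format_class_contrast(mean_a: float, mean_b: float, unit: str = "",
                          absolute: bool = False) -> str:
    """Human-readable contrast between two genotype-class means.

    Relative contrasts print as whole percent ("17%"); absolute contrasts
    print the difference with two decimals and the unit ("10.09 g").
    """
    if absolute:
        return f"{mean_a - mean_b:.2f} {unit}".strip()
    return f"{percent_increase(mean_a, mean_b):.0f}%"
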