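"""Candidate-gene prioritization: the decision-tree score and ranking.

Each gene in a QTL region is scored from its variant annotations, its
liver differential-expression status and its KEGG pathway membership:

=====================================  ======
component                              points
=====================================  ======
stop gain / stop loss                       3
missense in a functional domain             3
missense SIFT deleterious                   3
missense SIFT tolerated (no deleterious)    1
promoter variant                            3
splice-site variant                         3
UTR variant                                 1
enhancer variant                            1
CTCF-binding-site variant                   1
differentially expressed in liver           2
relevant KEGG metabolic pathway             1
=====================================  ======

Category-once semantics: a component contributes its full value when ANY
variant of the gene triggers it, however many do (so duplicated annotation
rows never change a score), and the domain and SIFT components of the same
missense variant add.  The maximum total is 21.  A per-variant additive
variant of the rules is available behind a flag for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import pandas as pd

from .io import validate_annotations
from .expression import DEResult

MAX_SCORE = 21

_COMPONENTS = ("coding_stop", "coding_domain_missense", "coding_sift",
               "promoter", "splice", "utr", "enhancer", "ctcf",
               "de_liver", "kegg")


@dataclass
class GeneScore:
    gene: str
    coding_stop: int = 0  # 0 or 3
    coding_domain_missense: int = 0  # 0 or 3
    coding_sift: int = 0  # 0, 1 or 3
    promoter: int = 0  # 0 or 3
    splice: int = 0  # 0 or 3
    utr: int = 0  # 0 or 1
    enhancer: int = 0  # 0 or 1
    ctcf: int = 0  # 0 or 1
    de_liver: int = 0  # 0 or 2
    kegg: int = 0  # 0 or 1
    total: int = field(init=False)

    def __post_init__(self) -> None:
        self.total = sum(getattr(self, c) for c in _COMPONENTS)

    def to_dict(self) -> dict:
        return asdict(self)


def score_gene(annotations: pd.DataFrame, de_bh_p: float | None = None,
               in_kegg: bool = False, de_alpha: float = 0.05,
               per_variant: bool = False, gene: str | None = None) -> GeneScore:
    """Score one gene from its annotation rows, DE status and KEGG flag.

    ``annotations`` holds the gene's rows of a variant-annotation table
    (may be empty: no variants, score from DE/KEGG only).  ``de_bh_p`` is
    the gene's BH-adjusted liver DE p-value, or None when the gene was not
    tested.  With ``per_variant=True`` every triggering variant row counts
    (sensitivity analysis), instead of each category at most once.
    """
    ann = validate_annotations(annotations) if len(annotations) else annotations
    if len(ann):
        symbols = set(ann.gene_symbol.astype(str))
        if gene is None:
            if len(symbols) > 1:
                raise ValueError(f"annotation rows span several genes: {sorted(symbols)}")
            gene = symbols.pop()
    if gene is None:
        raise ValueError("gene symbol required when there are no annotation rows")

    def count(mask) -> int:
        n = int(mask.sum())
        return n if per_variant else min(n, 1)

    if len(ann):
        stop = count(ann.coding_consequence.isin(["stop_gain", "stop_loss"]))
        missense = ann.coding_consequence == "missense"
        domain = count(missense & ann.in_functional_domain)
        n_del = count(missense & (ann.sift_class == "deleterious"))
        n_tol = count(missense & (ann.sift_class == "tolerated"))
        prom = count(ann.regulatory_feature == "promoter")
        spl = count(ann.regulatory_feature == "splice_site")
        utr = count(ann.regulatory_feature == "utr")
        enh = count(ann.regulatory_feature == "enhancer")
        ctcf = count(ann.regulatory_feature == "ctcf_binding_site")
    else:
        stop = domain = n_del = n_tol = prom = spl = utr = enh = ctcf = 0

    # SIFT: deleterious dominates tolerated under category-once semantics
    sift = 3 * n_del + 1 * n_tol if per_variant else (3 if n_del else (1 if n_tol else 0))
    de_sig = de_bh_p is not None and de_bh_p < de_alpha
    gs = GeneScore(
        gene=gene,
        coding_stop=3 * stop,
        coding_domain_missense=3 * domain,
        coding_sift=sift,
        promoter=3 * prom,
        splice=3 * spl,
        utr=1 * utr,
        enhancer=1 * enh,
        ctcf=1 * ctcf,
        de_liver=2 if de_sig else 0,
        kegg=1 if in_kegg else 0,
    )
    if not per_variant:
        assert 0 <= gs.total <= MAX_SCORE  # bound holds for category-once only
    return gs


def score_genes(annotations: pd.DataFrame, de: DEResult | None = None,
                kegg_gene_set: Sequence[str] = (), de_alpha: float = 0.05,
                genes: Sequence[str] | None = None) -> list[GeneScore]:
    """Score every gene of an annotation table (plus any extra ``genes``
    that have DE/KEGG evidence but no variants)."""
    kegg = set(kegg_gene_set)
    ann_genes = list(pd.unique(annotations.gene_symbol)) if len(annotations) else []
    all_genes = list(dict.fromkeys([*ann_genes, *(genes or [])]))
    out = []
    for g in all_genes:
        rows = annotations[annotations.gene_symbol == g] if len(annotations) else annotations
        bh = None
        if de is not None and g in de.table.index:
            bh = de.bh_p(g)
        out.append(score_gene(rows, de_bh_p=bh, in_kegg=g in kegg,
                              de_alpha=de_alpha, gene=g))
    return out


def rank_genes(scores: Iterable[GeneScore]) -> pd.DataFrame:
    """Ranked candidate table: descending total, ties alphabetical.

    Genes with a zero total stay at the bottom, flagged
    "non-polymorphic or unscored".  Duplicate gene entries are an error
    (scores must be aggregated per gene beforehand).
    """
    scores = list(scores)
    names = [s.gene for s in scores]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate gene entries: {dup}")
    df = pd.DataFrame([s.to_dict() for s in scores])
    if df.empty:
        return pd.DataFrame(columns=["gene", *_COMPONENTS, "total", "flag"])
    df["flag"] = ""
    df.loc[df.total == 0, "flag"] = "non-polymorphic or unscored"
    return (df.sort_values(["total", "gene"], ascending=[False, True])
            .reset_index(drop=True))


def genes_in_regions(gene_positions: pd.DataFrame, regions: Iterable) -> list[str]:
    """Positional filter: genes whose midpoint falls inside a QTL region.

    ``gene_positions`` needs columns gene_symbol, chromosome, start_bp,
    stop_bp (1-based inclusive).
    """
    mid = (gene_positions.start_bp + gene_positions.stop_bp) / 2.0
    keep = pd.Series(False, index=gene_positions.index)
    for r in regions:
        keep |= ((gene_positions.chromosome.astype(str) == str(r.chromosome))
                 & (mid >= r.start_bp) & (mid <= r.stop_bp))
    return list(pd.unique(gene_positions.gene_symbol[keep]))
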