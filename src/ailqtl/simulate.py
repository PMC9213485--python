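"""Forward simulation of an advanced intercross line (AIL) and the
associated phenotype, expression and variant-annotation data.

The generative model mirrors the data structure the analysis assumes:

* Two fully inbred founder lines, homozygous for opposite alleles at every
  marker, are crossed; from F1 on, each generation is produced by random
  monogamous pairing within the generation (full-sib pairs excluded from
  generation 2 onward — all F1 animals are full sibs and genetically
  identical heterozygotes, so the restriction is vacuous there).
* Meiosis uses Haldane's no-interference model: per chromosome the
  crossover count is Poisson with mean ``chromosome_length_cM / 100`` and
  crossover positions are uniform on the genetic map.  Marker genetic
  positions are interpolated from bp at ``cM_per_Mb`` when no map is given.
* Quantitative traits are built additively: intercept + sex effect +
  per-dam subfamily effect (Normal(0, subfamily_sd^2)) + litter-size slope +
  per-QTL genotype effect (-a, d, +a for the line-2 homozygote,
  heterozygote, line-1 homozygote at the marker nearest the QTL) +
  Gaussian residual.
* Expression is two-group log2-normal intensity data with planted shifts;
  variant annotations draw each scoring category independently per gene.

Randomness is split over fixed, purpose-keyed streams derived from one
global seed, so e.g. adding markers does not perturb the pedigree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    GenotypeMatrix,
    ExpressionMatrix,
    PhenotypeTable,
    GROUP_LINE1,
    GROUP_LINE2,
    MISSING,
    make_marker_map,
    validate_annotations,
    logger,
)

# purpose keys for the hierarchical random streams
_STREAM_PEDIGREE = 0
_STREAM_MEIOSIS = 1
_STREAM_MISSING = 2
_STREAM_PHENOTYPE = 3
_STREAM_EXPRESSION = 4
_STREAM_ANNOTATION = 5


def _stream(seed: int, purpose: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), purpose]))


@dataclass
class QTLSpec:
    chromosome: str
    position_cM: float
    additive: float  # a: half the homozygote difference
    dominance: float  # d: heterozygote deviation from the homozygote midpoint
    trait: str = "trait"


@dataclass
class CovariateEffects:
    sex_effect: float = 0.0  # added for males
    subfamily_sd: float = 0.0  # SD of per-dam random shifts
    litter_slope: float = 0.0  # per-pup change of the trait


@dataclass
class SimulationConfig:
    """Full generative specification; defaults emulate the study design:
    a ~120-animal generation-10 AIL genotyped at a few hundred markers."""

    n_chromosomes: int = 5
    markers_per_chromosome: int = 100
    chromosome_length_cM: float = 80.0
    cM_per_Mb: float = 0.5
    n_f2: int | None = None  # generation-2 size; default pairs * offspring
    pairs_per_generation: int = 62
    offspring_per_pair: int = 2
    final_generation: int = 10
    qtl_specs: list[QTLSpec] = field(default_factory=list)
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    trait_intercept: float = 0.0
    residual_sd: float = 1.0
    missing_rate: float = 0.0
    # expression block
    n_genes: int = 500
    de_specs: list[tuple[str, float]] = field(default_factory=list)
    expression_baseline_mean: float = 8.0
    expression_baseline_sd: float = 2.0
    expression_noise_sd: float = 0.25
    n_samples_per_group: tuple[int, int] = (6, 5)
    # annotation block
    annotation_frequencies: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.final_generation < 2:
            raise ValueError("final_generation must be >= 2")
        for name in ("n_chromosomes", "markers_per_chromosome",
                     "pairs_per_generation", "offspring_per_pair"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0,1)")
        for k, v in self.annotation_frequencies.items():
            if not 0 <= v <= 1:
                raise ValueError(f"annotation frequency {k}={v} outside [0,1]")
        if isinstance(self.n_samples_per_group, int):
            self.n_samples_per_group = (self.n_samples_per_group,
                                        self.n_samples_per_group)

    @property
    def generation_size(self) -> int:
        return self.pairs_per_generation * self.offspring_per_pair


def default_marker_map(config: SimulationConfig) -> pd.DataFrame:
    """Evenly spaced markers on each chromosome, with cM interpolated from
    bp through the linear ``cM_per_Mb`` map."""
    ids, chroms, bps, cms = [], [], [], []
    for c in range(1, config.n_chromosomes + 1):
        cm = np.linspace(0.0, config.chromosome_length_cM,
                         config.markers_per_chromosome)
        bp = np.round(cm / config.cM_per_Mb * 1e6).astype(np.int64) + 1
        for j in range(config.markers_per_chromosome):
            ids.append(f"m{c}_{j + 1:04d}")
        chroms.extend([str(c)] * config.markers_per_chromosome)
        bps.extend(bp.tolist())
        cms.extend(cm.tolist())
    return make_marker_map(ids, chroms, bps, cms)


def _gamete(haps: np.ndarray, cm: np.ndarray, length_cM: float,
            rng: np.random.Generator) -> np.ndarray:
    """One meiotic product from a (2, m) haplotype pair (Haldane model)."""
    k = rng.poisson(length_cM / 100.0)
    start = rng.integers(2)
    if k == 0:
        return haps[start]
    xos = np.sort(rng.uniform(0.0, length_cM, k))
    which = (start + np.searchsorted(xos, cm, side="right")) % 2
    return np.where(which == 0, haps[0], haps[1])


def simulate_ail(config: SimulationConfig, *, return_haplotypes: bool = False):
    """Simulate the intercross to ``final_generation``.

    Returns ``(GenotypeMatrix, pedigree)`` where the genotype matrix holds
    the final generation only and the pedigree (DataFrame: id, generation,
    sire, dam, sex) covers every generation.  With ``return_haplotypes``
    a third element maps generation -> (ids, {chromosome: (n, 2, m) allele
    array}) for haplotype-level diagnostics; allele 1 is the line-1 allele.
    """
    markers = default_marker_map(config)
    cm_by_chrom = {
        str(c): markers.loc[markers.chromosome == str(c), "position_cM"].to_numpy()
        for c in range(1, config.n_chromosomes + 1)
    }
    chrom_order = [str(c) for c in range(1, config.n_chromosomes + 1)]

    rng_ped = _stream(config.seed, _STREAM_PEDIGREE)
    rng_mei = _stream(config.seed, _STREAM_MEIOSIS)

    ped_rows = [
        {"id": "G00_1", "generation": 0, "sire": None, "dam": None, "sex": "M"},
        {"id": "G00_2", "generation": 0, "sire": None, "dam": None, "sex": "F"},
    ]
    haps = {
        "G00_1": {c: np.ones((2, len(cm_by_chrom[c])), dtype=np.int8)
                  for c in chrom_order},
        "G00_2": {c: np.zeros((2, len(cm_by_chrom[c])), dtype=np.int8)
                  for c in chrom_order},
    }
    parents_of = {"G00_1": None, "G00_2": None}
    generation_ids = {0: ["G00_1", "G00_2"]}
    kept = {}

    current = [("G00_1", "G00_2")]  # pairs producing the next generation
    for gen in range(1, config.final_generation + 1):
        if gen == 1:
            n_offspring = 2 * config.pairs_per_generation
        elif gen == 2 and config.n_f2 is not None:
            n_offspring = config.n_f2
        else:
            n_offspring = config.generation_size
        new_ids, new_haps = [], {}
        sexes = rng_ped.integers(0, 2, n_offspring)  # Bernoulli(0.5)
        for i in range(n_offspring):
            sire, dam = current[i % len(current)]
            iid = f"G{gen:02d}_{i + 1}"
            new_ids.append(iid)
            child = {}
            for c in chrom_order:
                g1 = _gamete(haps[sire][c], cm_by_chrom[c],
                             config.chromosome_length_cM, rng_mei)
                g2 = _gamete(haps[dam][c], cm_by_chrom[c],
                             config.chromosome_length_cM, rng_mei)
                child[c] = np.stack([g1, g2])
            new_haps[iid] = child
            parents_of[iid] = (sire, dam)
            ped_rows.append({"id": iid, "generation": gen, "sire": sire,
                             "dam": dam, "sex": "M" if sexes[i] else "F"})
        generation_ids[gen] = new_ids
        if return_haplotypes:
            kept[gen] = (new_ids, {c: np.stack([new_haps[i][c] for i in new_ids])
                                   for c in chrom_order})
        haps = new_haps
        if gen < config.final_generation:
            current = _form_pairs(new_ids, ped_rows, parents_of,
                                  config.pairs_per_generation, rng_ped,
                                  allow_sibs=(gen == 1))

    final_ids = generation_ids[config.final_generation]
    calls = np.empty((len(final_ids), len(markers)), dtype=np.int8)
    for i, iid in enumerate(final_ids):
        calls[i] = np.concatenate([haps[iid][c].sum(axis=0) for c in chrom_order])
    if config.missing_rate > 0:
        rng_miss = _stream(config.seed, _STREAM_MISSING)
        drop = rng_miss.random(calls.shape) < config.missing_rate
        calls[drop] = MISSING

    gm = GenotypeMatrix(final_ids, markers, calls)
    pedigree = pd.DataFrame(ped_rows)
    logger.info("simulated AIL: %d generations, %d final individuals, %d markers",
                config.final_generation, len(final_ids), len(markers))
    if return_haplotypes:
        return gm, pedigree, kept
    return gm, pedigree


def _form_pairs(ids, ped_rows, parents_of, n_pairs, rng, allow_sibs):
    """Random monogamous male-female pairs, excluding full sibs.

    Forms at most ``n_pairs`` pairs; the next generation's offspring are
    distributed round-robin over the formed pairs, so a sex-ratio
    fluctuation shrinks litter counts rather than the population.
    """
    by_id = {r["id"]: r for r in ped_rows}
    males = [i for i in ids if by_id[i]["sex"] == "M"]
    females = [i for i in ids if by_id[i]["sex"] == "F"]
    target = min(n_pairs, len(males), len(females))
    if target < 1:
        raise ValueError(
            "cannot form any mating pair (single-sex generation); "
            "increase pairs_per_generation or offspring_per_pair"
        )
    for _attempt in range(200):
        ms = list(rng.permutation(males))
        fs = list(rng.permutation(females))
        pairs = []
        for m in ms:
            if len(pairs) == target:
                break
            for j, f in enumerate(fs):
                if allow_sibs or parents_of[m] != parents_of[f]:
                    pairs.append((m, f))
                    fs.pop(j)
                    break
        if len(pairs) == target:
            return pairs
    raise ValueError(
        "population too small to avoid full-sib mating; "
        "increase pairs_per_generation"
    )


def simulate_phenotypes(genotypes: GenotypeMatrix, pedigree: pd.DataFrame,
                        config: SimulationConfig) -> PhenotypeTable:
    """Simulate covariates and traits for the genotyped individuals.

    Deterministic given ``config.seed``.  Subfamily is the dam id; litter
    size is the dam's offspring count in the final generation.
    """
    for q in config.qtl_specs:
        if str(q.chromosome) not in set(genotypes.markers.chromosome):
            raise ValueError(f"QTL chromosome {q.chromosome!r} absent from map")

    rng = _stream(config.seed, _STREAM_PHENOTYPE)
    ped = pedigree.set_index("id")
    rows = ped.loc[genotypes.individuals]
    dams = rows["dam"].astype(str)
    litter = dams.map(dams.value_counts())

    eff = config.covariate_effects
    dam_levels = sorted(dams.unique())
    dam_shift = dict(zip(dam_levels, rng.normal(0.0, eff.subfamily_sd,
                                                len(dam_levels))))

    traits = sorted({q.trait for q in config.qtl_specs}) or ["trait"]
    n = genotypes.n_individuals
    is_male = (rows["sex"] == "M").to_numpy()
    base = (config.trait_intercept
            + eff.sex_effect * is_male
            + np.array([dam_shift[d] for d in dams])
            + eff.litter_slope * litter.to_numpy())

    data = pd.DataFrame({
        "individual_id": genotypes.individuals,
        "sex": rows["sex"].to_numpy(),
        "subfamily": dams.to_numpy(),
        "litter_size": litter.to_numpy(),
    })
    for t in traits:
        y = base.copy()
        for q in config.qtl_specs:
            if q.trait != t:
                continue
            y += _qtl_contribution(genotypes, q)
        y += rng.normal(0.0, config.residual_sd, n)
        data[t] = y
    return PhenotypeTable(data, traits)


def _qtl_contribution(genotypes: GenotypeMatrix, q: QTLSpec) -> np.ndarray:
    mk = genotypes.markers
    on_chrom = mk.index[mk.chromosome == str(q.chromosome)]
    if "position_cM" in mk.columns and mk.loc[on_chrom, "position_cM"].notna().all():
        pos = mk.loc[on_chrom, "position_cM"].to_numpy()
        target = q.position_cM
    else:  # fall back to bp through the default linear map
        pos = mk.loc[on_chrom, "position_bp"].to_numpy() / 1e6 * 0.5
        target = q.position_cM
    nearest = on_chrom[int(np.argmin(np.abs(pos - target)))]
    calls = genotypes.calls[:, nearest]
    g = np.select(
        [calls == 2, calls == 1, calls == 0],
        [q.additive, q.dominance, -q.additive],
        default=q.dominance / 2.0,  # missing call: population-mean contribution
    )
    return g


def simulate_expression(config: SimulationConfig
                        ) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Two-group array intensities with planted differential genes.

    Per-gene baseline log2 intensity ~ Normal(baseline_mean, baseline_sd^2);
    planted genes are shifted by their log2 effect in group LINE1; i.i.d.
    Gaussian noise per sample.  Intensities are exported on the raw (2^x)
    scale.  Returns the matrix and a truth table (gene, log2_effect, is_de).
    """
    n1, n2 = config.n_samples_per_group
    if min(n1, n2) < 2:
        raise ValueError("need at least 2 samples per group")
    rng = _stream(config.seed, _STREAM_EXPRESSION)
    genes = [f"g{i + 1:04d}" for i in range(config.n_genes)]
    extra = [g for g, _ in config.de_specs if g not in set(genes)]
    genes = genes + sorted(extra)
    effects = pd.Series(0.0, index=genes)
    for g, e in config.de_specs:
        effects[g] = e

    baseline = rng.normal(config.expression_baseline_mean,
                          config.expression_baseline_sd, len(genes))
    log2 = np.empty((len(genes), n1 + n2))
    log2[:, :n1] = (baseline + effects.to_numpy())[:, None]
    log2[:, n1:] = baseline[:, None]
    log2 += rng.normal(0.0, config.expression_noise_sd, log2.shape)

    samples = [f"S1_{i + 1}" for i in range(n1)] + [f"B6_{i + 1}" for i in range(n2)]
    groups = pd.Series([GROUP_LINE1] * n1 + [GROUP_LINE2] * n2, index=samples)
    mat = ExpressionMatrix(pd.DataFrame(2.0 ** log2, index=genes, columns=samples),
                           groups, log2_transformed=False)
    truth = pd.DataFrame({"gene": genes, "log2_effect": effects.to_numpy(),
                          "is_de": effects.to_numpy() != 0.0})
    return mat, truth


# categories drawn independently per gene; values = (column updates, points)
_ANNOTATION_CATEGORIES: Mapping[str, dict] = {
    "stop_gain": {"coding_consequence": "stop_gain"},
    "stop_loss": {"coding_consequence": "stop_loss"},
    "missense_deleterious_domain": {"coding_consequence": "missense",
                                    "sift_class": "deleterious",
                                    "in_functional_domain": True},
    "missense_deleterious_nondomain": {"coding_consequence": "missense",
                                       "sift_class": "deleterious"},
    "missense_tolerated_domain": {"coding_consequence": "missense",
                                  "sift_class": "tolerated",
                                  "in_functional_domain": True},
    "missense_tolerated_nondomain": {"coding_consequence": "missense",
                                     "sift_class": "tolerated"},
    "promoter": {"regulatory_feature": "promoter"},
    "splice_site": {"regulatory_feature": "splice_site"},
    "utr": {"regulatory_feature": "utr"},
    "enhancer": {"regulatory_feature": "enhancer"},
    "ctcf": {"regulatory_feature": "ctcf_binding_site"},
}


def simulate_annotations(genes: Sequence[str], config: SimulationConfig,
                         de_genes: Sequence[str] = (),
                         kegg_genes: Sequence[str] = ()
                         ) -> tuple[pd.DataFrame, pd.Series]:
    """Draw per-gene variant-annotation categories and their truth scores.

    Each scoring category is an independent Bernoulli draw with the
    configured frequency (absent categories default to 0).  The returned
    truth series is the prioritization total each gene must receive under
    the decision tree, computed here by direct enumeration of the drawn
    category flags (independently of the scoring module).
    """
    freqs = config.annotation_frequencies
    rng = _stream(config.seed, _STREAM_ANNOTATION)
    de_set, kegg_set = set(de_genes), set(kegg_genes)

    rows, truth = [], {}
    pos = 1000
    for gene in genes:
        drawn = {cat: (rng.random() < freqs.get(cat, 0.0))
                 for cat in _ANNOTATION_CATEGORIES}
        for cat, updates in _ANNOTATION_CATEGORIES.items():
            if not drawn[cat]:
                continue
            pos += 1
            row = {"gene_id": gene, "gene_symbol": gene, "chromosome": "1",
                   "position_bp": pos, "coding_consequence": "none",
                   "sift_class": "n/a", "in_functional_domain": False,
                   "regulatory_feature": "none"}
            row.update(updates)
            rows.append(row)
        truth[gene] = _truth_score(drawn, gene in de_set, gene in kegg_set)

    table = (validate_annotations(pd.DataFrame(rows)) if rows
             else pd.DataFrame(columns=list(
                 validate_annotations(pd.DataFrame([{
                     "gene_id": "x", "gene_symbol": "x", "chromosome": "1",
                     "position_bp": 1, "coding_consequence": "none",
                     "sift_class": "n/a", "in_functional_domain": False,
                     "regulatory_feature": "none"}])).columns)))
    return table, pd.Series(truth, name="truth_score")


def _truth_score(drawn: Mapping[str, bool], is_de: bool, in_kegg: bool) -> int:
    """Decision-tree total by direct enumeration of category flags."""
    score = 0
    if drawn["stop_gain"] or drawn["stop_loss"]:
        score += 3
    if drawn["missense_deleterious_domain"] or drawn["missense_tolerated_domain"]:
        score += 3
    if drawn["missense_deleterious_domain"] or drawn["missense_deleterious_nondomain"]:
        score += 3
    elif drawn["missense_tolerated_domain"] or drawn["missense_tolerated_nondomain"]:
        score += 1
    if drawn["promoter"]:
        score += 3
    if drawn["splice_site"]:
        score += 3
    if drawn["utr"]:
        score += 1
    if drawn["enhancer"]:
        score += 1
    if drawn["ctcf"]:
        score += 1
    if is_de:
        score += 2
    if in_kegg:
        score += 1
    return score
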