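"""The AIL forward simulator: Mendelian segregation, map expansion,
trait construction, determinism and pedigree consistency."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ailqtl import (SimulationConfig, QTLSpec, CovariateEffects, simulate_ail,
                    simulate_phenotypes, simulate_expression, normalize,
                    write_expression, read_expression)
from ailqtl.io import HOM_LINE1, HET, HOM_LINE2


def test_f1_heterozygous_everywhere():
    """Inbred x inbred: every F1 individual is heterozygous at every marker."""
    cfg = SimulationConfig(n_chromosomes=2, markers_per_chromosome=15,
                           pairs_per_generation=10, final_generation=2, seed=0)
    _, _, haps = simulate_ail(cfg, return_haplotypes=True)
    ids, by_chrom = haps[1]
    for arr in by_chrom.values():
        assert np.all(arr.sum(axis=1) == 1)  # one line-1 + one line-2 allele


def test_f2_segregates_1_2_1():
    """Single-marker genotype frequencies in a large F2 fit 1:2:1."""
    cfg = SimulationConfig(n_chromosomes=1, markers_per_chromosome=5,
                           pairs_per_generation=50, n_f2=2000,
                           final_generation=2, seed=1)
    gm, _ = simulate_ail(cfg)
    counts = gm.class_counts(2)
    n = sum(counts.values())
    chi2 = stats.chisquare(
        [counts[HOM_LINE2], counts[HET], counts[HOM_LINE1]],
        [n / 4, n / 2, n / 4],
    )
    assert chi2.pvalue > 0.01


def test_map_expansion_increases_recombinant_fraction():
    """Ten generations of intercrossing accumulate recombinations: the
    recombinant two-locus haplotype fraction at 10 cM exceeds the F2 one
    (the design's whole point: sharper mapping resolution)."""
    def recomb_fraction(generation):
        cfg = SimulationConfig(n_chromosomes=1, markers_per_chromosome=2,
                               chromosome_length_cM=10.0,
                               pairs_per_generation=500, offspring_per_pair=2,
                               final_generation=generation, seed=2)
        _, _, haps = simulate_ail(cfg, return_haplotypes=True)
        _, by_chrom = haps[generation]
        arr = by_chrom["1"]  # (n, 2, 2): two haplotypes x two markers
        two_locus = arr.reshape(-1, 2)  # oracle: direct haplotype count
        recombinant = two_locus[:, 0] != two_locus[:, 1]
        return int(recombinant.sum()), len(recombinant)

    r2, n2 = recomb_fraction(2)
    r10, n10 = recomb_fraction(10)
    assert n2 >= 2000 and n10 >= 2000
    res = stats.fisher_exact([[r10, n10 - r10], [r2, n2 - r2]],
                             alternative="greater")
    assert res.pvalue < 0.01


def test_allele_frequency_drifts_around_half():
    """No selection: mean line-1 allele frequency over markers stays near
    0.5 in the final generation."""
    cfg = SimulationConfig(n_chromosomes=2, markers_per_chromosome=30,
                           pairs_per_generation=250, final_generation=5, seed=3)
    gm, _ = simulate_ail(cfg)
    freq = gm.calls.mean(axis=0) / 2.0  # no missing calls injected
    assert abs(freq.mean() - 0.5) < 0.02


def test_pedigree_generation_consistent_no_self_mating():
    cfg = SimulationConfig(n_chromosomes=1, markers_per_chromosome=5,
                           pairs_per_generation=15, final_generation=4, seed=4)
    _, ped = simulate_ail(cfg)
    by_id = ped.set_index("id")
    for _, row in ped[ped.generation > 0].iterrows():
        assert row.sire != row.dam
        assert by_id.loc[row.sire, "generation"] == row.generation - 1
        assert by_id.loc[row.dam, "generation"] == row.generation - 1
        assert by_id.loc[row.sire, "sex"] == "M"
        assert by_id.loc[row.dam, "sex"] == "F"
    founders = ped[ped.generation == 0]
    assert founders.sire.isna().all() and founders.dam.isna().all()


def test_too_small_population_raises_on_sib_mating():
    cfg = SimulationConfig(n_chromosomes=1, markers_per_chromosome=3,
                           pairs_per_generation=1, offspring_per_pair=4,
                           final_generation=3, seed=5)
    with pytest.raises(ValueError, match="pairs_per_generation"):
        simulate_ail(cfg)


def test_same_seed_byte_identical_outputs(tmp_path):
    import ailqtl.io as aio
    cfg = SimulationConfig(n_chromosomes=2, markers_per_chromosome=10,
                           pairs_per_generation=12, final_generation=3,
                           seed=6, missing_rate=0.05,
                           qtl_specs=[QTLSpec("1", 20.0, 1.0, 0.0, "bw")])
    files = []
    for run in range(2):
        gm, ped = simulate_ail(cfg)
        pheno = simulate_phenotypes(gm, ped, cfg)
        g, p = tmp_path / f"g{run}.csv", tmp_path / f"p{run}.csv"
        aio.write_genotypes(gm, g)
        aio.write_phenotypes(pheno, p)
        files.append((g.read_bytes(), p.read_bytes()))
    assert files[0] == files[1]


def _f2_with_trait(a, d, n=1000, seed=7, residual_sd=0.5):
    cfg = SimulationConfig(n_chromosomes=1, markers_per_chromosome=3,
                           pairs_per_generation=50, n_f2=n,
                           final_generation=2, seed=seed,
                           residual_sd=residual_sd,
                           qtl_specs=[QTLSpec("1", 40.0, a, d, "bw")])
    gm, ped = simulate_ail(cfg)
    pheno = simulate_phenotypes(gm, ped, cfg)
    calls = gm.calls[:, 1]  # middle marker sits at the QTL position
    y = pheno.data.bw.to_numpy()
    return {g: y[calls == g] for g in (HOM_LINE1, HET, HOM_LINE2)}


def test_null_trait_is_standard_normal():
    cfg = SimulationConfig(n_chromosomes=1, markers_per_chromosome=3,
                           pairs_per_generation=50, n_f2=1000,
                           final_generation=2, seed=8, residual_sd=1.0)
    gm, ped = simulate_ail(cfg)
    y = simulate_phenotypes(gm, ped, cfg).data.trait.to_numpy()
    assert abs(y.mean()) < 3 / np.sqrt(len(y))
    assert 0.8 < y.std() < 1.2


def test_complete_dominance_class_pattern():
    """a > 0, d = a: heterozygotes indistinguishable from line-1
    homozygotes, both above line-2 homozygotes."""
    groups = _f2_with_trait(a=1.0, d=1.0)
    t_het_hom1 = stats.ttest_ind(groups[HET], groups[HOM_LINE1])
    assert t_het_hom1.pvalue > 0.01
    assert stats.ttest_ind(groups[HET], groups[HOM_LINE2]).pvalue < 1e-10
    assert groups[HET].mean() > groups[HOM_LINE2].mean()
    assert groups[HOM_LINE1].mean() > groups[HOM_LINE2].mean()


def test_overdominance_heterozygote_highest():
    """a = 0, d > 0: the heterozygote class mean exceeds both homozygote
    means (the pattern of the body-weight locus unmasked by MQM)."""
    groups = _f2_with_trait(a=0.0, d=1.0)
    assert groups[HET].mean() > groups[HOM_LINE1].mean()
    assert groups[HET].mean() > groups[HOM_LINE2].mean()
    assert stats.ttest_ind(groups[HET], groups[HOM_LINE2]).pvalue < 1e-6


def test_covariate_effects_enter_the_trait():
    cfg = SimulationConfig(n_chromosomes=1, markers_per_chromosome=3,
                           pairs_per_generation=50, n_f2=800,
                           final_generation=2, seed=9, residual_sd=0.5,
                           covariate_effects=CovariateEffects(sex_effect=2.0))
    gm, ped = simulate_ail(cfg)
    data = simulate_phenotypes(gm, ped, cfg).data
    male = data[data.sex == "M"].trait.mean()
    female = data[data.sex == "F"].trait.mean()
    assert male - female == pytest.approx(2.0, abs=0.3)


def test_qtl_chromosome_must_exist():
    cfg = SimulationConfig(n_chromosomes=1, markers_per_chromosome=3,
                           pairs_per_generation=10, final_generation=2, seed=10,
                           qtl_specs=[QTLSpec("9", 10.0, 1.0, 0.0, "bw")])
    gm, ped = simulate_ail(cfg)
    with pytest.raises(ValueError, match="absent from map"):
        simulate_phenotypes(gm, ped, cfg)


def test_expression_round_trip_recovers_log2(tmp_path):
    cfg = SimulationConfig(seed=11, n_genes=40, de_specs=[("g0003", 1.5)])
    mat, truth = simulate_expression(cfg)
    assert not mat.log2_transformed  # exported on the raw 2**x scale
    assert truth.is_de.sum() == 1
    e, g = tmp_path / "e.tsv", tmp_path / "g.tsv"
    write_expression(mat, e, g)
    back = read_expression(e, g)
    np.testing.assert_allclose(np.log2(back.values.to_numpy()),
                               np.log2(mat.values.to_numpy()), rtol=1e-12)


def test_expression_needs_two_samples_per_group():
    with pytest.raises(ValueError, match="2 samples"):
        simulate_expression(SimulationConfig(seed=12, n_samples_per_group=(1, 5)))
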