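"""Association scan: F-test oracle equivalence, genomic control, simpleM,
thresholds, LOD-drop regions and MQM contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.linalg import hadamard

from ailqtl import (GenotypeMatrix, PhenotypeTable, make_marker_map,
                    lambda_correct, simpleM_effective_tests, lod_thresholds,
                    display_lod, lod_drop_region, scan, mqm_scan)
from ailqtl.io import HOM_LINE1, HET, HOM_LINE2, MISSING
from ailqtl.scan import ScanResult

from oracles import anova_f_test


def _geno(calls, chroms=None, cm=None):
    calls = np.asarray(calls, dtype=np.int8)
    m = calls.shape[1]
    mm = make_marker_map([f"m{j}" for j in range(m)],
                         chroms or ["1"] * m,
                         [1000 * (j + 1) for j in range(m)], cm)
    return GenotypeMatrix([f"i{k}" for k in range(calls.shape[0])], mm, calls)


def _pheno(gm, y, sex=None):
    n = gm.n_individuals
    return PhenotypeTable(pd.DataFrame({
        "individual_id": gm.individuals,
        "sex": sex if sex is not None else ["M"] * n,
        "subfamily": ["a"] * n, "litter_size": [3] * n, "y": y}))


# ---------------------------------------------------------------------------
# Oracle equivalence of the per-marker F-test
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("with_covariate", [False, True])
def test_scan_matches_first_principles_anova(with_covariate):
    """10 markers, 30 individuals: scan F-test p-values agree with an
    independent Gram-Schmidt sum-of-squares implementation to 1e-10."""
    rng = np.random.default_rng(11)
    calls = rng.choice([HOM_LINE1, HET, HOM_LINE2], (30, 10))
    gm = _geno(calls)
    sex = rng.choice(["M", "F"], 30)
    y = rng.normal(0, 1, 30) + 0.8 * (calls[:, 3] == HOM_LINE1)
    pheno = _pheno(gm, y, sex)
    covs = ["sex"] if with_covariate else []
    res = scan("y", gm, pheno, covs, meff=10)
    for j in range(10):
        Z = (sex == "M").astype(float).reshape(-1, 1) if with_covariate else None
        _, p_oracle = anova_f_test(y, calls[:, j], Z)
        assert res.table.p_raw.iloc[j] == pytest.approx(p_oracle, abs=1e-10)


def test_scan_matches_statsmodels_anova():
    """Cross-check against the standard OLS/anova machinery as a second,
    library-based route."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    rng = np.random.default_rng(12)
    calls = rng.choice([HOM_LINE1, HET, HOM_LINE2], (40, 4))
    gm = _geno(calls)
    y = rng.normal(0, 1, 40)
    res = scan("y", gm, _pheno(gm, y), [], meff=4)
    for j in range(4):
        df = pd.DataFrame({"y": y, "g": calls[:, j].astype(str)})
        fit = smf.ols("y ~ C(g)", df).fit()
        p_sm = sm.stats.anova_lm(fit, typ=2).loc["C(g)", "PR(>F)"]
        assert res.table.p_raw.iloc[j] == pytest.approx(p_sm, rel=1e-8)


def test_trait_equal_to_covariate_gives_zero_lod():
    """If the trait is an exact function of an included covariate there is
    no residual genotype signal: LOD ~ 0 everywhere."""
    rng = np.random.default_rng(13)
    calls = rng.choice([HOM_LINE1, HET, HOM_LINE2], (60, 5))
    gm = _geno(calls)
    sex = rng.choice(["M", "F"], 60)
    y = 5.0 + 2.0 * (sex == "M")
    res = scan("y", gm, _pheno(gm, y, sex), ["sex"], meff=5)
    assert np.nanmax(res.table.lod_raw) < 1e-8


# ---------------------------------------------------------------------------
# Genomic control
# ---------------------------------------------------------------------------


def test_lambda_near_one_under_uniform_null():
    rng = np.random.default_rng(14)
    lam, _ = lambda_correct(rng.uniform(size=10_000))
    assert lam == pytest.approx(1.0, abs=0.03)


def test_lambda_two_from_constructed_quantile_median():
    """1-df quantiles with median 0.9098728 give lambda = 2.000 and a
    median corrected p of 0.5 (inverting the chi-square CDF)."""
    q = np.array([0.2, 0.9098728, 3.0])
    p = stats.chi2.sf(q, 1)
    lam, corrected = lambda_correct(p)
    assert lam == pytest.approx(2.0, rel=1e-6)
    assert np.median(corrected) == pytest.approx(0.5, rel=1e-6)


def test_lambda_below_trigger_leaves_p_unchanged():
    q = np.array([stats.chi2.ppf(0.5, 1) * 1.04])  # lambda exactly 1.04
    p = stats.chi2.sf(q, 1)
    lam, corrected = lambda_correct(p, trigger=1.05)
    assert lam == pytest.approx(1.04, rel=1e-9)
    np.testing.assert_array_equal(corrected, p)


def test_lambda_correction_shrinks_lod_when_applied():
    rng = np.random.default_rng(15)
    p = rng.uniform(1e-8, 1, 500) ** 2  # inflated small p-values
    lam, corrected = lambda_correct(p)
    assert lam > 1.05
    assert (corrected >= p - 1e-15).all()  # corrected LOD <= raw LOD


def test_lambda_empty_input_is_an_error():
    with pytest.raises(ValueError):
        lambda_correct([])


# ---------------------------------------------------------------------------
# simpleM
# ---------------------------------------------------------------------------


def test_simplem_duplicated_marker_counts_once():
    rng = np.random.default_rng(16)
    col = rng.choice([0, 1, 2], 40)
    gm = _geno(np.stack([col, col], axis=1))
    assert simpleM_effective_tests(gm) == 1


def test_simplem_perfect_ld_blocks_count_block_number():
    """3 mutually-orthogonal blocks duplicated twice each -> Meff = 3."""
    c1 = np.array([0, 0, 2, 2], dtype=np.int8)
    c2 = np.array([0, 2, 0, 2], dtype=np.int8)
    c3 = np.array([0, 2, 2, 0], dtype=np.int8)
    gm = _geno(np.stack([c1, c1, c2, c2, c3, c3], axis=1))
    assert simpleM_effective_tests(gm) == 3


def test_simplem_orthogonal_markers_keep_fraction():
    """M exactly-uncorrelated markers: all eigenvalues equal, so
    Meff = ceil(0.995 * M)."""
    H = hadamard(256)[:, 1:]  # drop the constant column
    calls = ((H + 1)).astype(np.int8)  # -1/1 -> 0/2
    gm = _geno(calls)
    M = 255
    assert simpleM_effective_tests(gm) == int(np.ceil(0.995 * M))
    assert simpleM_effective_tests(gm, variance_fraction=1.0) == M


def test_simplem_sums_over_chromosomes():
    rng = np.random.default_rng(17)
    col = rng.choice([0, 1, 2], 50)
    other = rng.choice([0, 1, 2], 50)
    gm = _geno(np.stack([col, col, other, other], axis=1),
               chroms=["1", "1", "2", "2"])
    assert simpleM_effective_tests(gm) == 2


def test_simplem_zero_variance_marker_is_internal_error():
    gm = _geno(np.stack([np.ones(20), np.arange(20) % 3], axis=1))
    with pytest.raises(RuntimeError, match="QC"):
        simpleM_effective_tests(gm)


def test_simplem_never_exceeds_marker_count():
    rng = np.random.default_rng(18)
    gm = _geno(rng.choice([0, 1, 2], (30, 12)))
    assert simpleM_effective_tests(gm) <= 12


# ---------------------------------------------------------------------------
# Thresholds
# ---------------------------------------------------------------------------


def test_lod_thresholds_display():
    sig, high = lod_thresholds(1365, 0.05, 0.01)
    assert display_lod(sig) == "4.4"
    assert display_lod(high) == "5.1"
    sig1, _ = lod_thresholds(1, 0.05, 0.01)
    assert display_lod(sig1) == "1.3"


# ---------------------------------------------------------------------------
# LOD-drop regions
# ---------------------------------------------------------------------------


def _scan_from_lods(lods, bps, chrom="1"):
    table = pd.DataFrame({
        "marker_id": [f"m{j}" for j in range(len(lods))],
        "chromosome": [chrom] * len(lods),
        "position_bp": bps,
        "lod_corrected": lods,
        "partial_r2": [5.0] * len(lods),
        "mean_HOM_LINE1": np.nan, "mean_HET": np.nan, "mean_HOM_LINE2": np.nan,
    })
    return ScanResult("y", table, 1.0, False, 4.4, 5.1, 100)


def test_lod_drop_hand_example():
    r = lod_drop_region(_scan_from_lods([1.0, 2.0, 5.0, 3.6, 3.4, 2.0],
                                        [10, 20, 30, 40, 50, 60]), "1", 1.5)
    assert (r.start_bp, r.top_bp, r.stop_bp) == (20, 30, 50)


def test_lod_drop_top_at_chromosome_start():
    r = lod_drop_region(_scan_from_lods([5.0, 3.0, 1.0], [10, 20, 30]), "1", 1.5)
    assert r.start_bp == r.top_bp == 10
    assert r.stop_bp == 20


def test_lod_drop_no_flanking_drop_extends_to_ends():
    r = lod_drop_region(_scan_from_lods([4.5, 5.0, 4.6], [10, 20, 30]), "1", 1.5)
    assert (r.start_bp, r.stop_bp) == (10, 30)


def test_lod_drop_tie_picks_smaller_bp():
    r = lod_drop_region(_scan_from_lods([1.0, 5.0, 5.0, 1.0],
                                        [10, 20, 30, 40]), "1", 1.5)
    assert r.top_bp == 20


def test_region_below_threshold_not_called():
    assert lod_drop_region(_scan_from_lods([1.0, 2.0, 1.0], [10, 20, 30]),
                           "1", 1.5, threshold=4.4) is None


@given(st.lists(st.floats(0, 10), min_size=2, max_size=15),
       st.floats(0.1, 3.0), st.floats(0.1, 3.0))
@settings(max_examples=80, deadline=None, derandomize=True)
def test_widening_lod_drop_never_shrinks_region(lods, d1, d2):
    bps = [10 * (j + 1) for j in range(len(lods))]
    res = _scan_from_lods(lods, bps)
    lo, hi = min(d1, d2), max(d1, d2)
    r_small = lod_drop_region(res, "1", lo)
    r_big = lod_drop_region(res, "1", hi)
    assert r_big.start_bp <= r_small.start_bp
    assert r_big.stop_bp >= r_small.stop_bp
    assert r_small.start_bp <= r_small.top_bp <= r_small.stop_bp


# ---------------------------------------------------------------------------
# Scan output contracts and MQM
# ---------------------------------------------------------------------------


def test_scan_invariants_on_simulated_data():
    rng = np.random.default_rng(19)
    n, m = 120, 30
    calls = rng.choice([HOM_LINE1, HET, HOM_LINE2], (n, m))
    calls[rng.random((n, m)) < 0.05] = MISSING
    gm = _geno(calls)
    y = rng.normal(0, 1, n) + (calls[:, 7] == HOM_LINE1)
    res = scan("y", gm, _pheno(gm, y), [], meff=m)
    t = res.table
    ok = t.p_raw.notna()
    np.testing.assert_allclose(t.lod_raw[ok], -np.log10(t.p_raw[ok]))
    np.testing.assert_allclose(t.lod_corrected[ok], -np.log10(t.p_corrected[ok]))
    assert ((t.partial_r2[ok] >= 0) & (t.partial_r2[ok] <= 100)).all()
    assert res.lambda_applied == (res.lambda_ > 1.05)
    if res.lambda_applied:
        assert (t.lod_corrected[ok] <= t.lod_raw[ok] + 1e-12).all()
    # class counts at each marker sum to the individuals carrying calls
    counted = t.n_HOM_LINE1 + t.n_HET + t.n_HOM_LINE2
    assert (counted <= n).all()


def test_marker_with_single_class_gets_na_record():
    calls = np.stack([np.full(30, HET), np.arange(30) % 3], axis=1).astype(np.int8)
    gm = _geno(calls)
    rng = np.random.default_rng(20)
    res = scan("y", gm, _pheno(gm, rng.normal(size=30)), [], meff=1)
    assert np.isnan(res.table.p_raw.iloc[0])
    assert np.isfinite(res.table.p_raw.iloc[1])


def test_mqm_cofactor_itself_and_perfect_ld_markers_are_na():
    rng = np.random.default_rng(21)
    col = rng.choice([HOM_LINE1, HET, HOM_LINE2], 60)
    other = rng.choice([HOM_LINE1, HET, HOM_LINE2], 60)
    # m0 = cofactor, m1 identical, m2 relabelled bijection (perfect LD), m3 free
    relabel = {HOM_LINE1: HOM_LINE2, HET: HET, HOM_LINE2: HOM_LINE1}
    m2 = np.vectorize(relabel.get)(col)
    gm = _geno(np.stack([col, col, m2, other], axis=1))
    y = rng.normal(0, 1, 60)
    res = mqm_scan("y", gm, _pheno(gm, y), [], "m0", meff=4)
    assert res.cofactors == ["m0"]
    assert np.isnan(res.table.p_raw.iloc[0])
    assert np.isnan(res.table.p_raw.iloc[1])
    assert np.isnan(res.table.p_raw.iloc[2])
    assert np.isfinite(res.table.p_raw.iloc[3])


def test_mqm_with_null_cofactor_matches_single_scan():
    """A cofactor with no effect only costs degrees of freedom: at large n
    the per-marker LODs agree with the plain scan."""
    rng = np.random.default_rng(22)
    n = 2000
    calls = rng.choice([HOM_LINE1, HET, HOM_LINE2], (n, 6))
    gm = _geno(calls)
    y = rng.normal(0, 1, n) + 0.5 * (calls[:, 2] == HOM_LINE1)
    pheno = _pheno(gm, y)
    single = scan("y", gm, pheno, [], meff=6)
    cofac = mqm_scan("y", gm, pheno, [], "m5", meff=6)
    keep = cofac.table.p_raw.notna() & (cofac.table.marker_id != "m5")
    np.testing.assert_allclose(cofac.table.lod_raw[keep],
                               single.table.lod_raw[keep], atol=0.35)


def test_mqm_unknown_cofactor_is_configuration_error():
    rng = np.random.default_rng(23)
    gm = _geno(rng.choice([0, 1, 2], (20, 3)))
    with pytest.raises(ValueError, match="not in matrix"):
        mqm_scan("y", gm, _pheno(gm, np.zeros(20)), [], "nope")
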