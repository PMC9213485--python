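# ailqtl

QTL mapping and candidate-gene prioritization for mouse advanced
intercross lines (AIL), built around the analysis design used for obesity
and fatty-liver crosses between a Berlin Fat Mouse inbred line and
C57BL/6N: a few hundred genotyped generation-10 animals, array genotypes
with three-class calls, covariate-adjusted single-marker scans, and a
variant-consequence decision tree that ranks the genes inside each QTL
support interval.

The package is aimed at quantitative geneticists who want the complete
chain — marker QC, scans, thresholds, support intervals, cofactor
rescans, expression contrast, gene scoring — as tested, scriptable Python,
plus a forward simulator that generates AIL data with the statistical
structure the analysis assumes, so every stage can be verified without
access to animal data.

## The method

For each trait *y* and marker with genotype classes *g* ∈ {S1/S1, S1/B6,
B6/B6} the scan fits the fixed-effects linear model

    y = covariates + genotype class + e

where the covariates (sex, subfamily = dam, litter size) are included per
trait when a marginal screen finds them significant (p < 0.05).  The
marker p-value is the F-test of the genotype factor against the
covariates-only null, and LOD = −log10(p).

Population structure is handled by genomic control: p-values are mapped to
1-df χ² quantiles, the inflation factor λ = median(q)/0.4549 is computed
per scan, and when λ > 1.05 the quantiles are deflated by λ before mapping
back.  Significance thresholds are Bonferroni over the effective number of
independent markers M_eff, estimated per chromosome from the eigenvalues
of the marker–marker correlation matrix (smallest k capturing 99.5 % of
the eigenvalue total, summed over chromosomes); with M_eff = 1365 the
thresholds display as LOD 4.4 (5 %) and 5.1 (1 %).  QTL support intervals
run to the first flanking markers whose LOD falls 1.5 below the top
marker.  A multiple-QTL (MQM) rescan adds a known locus' top marker as a
model cofactor to expose masked QTL.

Candidate genes inside an interval are scored additively per category:
stop gain/loss 3, missense in a functional protein domain 3, SIFT
deleterious 3 / tolerated 1, promoter or splice-site variant 3,
UTR / enhancer / CTCF-site variant 1, liver differential expression
(BH-adjusted t-test, p < 0.05) 2, KEGG pathway membership 1 — each
category at most once per gene, maximum 21.

## Worked example

```python
import ailqtl as a

cfg = a.SimulationConfig(
    n_chromosomes=5, markers_per_chromosome=100,
    pairs_per_generation=62, offspring_per_pair=2, final_generation=10,
    seed=11, residual_sd=1.0, trait_intercept=33.0,
    covariate_effects=a.CovariateEffects(sex_effect=1.0, subfamily_sd=0.3),
    qtl_specs=[a.QTLSpec("3", 40.0, 1.0, 0.3, "body_weight")],
)
gm, ped = a.simulate_ail(cfg)                 # ~124 generation-10 animals
pheno = a.simulate_phenotypes(gm, ped, cfg)
gq, report = a.apply_marker_qc(gm, group_min=10)
sel = a.screen_covariates(pheno)
res = a.scan("body_weight", gq, pheno, sel)
for r in a.call_regions(res):
    print(r.chromosome, r.start_bp, r.stop_bp, r.top_marker, r.top_lod)
```

With this configuration the run prints (numbers produced by the code):

```
markers in/out: 500 500  masked calls: 9
selected covariates: ['sex']  (sex p = 8.8e-4)
lambda = 1.697 (applied), Meff = 282, LOD thresholds 3.8 / 4.5
chr3: 75,959,597-80,808,082  top m3_0050 @ 79,191,920  LOD 7.12 (32.8% var)
class means: S1/S1 34.33, S1/B6 33.58, B6/B6 32.06
S1/S1 vs B6/B6: 7% (2.27 g)
```

Reading this: QC kept all 500 simulated markers and only masked 9 calls in
under-sized genotype groups; sex was the only covariate passing the
screen; the scan's inflation factor exceeded the 1.05 trigger, so the
reported LODs are λ-corrected; 282 effective tests set the significance
thresholds; and the planted chromosome-3 locus (additive effect 1 residual
SD at 40 cM) is recovered as a 1.5-LOD-drop interval around 79.2 Mb —
the true position under the simulator's 0.5 cM/Mb map is 80 Mb — with
covariate-adjusted class means showing the expected S1-allele dosage
pattern.

The same chain is available from the shell:

```bash
ailqtl simulate --out-dir data --seed 11
ailqtl qc --genotypes data/genotypes.csv --map data/markers.csv \
          --out-genotypes data/qc.csv --out-report data/qc.json
ailqtl scan --genotypes data/qc.csv --phenotypes data/phenotypes.csv \
            --trait bw --out-prefix out/bw
ailqtl report --scan-tsv out/bw.scan.tsv --chromosome 1
```

(`mqm`, `correlate`, `de` and `score` cover the cofactor scan, the trait
correlation matrix, differential expression and gene ranking.)

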