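# Methods

## Data model

Genotypes are stored as the dosage of the line-1 (BFMI-like founder)
allele: 2/1/0 with −1 for missing, alongside a marker map (chromosome
"1"–"19"/"X", 1-based bp, optional cM).  All in-memory coordinates are
1-based inclusive; BED output is 0-based half-open and converts back
losslessly.  Chromosome labels are plain strings and the X is carried
through QC and scans like an autosome — no dosage compensation or
X-specific inheritance is modelled anywhere in the package.  Missing trait
values are NaN and are removed listwise per model fit, never imputed.

## Marker quality control

Three rules in a fixed order: (1) drop markers with all calls missing,
(2) drop non-segregating markers (exactly one observed class — a marker
with only heterozygous calls is removed under this rule), (3) require at
least two genotype classes with `group_min` (default 10) observations;
markers failing that are dropped, and on surviving markers any class with
1..`group_min`−1 observations is masked to missing.  The rule order only
affects how removals are attributed in the report, not the surviving set.
Masking is symmetric — an under-sized heterozygote class is masked exactly
like an under-sized homozygote class.  The procedure is idempotent, and
masking can only set calls to missing, never flip them.

## Covariate screening and adjusted means

Covariates are screened marginally, one model per covariate per trait
(one-way F-test for sex and subfamily, slope t-test for litter size),
selected at p < `alpha_covariate` = 0.05.  Marginal rather than joint
screening mirrors the per-covariate p-value layout such studies report; it
also means a covariate can be selected through its correlation with
another.  Subfamily (the dam) doubles as the kinship correction: a fixed
factor, not a genomic relationship matrix, which is adequate for a
population whose structure is dominated by maternal families.

Genotype-class means are least-squares means: one indicator column per
observed class plus the covariate columns, with the covariate contribution
evaluated at its sample mean, so classes are compared at identical
covariate values.  With no covariates this reduces exactly to the raw
class means.

## Single-marker scan

The genotype enters as a categorical factor (2 df with three observed
classes, 1 df with two).  An additive dosage coding would be more powerful
for strictly additive loci but blind to overdominance — and the secondary
body-weight locus this design is meant to detect is exactly the
heterozygote-highest case — so the factor coding is the default and only
coding.  The marker p-value is the partial F-test against the
covariates-only null refit on the same individuals (listwise deletion per
marker).  Degrees of freedom come from numerical ranks of the design
matrices, so a marker collinear with the covariates or the MQM cofactor
(including perfect-LD relabelings) cleanly yields an NA record rather
than a spurious test.  Variance explained is reported as
(SSE_null − SSE_full)/SST × 100 on the analyzed individuals.

## Genomic control

λ is computed per trait scan from 1-df χ² quantiles of the raw p-values
(λ = median(q)/0.4549364); correction divides the quantiles by λ when
λ > 1.05 and is reported either way.  The 1-df convention is standard for
genomic control and is kept regardless of the F-test's df; a `lambda_df`
option switches to the test df.  Two caveats are inherent to the method:
with only a few hundred markers λ is itself noisy, and widespread true
signal inflates the median, making the correction conservative (visible in
the README example, where a single strong QTL on one of five chromosomes
pushes λ to 1.7).

## Multiple testing

The effective number of tests uses the eigenvalue method on the
marker–marker correlation matrix (0/1/2 dosages, pairwise-complete,
negative eigenvalues clipped): M_eff is the smallest k whose leading
eigenvalues reach `variance_fraction` = 0.995 of the eigenvalue total,
computed per chromosome and summed, since LD — the redundancy the method
measures — only spans linked markers.  A genome-wide variant is available
by flag.  Thresholds are −log10(α/M_eff) at α = 0.05 and 0.01, compared
unrounded and displayed to one decimal.

## Support intervals and MQM

The support interval runs from the first marker upstream of the top marker
(ties broken toward the smaller bp) whose corrected LOD is at least
`lod_drop` = 1.5 below the top LOD, to the symmetric marker downstream,
capped at the chromosome ends.  Widening the drop can only widen the
interval.  The MQM scan re-runs the genome with the cofactor marker's
genotype as an extra categorical covariate; the cofactor itself and
markers carrying no additional genotype df are emitted as NA, and λ is
recomputed on the new p-value list.

## Differential expression

Raw intensities are log2-transformed, then quantile-normalized with all
samples of both groups pooled (normalizing the groups separately would
leave a between-group location artifact).  Ties receive the mean of the
quantile means their ranks span.  Each gene gets a two-tailed two-sample
t-test — equal-variance Student by default, since nothing in a 6-vs-5
array design justifies estimating separate variances per group; Welch by
flag — and Benjamini–Hochberg adjustment across all genes.  Fold change is
reported on the log2 scale as mean(line 1) − mean(line 2): the magnitudes
printed for such arrays (±0.03..0.19) are log2 differences, not linear
ratios; a linear-ratio column is available by flag.  Zero-variance genes
with equal means get p = 1 by convention.

## Gene prioritization

Category-once semantics: each scoring component (stop codon 3, domain
missense 3, SIFT deleterious 3/tolerated 1, promoter 3, splice 3, UTR 1,
enhancer 1, CTCF 1, liver DE 2, KEGG 1) takes its full value if any
variant of the gene triggers it, and the domain and SIFT components of one
missense variant add — the reading that reproduces the published worked
totals without further assumptions.  Deleterious dominates tolerated
rather than summing.  A per-variant additive mode exists behind a flag for
sensitivity analysis (its totals are unbounded).  KEGG membership is a
user-supplied gene set — the package makes no database calls.  Restricting
candidates to QTL intervals is a midpoint-in-interval filter, not a
transcript-model intersection.

## The simulator

The generator produces data with the structure the analysis assumes, under
the study's design: two fully inbred founders homozygous for opposite
alleles everywhere, an F1, then random monogamous non-full-sib pairing
within each generation to generation 10.  All F1 animals are full sibs of
the single founder couple and genetically identical heterozygotes, so the
sib exclusion is enforced from generation 2 onward (it is vacuous at F1).
Sexes are Bernoulli(0.5); the next generation's offspring are distributed
round-robin over the formed pairs, so sex-ratio fluctuations shrink
litters rather than the population.  Litter size is the dam's realized
offspring count and subfamily is the dam — giving covariates with the same
degeneracies real data has.

Meiosis is Haldane (no interference): crossover counts Poisson with mean
L/100 per chromosome, positions uniform on the genetic map, marker cM
interpolated from bp at 0.5 cM/Mb (the mouse genome-average scale) when no
map is supplied.  Defaults are 5 chromosomes × 100 markers over 80 cM and
62 pairs × 2 offspring per generation (~124 animals, matching the
genotyped population's order of magnitude); family sizes per generation
are not published, so these are the package's choice and fully
configurable.

Traits are intercept + sex effect + per-dam Normal(0, σ_subfamily²) shift
+ litter-size slope + Σ QTL effects (−a, d, +a at the marker nearest the
QTL position) + Normal(0, σ_residual²).  Expression is per-gene baseline
log2 intensity Normal(8, 2²) with planted log2 shifts in group 1 and
i.i.d. noise (default SD 0.25), exported on the raw 2^x scale with a
6-vs-5 group design.  Annotations draw each scoring category independently
per gene and return, alongside the table, a truth score computed by direct
enumeration of the drawn flags — an independent path against which the
scoring module is closed-loop tested.

One global seed feeds fixed purpose-keyed substreams (pedigree, meiosis,
missingness, phenotypes, expression, annotations), so runs are
byte-identical given the seed and, e.g., adding markers does not perturb
the pedigree.

What the simulator does not emulate: selection, mutation, genotyping error
beyond uniform missingness, X-specific inheritance, crossover
interference, non-Gaussian trait residuals, and probe-level array
artifacts.  Passing tests therefore demonstrate the statistical machinery
is correct under the stated generative model, not that real data meet
that model.

## Verification set-up and problem sizes

The acceptance-style tests run the stages under the study's scale as the
package's own verification conditions: 100 null scans of ~124 generation-10
animals at 500 markers on 5 chromosomes for family-wise error; 100
replicates at n = 400 with a planted 1-SD QTL for position recovery
(within 5 cM in ≥ 90 %); 100 two-QTL replicates (a = 1.5 and 0.5 SD) for
the MQM unmasking rate (≥ 80 %); 200 replicates of the 500-gene, 6-vs-5
null expression design for FDR control; and exact-arithmetic oracles
(Gram-Schmidt sum-of-squares ANOVA, literal BH step-up, hand-computable
eigenstructures for the effective-test count) for numerical equivalence
at 1e-10.

## Numerical choices

p-values are floored at 1e-300 so LODs stay finite; partial R² is clipped
to [0, 100]; ties for the top marker resolve to the smaller bp; simpleM's
threshold comparison uses a 1e-12 slack so exact-equality eigenvalue cases
(k/M = fraction) land on the mathematically intended k.  Least-squares
fits use `numpy.linalg.lstsq` with rank from the same SVD; the test suite
pins the results to an independent Gram–Schmidt implementation and to
statsmodels' ANOVA.

## Known limitations

No interval mapping between markers (single-marker tests only), no
mixed-model kinship correction, no permutation thresholds, no
sex-stratified scans, no probe summarization or batch correction for
expression, and the real study's per-animal phenotypes are not public —
its genome-scan LOD values are therefore out of reach by construction,
and verification rests on the printed self-contained quantities plus
simulation.
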