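# Methods

`xcrossqtl` implements the comparative-cross strategy for nominating
candidate genes under an obesity QTL that is shared by two mouse backcross
populations: genome scans with permutation thresholds in each cross,
positional matching of the resulting QTL, haplotype-window classification of
the shared interval from multi-strain SNPs, a strain-differential expression
screen in the QTL target tissue, cis-eQTL confirmation, and the intersection
of the evidence streams. A synthetic-data generator reproduces the
statistical structure of such a study so that every stage runs, and is
tested, without external data.

## Genetic model and genotype probabilities

The populations are N2 backcrosses: F1 males crossed back to the recurrent
(obese, NZO-like) strain. Each individual carries one recombinant F1 gamete,
so every locus has two genotype classes — `A` (homozygous recurrent parent)
and `H` (heterozygous) — segregating 1:1. Along a chromosome the true
genotype sequence is a two-state Markov chain; transition probabilities are
recombination fractions from the **Haldane map function**
`r = (1 − e^(−2d/100))/2` (no crossover interference). Conditional genotype
probabilities at markers and at pseudomarkers inserted every `step_cm`
(default 1 cM) are computed exactly per chromosome by the scaled
forward–backward algorithm. Observed marker genotypes are treated as noisy
emissions with a symmetric genotyping-error rate `error_prob` (default
1e-4, the conventional order for SNP-assay genotyping); missing genotypes
are uninformative emissions. An X chromosome, if present, is treated as
autosomal and noted in the log. The implementation is verified against
exhaustive enumeration over all `2^m` true-genotype sequences on small
chromosomes (agreement < 1e-10).

## Genome scans

**EM interval mapping.** At each evaluation position the trait is modelled
as a two-component normal mixture with known mixing weights `p_ig` (the
conditional genotype probabilities), class means `μ_A, μ_H` and a common
residual SD. The mixture is fitted by EM — E-step
`w_ig ∝ p_ig·φ(y_i; μ_g, σ)`, M-step weighted class means and pooled
variance — initialised from the single-pass regression of the trait on
P(H), iterated to `|Δ log-lik| < 1e-6` (cap 1000 iterations). LOD is
`log10` of the fitted mixture likelihood over the single-normal null
likelihood, clipped at zero. The log-likelihood is asserted nondecreasing
across iterations. At a fully informative marker the statistic collapses to
the two-group regression LOD `(n/2)·log10(RSS0/RSS1)`, which the tests use
as an independent oracle; LOD curves are invariant under affine trait
transformations.

**Nonparametric scan.** For expression traits the scan statistic is the
rank-based extension of the Kruskal–Wallis statistic to probabilistic
genotype weights: with mid-ranks `R_i` and the usual tie correction,
`H = [12/(n(n+1))]·Σ_g (Σ_i p_ig R_i)²/(Σ_i p_ig) − 3(n+1)`, reported on
the LOD scale as `H/(2·ln 10)`. At an informative marker it equals
Kruskal–Wallis exactly, and it is invariant under strictly monotone trait
transformations — scanning ΔCt or `2^−ΔCt` gives identical curves, which
the tests assert.

**Trait preprocessing.** Normality is assessed with the D'Agostino–Pearson
omnibus K² test (requires n ≥ 20; delegated to `scipy.stats.normaltest`,
which implements exactly that statistic). Blood-glucose traits are
log2-transformed before scanning; the transform rejects nonpositive values
by individual. Longitudinal traits are scanned week by week; the reported
summary of a trait family takes the peak from the week with the highest
LOD and lists every week whose own scan clears its own threshold.

**Permutation thresholds.** The genome-wide 5% threshold per trait is the
empirical 95th percentile (linear interpolation between order statistics)
of the genome-wide maximum LOD over `n_perm` permutations of the phenotype
vector against the fixed genotypes (default 1000; the marker correlation
structure is preserved). The RNG seed is recorded. Calibration: across 200
null replicates the exceedance rate of the 5% threshold is 0.05 ± 0.02.

**Support intervals.** Default is the 95% Bayes credible interval: the
smallest contiguous interval of evaluated positions, containing the peak,
that holds ≥ 95% of the trapezoid-normalised mass of `10^LOD` on the
chromosome. A 1.5-LOD drop interval (outermost positions within 1.5 LOD of
the peak) is available by option. Ties at the peak resolve to the leftmost
position; the closest marker is chosen by |ΔcM| with ties broken toward the
smaller Mbp. A flat zero curve yields the whole chromosome with a warning.

## Cross comparison

Two QTL summaries match when they lie on the same chromosome, belong to the
same trait family, and their support intervals overlap (a zero-length
touching intersection counts; no quantitative coincidence test is applied —
positional overlap is the operational rule). Body weight, fat/lean mass and
blood glucose map to one "obesity" family by default, so a body-weight hit
in one cross can match a fat-mass hit in the other; the mapping is
configurable. A matched locus is classified as specific to the shared
recurrent strain; an unmatched locus is attributed to the lean donor strain
of its own cross. For shared loci the refined interval is the intersection
of the two support intervals, which is never longer than either input.

## Haplotype windows

The focal interval is tiled with 250-kb windows anchored at the region
start (the trailing partial window is kept and classified by the same
rule). Per window, the total variant rows and the *discordant* SNPs — focal
strain allele present and different from **both** lean strains; a missing
call never counts as discordant — are counted; 1-based SNP positions are
mapped into 0-based half-open windows. A window is polymorphic when its
discordant count **strictly exceeds** the threshold (default 100; the
boundary is tested explicitly). Genes overlapping a flagged window by at
least 1 bp (half-open interval semantics; abutting intervals do not
overlap) form the haplotype candidate set — any-overlap rather than full
containment, the more conservative inclusion rule. The nonsynonymous
shortlist keeps discordant missense rows and flags predicted-deleterious
variants (SIFT score < 0.05; SIFT scores are ingested as a column, never
computed) and focal-strain uniqueness against an optional panel of
additional lean strains.

## Expression filter, qPCR and eQTL

The strain-differential screen tests the focal strain against each lean
strain per gene with the exact two-sided Mann–Whitney rank-sum test; a gene
passes when both raw P-values are below α = 0.05 and both focal/lean mean
ratios fall on the same side of 1. The groups are unpaired (independent
animals per strain), so an unpaired rank-sum test is the defensible choice
even where a signed-rank procedure might be named for such designs; a
one-sided alternative and a Benjamini–Hochberg option exist but are off by
default — the screen is deliberately a raw per-gene filter, and no
fold-change floor is applied. qPCR quantification follows `2^−ΔΔCt`:
`ΔΔCt = (Ct_target,sample − Ct_ref,sample) − (Ct_target,calibrator −
Ct_ref,calibrator)`.

eQTL scans use the nonparametric statistic on `2^−ΔCt` expression traits
with a per-gene permutation threshold. A significant eQTL is *cis* when its
peak is on the gene's chromosome and the peak marker lies within 20 Mbp of
the gene midpoint (default chosen to span peak-marker-to-gene distances of
the order seen in backcross eQTL with ~20-Mbp marker spacing; configurable),
otherwise *trans*. The final candidate set is the intersection of the
haplotype gene set with the passing DE genes; the report carries both input
sets, Venn counts, per-candidate evidence (DE record, eQTL record, shortlist
hits) and provenance (seed, config digest).

## Synthetic data: what it emulates and what it does not

The generator reproduces the study conditions the analysis assumes: two
backcross populations of 310 and 307 females; a stylised 19-autosome genome
(160 down to 60 Mbp, 113 markers at 20-Mbp spacing, 0.5 cM/Mbp); Haldane
meiosis without interference, matching the map function used in scanning —
the simplest self-consistent choice; longitudinal body-weight (weeks 6–20,
means 30.8→60 g), fat-mass (weeks 6–15) and blood-glucose traits with
Gaussian residuals whose means, effect sizes (e.g. +3.5 g on week-20 body
weight for the homozygous class) and SDs are of the magnitude reported for
such crosses; a shared chromosome-14 QTL at 30 cM plus one cross-specific
QTL per population, effects parameterised on the homozygous class (the
direction in which the obese-strain allele raises weight and adiposity);
qPCR-style expression traits (ΔCt additive-normal, hence lognormal
expression) with one strong cis (ΔCt gap 2), one weak cis (0.7), one trans
and one null architecture; a 53–75 Mb variant table with three polymorphic
blocks (400 discordant SNPs per 250 kb vs 15 in IBD segments, ~650/500
total), 42 planted missense rows of which 3 score SIFT < 0.05 but are
shared with panel strains; and a 200-gene three-strain expression matrix
(n = 5 per strain, log2 SD 0.5) with nine focal-strain regulated genes of
which exactly two sit in polymorphic blocks — the planted candidate pair.

It does **not** emulate: crossover interference, X-dosage, epistasis,
litter or cage effects, selection, genotyping batch structure, microarray
normalisation artefacts, linkage-disequilibrium structure inside windows,
or a realistic mouse physical-to-genetic map (the synthetic map is linear
at 0.5 cM/Mbp). Passing tests therefore demonstrate the correctness and
calibration of the statistical machinery under the stated model, not
robustness to those real-data complications.

## Numerical choices

EM tolerance 1e-6 on the log-likelihood, 1000-iteration cap, variance
floored at 1e-12; genotype probabilities floored at 1e-300 inside logs;
LOD clipped at 0. Quantiles use linear interpolation between order
statistics. Degenerate phenotypes (fewer than two distinct non-missing
values) are rejected, as are rank scans on fully tied data. Positions are
rounded to 1e-9 cM when merging markers with the pseudomarker grid;
markers sharing a grid position have their emissions multiplied. Peak ties
resolve leftmost for determinism. Genome scans for permutations are
vectorised across permutation replicates in memory-bounded chunks
(~4e6 array elements), which changes nothing statistically.

## Problem sizes used in the packaged experiments

The packaged tests and the acceptance script use 100–200 permutations per
threshold, 200 replicates for null calibration (five 120-Mbp chromosomes,
n = 150, marker-only evaluation), 100 seeds for interval-coverage
estimation (one 90-Mbp chromosome, n = 300, 1-cM grid), and two scanned
trait-weeks per cross in the end-to-end run. These sizes give
Monte-Carlo errors comfortably inside the asserted tolerances while keeping
a full run at desk scale; the full-study defaults (1000 permutations, all
trait-weeks) remain the configuration defaults.

## Known limitations and out-of-scope quantities

* The published supplementary cross tables are not redistributable here, so
  the reproductions of the published LOD scores, class means and marker
  positions execute only when those files are supplied locally
  (`data/file_s1/`); without them the corresponding acceptance tests fail
  with an explanatory message rather than silently passing.
* The 431 → 83 gene haplotype count of the original study depends on a
  specific release of the full strain SNP database and its gene
  assignments; it is not reproducible from packaged data and is not
  attempted. The packaged window classifier is instead validated on planted
  block structure.
* The "seven novel obesity QTL" tally depends on the enumeration of
  trait-weeks and on stochastic permutation thresholds; it is reported by
  the pipeline for whatever inputs it is given but is not asserted.
* Human-cohort correlations (expression vs BMI/body fat in adipose tissue)
  require a clinical dataset that is not available; out of scope.
* All wet-lab quantities (e.g. the ~60% insulin-stimulated glucose uptake
  increase under overexpression, parental-strain phenotypes, Ct values of
  specific assays) are experimental observations, not outputs of this
  software, and are out of scope.
* No multiple-QTL or composite interval mapping, no covariates, no
  Kosambi/Carter–Falconer map functions, no VCF parsing (variant input is a
  TSV extract), no microarray preprocessing.
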