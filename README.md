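# xcrossqtl

Comparative two-backcross QTL mapping with haplotype-window and
expression-based candidate-gene filtering.

## The problem

Crossing an obese, diabetes-prone inbred mouse strain (e.g. NZO) to a single
lean strain finds quantitative trait loci (QTL) for body weight and fat
mass, but each locus typically spans tens of megabases and hundreds of
genes, and a single cross cannot tell whether the causal variant comes from
the obese or the lean parent. Running **two** backcrosses against different
lean strains (e.g. C3H and 129P2) adds leverage: a locus that appears in
both crosses points to a variant specific to the shared obese parent, its
interval can be refined by intersection, and the interval can be filtered
further with strain haplotypes and adipose-tissue expression.

`xcrossqtl` implements that whole strategy as a tested Python library plus a
thin CLI, for geneticists analysing N2 backcross data (or anyone who wants a
self-contained, reproducible reference implementation):

* **Genome scans** — single-QTL interval mapping by an EM-fitted normal
  mixture on exact forward–backward genotype probabilities (Haldane map,
  configurable genotyping-error rate and pseudomarker step), and a
  nonparametric rank scan for expression traits. At a fully informative
  marker these reduce to the two-group regression LOD
  `(n/2)·log10(RSS₀/RSS₁)` and to the Kruskal–Wallis statistic
  `H/(2 ln 10)`.
* **Inference** — genome-wide thresholds from phenotype permutations, 95%
  Bayes (or 1.5-LOD drop) support intervals, per-chromosome peak summaries
  with genotype-class means ± SEM.
* **Cross comparison** — positional matching of QTL between the two crosses,
  origin attribution, interval refinement by intersection.
* **Haplotype windows** — 250-kb windows over the shared interval classified
  polymorphic when more than 100 SNPs discriminate the focal strain from
  both lean strains; gene assignment by overlap; a nonsynonymous shortlist
  with SIFT-based deleteriousness and strain-uniqueness flags.
* **Expression evidence** — exact rank-sum strain-differential screen,
  `2^−ΔΔCt` quantification, nonparametric eQTL scans with cis/trans
  classification, and the final candidate intersection report.
* **Synthetic data** — generators for backcross populations, expression
  traits, strain expression matrices and block-structured variant tables,
  so the full pipeline runs and is validated offline.

See `docs/methods.md` for the model, assumptions, defaults and limitations.

## Worked example

Simulate a backcross with a planted QTL (chromosome 14, 30 cM, effect 1.5
trait units, residual SD 2), scan it, and compute a permutation threshold:

```bash
xcrossqtl simulate --n 300 --seed 7 --qtl 14:30:1.5:2 --out cross.csv
xcrossqtl scan --cross cross.csv --trait trait --method em --out scan.tsv
xcrossqtl permute --cross cross.csv --trait trait --n-perm 1000 --seed 7
```

which prints

```
wrote 300 individuals x 113 markers
peak: chr14 28.0 cM, LOD 9.51
threshold (alpha=0.05): 2.712
```

The planted locus is recovered 2 cM from its true position with a LOD far
above the genome-wide 5% threshold. The same applies through the Python
API:

```python
from xcrossqtl import RunConfig, run_pipeline

report = run_pipeline(RunConfig(seed=1, n_perm=100,
                                scan_traits=["bw_wk20", "fm_wk15"]),
                      outdir="run1")
print(report["candidates"]["intersection"])   # ['G031', 'G050']
print(report["candidates"]["venn"])
# {'universe': 60, 'haplotype': 23, 'differential_expression': 7, 'overlap': 2}
```

This runs the full synthetic study end-to-end: both crosses are scanned,
the shared chromosome-14 adiposity locus is matched across them and its
interval refined, the 53–75 Mb region is dissected into IBD vs polymorphic
250-kb windows, the strain expression matrix is screened, eQTL scans
classify the planted regulatory architectures, and the two genes planted as
candidates — differentially expressed in the focal strain *and* located in
polymorphic haplotype blocks — come out as the final intersection, each with
attached cis-eQTL evidence.

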