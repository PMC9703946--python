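"""Synthetic backcross populations, expression traits and variant tables.

The generators emulate the statistical structure the analysis assumes:

* **Meiosis.**  Each N2 individual inherits one recombinant F1 gamete; the
  gamete is a two-state Markov chain along each chromosome with Haldane
  recombination fractions (no crossover interference), so genotype classes
  ``A`` (homozygous recurrent parent) and ``H`` (heterozygous) segregate
  1:1 at every locus.
* **Phenotypes.**  ``y_i = mean + sum_q a_q * 1[g_iq = A] + eps_i`` with
  Gaussian residuals; effects are parameterised on the ``A`` class, the
  direction in which the obese-strain allele acts on weight and adiposity.
* **Expression traits.**  qPCR-style: a genotype-dependent delta-Ct shift
  plus Gaussian Ct noise, stored as ``2^-dCt`` (hence lognormal on the
  expression scale).
* **Variant tables.**  Alternating identical-by-descent and polymorphic
  blocks: SNP counts per 250-kb window are Poisson at block-specific
  densities, with discordant rows carrying a focal-strain allele that
  differs from both lean strains.

Default study conditions: two backcross populations of ~300 females
genotyped at ~110 markers spaced 20 Mbp over 19 chromosomes, longitudinal
body-weight / fat-mass / blood-glucose traits, and a shared adiposity QTL
on chromosome 14 next to cross-specific loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import SimpleNamespace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    GENOTYPE_A,
    GENOTYPE_H,
    CrossPopulation,
    ExpressionMatrix,
    GeneAnnotation,
    GeneticMap,
    ValidationError,
    VariantTable,
)
from .genoprob import haldane

DEFAULT_CM_PER_MBP = 0.5
DEFAULT_SPACING_MBP = 20.0

#: stylised 19-autosome genome (Mbp); 20-Mbp marker spacing yields 113
#: markers, matching the ~105-110 markers of the emulated study design
DEFAULT_CHROM_LENGTHS_MBP: tuple[float, ...] = (
    160, 150, 140, 130, 120, 120, 110, 110, 100, 100,
    100, 90, 90, 90, 80, 80, 70, 70, 60,
)


# ---------------------------------------------------------------------------
# marker maps
# ---------------------------------------------------------------------------

def make_marker_map(
    chrom_lengths_mbp: Sequence[float] = DEFAULT_CHROM_LENGTHS_MBP,
    spacing_mbp: float = DEFAULT_SPACING_MBP,
    cm_per_mbp: float = DEFAULT_CM_PER_MBP,
    chrom_names: Sequence[str] | None = None,
) -> GeneticMap:
    """Markers at multiples of ``spacing_mbp`` from 0 to the chromosome end
    (inclusive); cM positions are Mbp * ``cm_per_mbp``."""
    if spacing_mbp <= 0:
        raise ValueError("marker spacing must be > 0")
    if cm_per_mbp <= 0:
        raise ValueError("cm_per_mbp must be > 0")
    names = (
        [str(i + 1) for i in range(len(chrom_lengths_mbp))]
        if chrom_names is None
        else [str(c) for c in chrom_names]
    )
    rows = []
    for chrom, length in zip(names, chrom_lengths_mbp):
        if length <= 0:
            raise ValueError(f"chromosome {chrom}: nonpositive length {length}")
        mbp = np.arange(0.0, length + 1e-9, spacing_mbp)
        for m in mbp:
            rows.append(
                (f"S{chrom}_{int(round(m * 1e6)):09d}", chrom, m * cm_per_mbp, m)
            )
    return GeneticMap(pd.DataFrame(rows, columns=["marker", "chrom", "cm", "mbp"]))


# ---------------------------------------------------------------------------
# backcross populations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraitSpec:
    """Baseline of one phenotype column: mean, residual SD, positivity."""

    mean: float = 0.0
    sd: float = 1.0
    positive: bool = False  # floor at a small positive value (e.g. glucose)

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValidationError("trait residual SD must be > 0")


@dataclass(frozen=True)
class QtlSpec:
    """A planted QTL: locus plus additive effect on the ``A`` class per trait.

    ``sigma_e`` is the residual SD used for any affected trait without an
    explicit :class:`TraitSpec`.
    """

    chromosome: str
    position_cm: float
    effects: Mapping[str, float]
    sigma_e: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_e <= 0:
            raise ValidationError("sigma_e must be > 0")


def weekly(family: str, schedule: Mapping[int, float]) -> dict[str, float]:
    """Expand a per-week effect schedule into trait-column keys
    (``bw``, {6: 2.0, 20: 3.5} -> {"bw_wk06": 2.0, "bw_wk20": 3.5})."""
    return {f"{family}_wk{int(w):02d}": v for w, v in schedule.items()}


def _simulate_gametes(rng, cm: np.ndarray, n: int) -> np.ndarray:
    """State 0 = recurrent-parent allele, 1 = lean-strain allele; (n, L)."""
    L = len(cm)
    states = np.empty((n, L), dtype=np.int8)
    states[:, 0] = rng.integers(0, 2, n)
    r = haldane(np.diff(cm))
    for j in range(1, L):
        flip = rng.random(n) < r[j - 1]
        states[:, j] = np.where(flip, 1 - states[:, j - 1], states[:, j - 1])
    return states


def simulate_backcross(
    gmap: GeneticMap,
    n_individuals: int,
    qtl_specs: Sequence[QtlSpec] = (),
    seed: int = 0,
    traits: Mapping[str, TraitSpec] | None = None,
    cross_label: str = "sim",
    genotype_missing_rate: float = 0.0,
) -> CrossPopulation:
    """Simulate an N2 backcross with planted QTL.

    QTL genotypes are realised at their cM position on the same simulated
    gamete as the markers, so marker-QTL linkage follows the map exactly.
    """
    rng = np.random.default_rng(seed)
    traits = dict(traits or {})

    for q in qtl_specs:
        if q.chromosome not in gmap.chromosomes:
            raise ValidationError(f"QTL chromosome {q.chromosome!r} not on the map")
        sub = gmap.markers_on(q.chromosome)
        if not (sub["cm"].min() <= q.position_cm <= sub["cm"].max()):
            raise ValidationError(
                f"QTL at {q.position_cm} cM is off the map of chromosome "
                f"{q.chromosome} ({sub['cm'].min()}-{sub['cm'].max()} cM)"
            )

    trait_names = list(traits)
    for q in qtl_specs:
        for t in q.effects:
            if t not in trait_names:
                trait_names.append(t)
                traits[t] = TraitSpec(0.0, q.sigma_e)

    n = int(n_individuals)
    geno_cols: dict[str, np.ndarray] = {}
    qtl_is_a: dict[int, np.ndarray] = {}  # spec index -> indicator of class A
    for chrom in gmap.chromosomes:
        sub = gmap.markers_on(chrom)
        mcm = sub["cm"].to_numpy(dtype=float)
        qidx = [i for i, q in enumerate(qtl_specs) if q.chromosome == chrom]
        loci = np.concatenate([mcm, [qtl_specs[i].position_cm for i in qidx]])
        order = np.argsort(loci, kind="stable")
        states = (
            _simulate_gametes(rng, loci[order], n)
            if n
            else np.empty((0, len(loci)), dtype=np.int8)
        )
        unorder = np.empty_like(order)
        unorder[order] = np.arange(len(order))
        states = states[:, unorder]
        for j, marker in enumerate(sub["marker"]):
            col = np.where(states[:, j] == 0, GENOTYPE_A, GENOTYPE_H).astype(object)
            if genotype_missing_rate > 0 and n:
                col[rng.random(n) < genotype_missing_rate] = np.nan
            geno_cols[marker] = col
        for k, i in enumerate(qidx):
            qtl_is_a[i] = states[:, len(mcm) + k] == 0

    ids = pd.Index([f"{cross_label}_{i + 1:04d}" for i in range(n)], name="id")
    genotypes = pd.DataFrame(geno_cols, index=ids, columns=list(gmap.table["marker"]))

    pheno = {}
    for t in trait_names:
        spec = traits[t]
        y = spec.mean + rng.normal(0.0, spec.sd, n)
        for i, q in enumerate(qtl_specs):
            if t in q.effects:
                y = y + q.effects[t] * qtl_is_a[i]
        if spec.positive:
            y = np.maximum(y, 0.5)
        pheno[t] = y
    phenotypes = pd.DataFrame(pheno, index=ids, columns=trait_names, dtype=float)

    return CrossPopulation(
        gmap,
        genotypes,
        phenotypes,
        cross_label=cross_label,
        metadata={
            "seed": seed,
            "sex": "female",
            "planted_qtl": [
                {
                    "chromosome": q.chromosome,
                    "position_cm": q.position_cm,
                    "effects": dict(q.effects),
                }
                for q in qtl_specs
            ],
        },
    )


# ---------------------------------------------------------------------------
# expression traits (cis/trans eQTL architecture)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionTraitSpec:
    """A planted expression trait for eQTL scans.

    ``dct_shift`` is the delta-Ct added in the heterozygous class (negative
    shift = lower Ct = higher expression in heterozygotes); trait values are
    stored as ``2^-dCt``.
    """

    gene: str
    chromosome: str
    position_cm: float
    dct_shift: float
    base_dct: float = 8.0
    sd_dct: float = 1.0


def simulate_expression_traits(
    cross: CrossPopulation,
    specs: Sequence[ExpressionTraitSpec],
    seed: int = 0,
) -> CrossPopulation:
    """Append ``2^-dCt`` expression traits driven by a planted locus."""
    rng = np.random.default_rng(seed)
    pheno = cross.phenotypes.copy()
    n = cross.n_individuals
    for spec in specs:
        if spec.chromosome not in cross.gmap.chromosomes:
            raise ValidationError(
                f"unknown locus: chromosome {spec.chromosome!r} not on the map"
            )
        sub = cross.gmap.markers_on(spec.chromosome)
        if not (sub["cm"].min() <= spec.position_cm <= sub["cm"].max()):
            raise ValidationError(
                f"unknown locus: {spec.position_cm} cM off chromosome {spec.chromosome}"
            )
        nearest = sub.iloc[(sub["cm"] - spec.position_cm).abs().argsort().iloc[0]]
        g = cross.genotypes[nearest["marker"]].to_numpy(dtype=object)
        is_h = g == GENOTYPE_H
        missing = pd.isna(g)
        if missing.any():
            is_h = np.where(missing, rng.random(n) < 0.5, is_h)
        dct = spec.base_dct + spec.dct_shift * is_h.astype(float)
        dct = dct + rng.normal(0.0, spec.sd_dct, n)
        pheno[spec.gene] = np.power(2.0, -dct)
    meta = dict(cross.metadata)
    meta["expression_traits"] = list(meta.get("expression_traits", []))
    out = CrossPopulation(
        cross.gmap,
        cross.genotypes,
        pheno,
        cross_label=cross.cross_label,
        metadata=meta,
    )
    out.metadata["expression_traits"].extend(
        {
            "gene": s.gene,
            "chromosome": s.chromosome,
            "position_cm": s.position_cm,
            "dct_shift": s.dct_shift,
        }
        for s in specs
    )
    return out


# ---------------------------------------------------------------------------
# variant tables with IBD / polymorphic block structure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlockSpec:
    """One genomic block with target SNP densities per 250-kb window."""

    start: int  # bp, 0-based half-open
    end: int
    discordant_per_250kb: float
    total_per_250kb: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError("block end must exceed start")
        if self.discordant_per_250kb < 0 or self.total_per_250kb < 0:
            raise ValidationError("SNP densities must be >= 0")
        if self.total_per_250kb < self.discordant_per_250kb:
            raise ValidationError("total density must be >= discordant density")


_WINDOW_UNIT = 250_000.0


def simulate_variant_table(
    chromosome: str,
    region: tuple[int, int],
    block_specs: Sequence[BlockSpec],
    seed: int = 0,
    strains: Sequence[str] = ("NZO", "C3H", "129P2"),
) -> VariantTable:
    """Poisson-distributed SNPs per block.  Discordant rows give the focal
    (first) strain an allele differing from both other strains; the
    remaining rows are concordant (focal matches at least one)."""
    rng = np.random.default_rng(seed)
    focal, *others = strains
    blocks = sorted(block_specs, key=lambda b: b.start)
    for prev, nxt in zip(blocks, blocks[1:]):
        if nxt.start < prev.end:
            raise ValidationError("block specs overlap")
    for b in blocks:
        if b.start < region[0] or b.end > region[1]:
            raise ValidationError("block outside region")

    rows = []
    for b in blocks:
        scale = (b.end - b.start) / _WINDOW_UNIT
        n_disc = rng.poisson(b.discordant_per_250kb * scale)
        n_conc = rng.poisson(
            max(b.total_per_250kb - b.discordant_per_250kb, 0.0) * scale
        )
        pos = rng.integers(b.start, b.end, n_disc + n_conc) + 1  # 1-based
        for i, p in enumerate(pos):
            if i < n_disc:
                alleles = {focal: "G", **{s: "A" for s in others}}
            else:
                # focal shares an allele with at least one lean strain
                alt = others[int(rng.integers(0, len(others)))] if others else None
                alleles = {focal: "A", **{s: "A" for s in others}}
                if alt is not None and rng.random() < 0.5:
                    alleles[alt] = "C"
            rows.append((str(chromosome), int(p), "A", *[alleles[s] for s in strains]))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", *strains])
    if df.empty:
        df = pd.DataFrame(
            {
                "chrom": pd.Series(dtype=str),
                "pos": pd.Series(dtype=int),
                "ref": pd.Series(dtype=str),
                **{s: pd.Series(dtype=str) for s in strains},
            }
        )
    return VariantTable(df, tuple(strains))


# ---------------------------------------------------------------------------
# strain expression matrices
# ---------------------------------------------------------------------------

def simulate_strain_expression(
    n_genes: int,
    n_per_strain: int,
    de_spec: Mapping[str, float] | None = None,
    seed: int = 0,
    strains: Sequence[str] = ("NZO", "C3H", "129P2"),
    gene_names: Sequence[str] | None = None,
    base_log2: float = 8.0,
    sd_log2: float = 0.5,
) -> ExpressionMatrix:
    """Lognormal expression for three strain groups; ``de_spec`` maps gene
    name -> log2 shift applied in the focal (first) strain only."""
    if n_genes and n_per_strain < 2:
        raise ValueError("need at least 2 samples per strain")
    rng = np.random.default_rng(seed)
    de_spec = dict(de_spec or {})
    if gene_names is None:
        gene_names = [f"g{i + 1:04d}" for i in range(n_genes)]
    if len(gene_names) != n_genes:
        raise ValueError("gene_names length must equal n_genes")
    unknown = set(de_spec) - set(gene_names)
    if unknown:
        raise ValueError(f"de_spec names unknown genes: {sorted(unknown)}")
    focal = strains[0]
    samples, labels = [], {}
    for s in strains:
        for i in range(n_per_strain):
            name = f"{s}_{i + 1}"
            samples.append(name)
            labels[name] = s
    log2_vals = base_log2 + rng.normal(0.0, sd_log2, (n_genes, len(samples)))
    shift = np.array([de_spec.get(g, 0.0) for g in gene_names])
    focal_cols = np.array([labels[s] == focal for s in samples])
    log2_vals[:, focal_cols] += shift[:, None]
    values = pd.DataFrame(
        np.power(2.0, log2_vals), index=pd.Index(gene_names, name="gene"),
        columns=samples,
    )
    return ExpressionMatrix(values, labels)


# ---------------------------------------------------------------------------
# default end-to-end scenario
# ---------------------------------------------------------------------------

#: planted polymorphic blocks (bp) inside the chromosome-14 focal region
SCENARIO_REGION = (53_000_000, 75_000_000)
SCENARIO_POLY_BLOCKS = (
    (56_000_000, 58_250_000),
    (62_250_000, 66_250_000),
    (70_000_000, 71_750_000),
)
SCENARIO_POLY_DENSITY = (400.0, 650.0)  # discordant, total per 250 kb
SCENARIO_IBD_DENSITY = (15.0, 500.0)

SCENARIO_TRAITS = {
    "bw_wk06": TraitSpec(30.8, 3.0),
    "bw_wk10": TraitSpec(42.0, 4.5),
    "bw_wk15": TraitSpec(52.0, 5.5),
    "bw_wk20": TraitSpec(60.0, 6.5),
    "fm_wk06": TraitSpec(9.9, 2.0),
    "fm_wk10": TraitSpec(19.0, 3.5),
    "fm_wk15": TraitSpec(26.5, 4.5),
    "bg_wk20": TraitSpec(140.0, 25.0, positive=True),
}

SCENARIO_SHARED_QTL_CM = 30.0  # chromosome 14 (= 60 Mbp at 0.5 cM/Mbp)


def _scenario_qtl(shared_only: bool, cross: str) -> list[QtlSpec]:
    shared = QtlSpec(
        "14",
        SCENARIO_SHARED_QTL_CM,
        {
            **weekly("bw", {6: 2.0, 10: 2.5, 15: 3.0, 20: 3.5}),
            **weekly("fm", {6: 1.3, 10: 2.0, 15: 2.6}),
            **weekly("bg", {20: 12.0}),
        },
    )
    if shared_only:
        return [shared]
    if cross == "NZOxC3H":
        extra = QtlSpec(
            "10", 7.0,
            {**weekly("bw", {6: 2.3, 10: 2.6}), **weekly("fm", {6: 1.6, 10: 2.4})},
        )
    else:
        extra = QtlSpec(
            "1", 19.0,
            {**weekly("bw", {15: 2.5, 20: 3.9}), **weekly("bg", {20: 13.0})},
        )
    return [shared, extra]


def _scenario_genes() -> GeneAnnotation:
    rows = []
    for k in range(60):
        start = 53_100_000 + k * 360_000
        rows.append(("14", start, start + 150_000, f"G{k + 1:03d}", "."))
    return GeneAnnotation(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])
    )


#: nine focal-strain regulated genes: two inside polymorphic blocks (the
#: planted candidates), three annotated genes in IBD segments, four genes
#: outside the annotated region
SCENARIO_DE_SPEC = {
    "G031": -1.5,  # candidate, down in the focal strain
    "G050": 1.5,   # candidate, up in the focal strain
    "G005": -1.2,
    "G020": 1.2,
    "G040": -1.5,
    "X001": 1.5,
    "X002": -1.2,
    "X003": 1.2,
    "X004": -1.5,
}

SCENARIO_EXPRESSION_SPECS = (
    # strong cis trait: large delta-Ct gap at its own locus
    ExpressionTraitSpec("G031", "14", 31.99, dct_shift=-2.0, base_dct=10.0),
    # weaker cis trait
    ExpressionTraitSpec("G050", "14", 35.41, dct_shift=0.7, base_dct=8.0),
    # trans architecture: regulator on another chromosome
    ExpressionTraitSpec("G020", "2", 20.0, dct_shift=1.0, base_dct=8.0),
    # null expression trait
    ExpressionTraitSpec("G005", "14", 27.3, dct_shift=0.0, base_dct=8.0),
)


#: planted coding variation: discordant missense SNPs inside polymorphic
#: blocks, a few predicted deleterious but shared with lean panel strains
SCENARIO_N_MISSENSE = 42
SCENARIO_N_DELETERIOUS = 3


def _annotate_scenario_variants(variants: VariantTable, rng) -> VariantTable:
    """Add consequence / SIFT / lean-panel columns to the scenario table."""
    df = variants.data.copy()
    df["consequence"] = "intergenic_variant"
    df["sift"] = np.nan
    disc = (df["NZO"].notna() & df["C3H"].notna() & df["129P2"].notna()
            & (df["NZO"] != df["C3H"]) & (df["NZO"] != df["129P2"]))
    cand = np.flatnonzero(disc.to_numpy())
    n_mis = min(SCENARIO_N_MISSENSE, len(cand))
    mis = rng.choice(cand, size=n_mis, replace=False)
    df.loc[df.index[mis], "consequence"] = "missense_variant"
    sift = rng.uniform(0.1, 1.0, n_mis)
    sift[:SCENARIO_N_DELETERIOUS] = rng.uniform(0.0, 0.04, SCENARIO_N_DELETERIOUS)
    df.loc[df.index[mis], "sift"] = np.round(sift, 3)
    # lean reference panel: deleterious focal alleles are shared by a panel
    # strain (hence not focal-unique), the rest are not
    for panel in ("PANEL1", "PANEL2"):
        df[panel] = df["C3H"]
    shared = df.index[mis[:SCENARIO_N_DELETERIOUS]]
    df.loc[shared, "PANEL1"] = df.loc[shared, "NZO"]
    return VariantTable(df, variants.strains)


def default_scenario(
    seed: int = 0,
    n_c3h: int = 310,
    n_129: int = 307,
) -> SimpleNamespace:
    """Build the full synthetic study: two backcrosses with a shared
    chromosome-14 adiposity QTL, cis/trans expression traits, a
    block-structured variant table, gene annotations and a three-strain
    expression matrix with nine planted focal-strain genes."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, 5)
    gmap = make_marker_map()

    cross_c3h = simulate_backcross(
        gmap, n_c3h, _scenario_qtl(False, "NZOxC3H"), seed=int(seeds[0]),
        traits=SCENARIO_TRAITS, cross_label="NZOxC3H",
    )
    cross_c3h = simulate_expression_traits(
        cross_c3h, SCENARIO_EXPRESSION_SPECS, seed=int(seeds[1])
    )
    cross_129 = simulate_backcross(
        gmap, n_129, _scenario_qtl(False, "NZOx129P2"), seed=int(seeds[2]),
        traits=SCENARIO_TRAITS, cross_label="NZOx129P2",
    )

    start, end = SCENARIO_REGION
    blocks = []
    cursor = start
    for bs, be in SCENARIO_POLY_BLOCKS:
        if bs > cursor:
            blocks.append(BlockSpec(cursor, bs, *SCENARIO_IBD_DENSITY))
        blocks.append(BlockSpec(bs, be, *SCENARIO_POLY_DENSITY))
        cursor = be
    if cursor < end:
        blocks.append(BlockSpec(cursor, end, *SCENARIO_IBD_DENSITY))
    variants = simulate_variant_table("14", SCENARIO_REGION, blocks, seed=int(seeds[3]))
    variants = _annotate_scenario_variants(variants, np.random.default_rng(int(seeds[3]) + 1))

    genes = _scenario_genes()
    expr_gene_names = [f"G{k + 1:03d}" for k in range(60)] + [
        f"X{k + 1:03d}" for k in range(140)
    ]
    expr = simulate_strain_expression(
        n_genes=200,
        n_per_strain=5,
        de_spec=SCENARIO_DE_SPEC,
        seed=int(seeds[4]),
        gene_names=expr_gene_names,
    )

    return SimpleNamespace(
        gmap=gmap,
        cross_c3h=cross_c3h,
        cross_129=cross_129,
        variants=variants,
        genes=genes,
        expression=expr,
        truth=SimpleNamespace(
            shared_qtl=("14", SCENARIO_SHARED_QTL_CM),
            specific_qtl={"NZOxC3H": ("10", 7.0), "NZOx129P2": ("1", 19.0)},
            poly_blocks=SCENARIO_POLY_BLOCKS,
            candidates=("G031", "G050"),
            de_genes=tuple(sorted(SCENARIO_DE_SPEC)),
            cis_genes=("G031", "G050"),
            trans_genes=("G020",),
        ),
    )
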