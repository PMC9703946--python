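"""Strain-differential expression, qPCR quantification, eQTL orchestration
and the final candidate intersection.

Candidate logic: a gene is a candidate for the shared locus when it is
(1) differentially expressed in the focal strain versus *both* lean strains
in the QTL target tissue, with a consistent direction, and (2) located in a
genomic segment classified polymorphic between the focal strain and both
lean strains.  cis-eQTL evidence (an expression QTL whose peak co-locates
with the gene itself) corroborates a local regulatory variant.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    CrossPopulation,
    ExpressionMatrix,
    GeneAnnotation,
    ValidationError,
)
from .genoprob import (
    DEFAULT_ERROR_PROB,
    DEFAULT_STEP_CM,
    conditional_genotype_probs,
)
from .qtl_scan import np_scan, permutation_threshold

logger = logging.getLogger(__name__)

DEFAULT_CIS_WINDOW_MBP = 20.0


# ---------------------------------------------------------------------------
# strain-differential expression filter
# ---------------------------------------------------------------------------

def strain_differential_expression(
    matrix: ExpressionMatrix,
    focal: str = "NZO",
    others: Sequence[str] = ("C3H", "129P2"),
    alpha: float = 0.05,
    alternative: str = "two-sided",
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-gene rank-sum tests of the focal strain against each lean strain.

    A gene passes when both comparisons are significant at ``alpha`` and the
    two focal/lean mean-expression ratios fall on the same side of 1.
    ``alternative`` is passed to the (exact, unpaired) Mann-Whitney test;
    ``fdr=True`` applies Benjamini-Hochberg within each comparison before
    thresholding (off by default: the filter is a raw per-gene screen).
    """
    for s in (focal, *others):
        if s not in matrix.strains:
            raise ValidationError(f"strain {s!r} absent from expression matrix")
        if len(matrix.samples_of(s)) < 2:
            raise ValidationError(f"strain {s!r} has fewer than 2 samples")

    vals = matrix.values
    x = vals[matrix.samples_of(focal)].to_numpy(dtype=float)
    records = {"gene": vals.index.to_numpy()}
    for o in others:
        yo = vals[matrix.samples_of(o)].to_numpy(dtype=float)
        pvals = np.empty(len(vals))
        for i in range(len(vals)):
            pvals[i] = stats.mannwhitneyu(
                x[i], yo[i], alternative=alternative
            ).pvalue
        if fdr:
            pvals = _benjamini_hochberg(pvals)
        records[f"ratio_{o}"] = x.mean(axis=1) / yo.mean(axis=1)
        records[f"p_{o}"] = pvals
    df = pd.DataFrame(records).set_index("gene")

    ratios = df[[f"ratio_{o}" for o in others]]
    up = (ratios > 1).all(axis=1)
    down = (ratios < 1).all(axis=1)
    sig = (df[[f"p_{o}" for o in others]] < alpha).all(axis=1)
    df["direction"] = np.where(up, "up-in-focal", np.where(down, "down-in-focal", "mixed"))
    df["passed"] = sig & (up | down)
    return df.reset_index()


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    adj = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def passing_genes(de_records: pd.DataFrame) -> set[str]:
    return set(de_records.loc[de_records["passed"], "gene"])


# ---------------------------------------------------------------------------
# qPCR relative quantification
# ---------------------------------------------------------------------------

def delta_delta_ct(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> tuple[float, float]:
    """2^-ddCt relative quantification.

    ddCt = (Ct_target,sample - Ct_ref,sample)
         - (Ct_target,calibrator - Ct_ref,calibrator); fold = 2^-ddCt.
    """
    for v in (ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (
        ct_target_calibrator - ct_ref_calibrator
    )
    return ddct, 2.0 ** (-ddct)


# ---------------------------------------------------------------------------
# eQTL orchestration
# ---------------------------------------------------------------------------

@dataclass
class EqtlRecord:
    gene: str
    gene_chrom: str | None
    gene_mid_mbp: float
    peak_chrom: str
    peak_cm: float
    peak_lod: float
    peak_marker: str
    peak_marker_mbp: float
    threshold: float
    significant: bool
    regulation: str | None  # "cis" | "trans" | None (not significant)

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "gene_chrom": self.gene_chrom,
            "gene_mid_mbp": self.gene_mid_mbp,
            "peak_chrom": self.peak_chrom,
            "peak_cm": self.peak_cm,
            "peak_lod": self.peak_lod,
            "peak_marker": self.peak_marker,
            "peak_marker_mbp": self.peak_marker_mbp,
            "threshold": self.threshold,
            "significant": self.significant,
            "regulation": self.regulation,
        }


def classify_cis(
    peak_chrom: str,
    peak_marker_mbp: float,
    gene_chrom: str,
    gene_mid_mbp: float,
    window_mbp: float = DEFAULT_CIS_WINDOW_MBP,
) -> str:
    """cis iff the peak is on the gene's chromosome and the peak marker lies
    within ``window_mbp`` of the gene midpoint."""
    if gene_chrom is None or not math.isfinite(gene_mid_mbp):
        raise ValidationError("gene location required for cis/trans classification")
    if str(peak_chrom) != str(gene_chrom):
        return "trans"
    if not math.isfinite(peak_marker_mbp):
        raise ValidationError("peak marker has no Mbp position")
    return "cis" if abs(peak_marker_mbp - gene_mid_mbp) <= window_mbp else "trans"


def eqtl_scan_all(
    cross: CrossPopulation,
    genes: GeneAnnotation,
    gene_traits: Iterable[str] | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    step_cm: float = DEFAULT_STEP_CM,
    error_prob: float = DEFAULT_ERROR_PROB,
    cis_window_mbp: float = DEFAULT_CIS_WINDOW_MBP,
) -> list[EqtlRecord]:
    """Nonparametric genome scan per expression trait with a per-gene
    permutation threshold and cis/trans classification of significant peaks.

    ``gene_traits`` defaults to every phenotype column whose name appears in
    the gene annotation.  Genes whose trait is entirely missing are skipped
    with a log entry.
    """
    ann = genes.data.set_index("name")
    if gene_traits is None:
        gene_traits = [t for t in cross.traits if t in ann.index]
    probs = conditional_genotype_probs(cross, step_cm=step_cm, error_prob=error_prob)
    records = []
    for i, gene in enumerate(gene_traits):
        y = cross.phenotypes[gene]
        if y.notna().sum() == 0:
            logger.warning("gene %s: expression trait entirely missing; skipped", gene)
            continue
        scan = np_scan(probs, y, trait=gene)
        perm = permutation_threshold(
            probs, y, n_perm=n_perm, seed=seed + i, method="np", trait=gene
        )
        thr = perm.threshold(alpha)
        peak_chrom, peak_cm, peak_lod = scan.peak()
        idx = scan.positions
        chrom_pos = idx[idx["chrom"] == peak_chrom]
        marker_name = chrom_pos.loc[
            (chrom_pos["cm"] - peak_cm).abs().idxmin(), "nearest_marker"
        ]
        marker = cross.gmap.marker_row(marker_name)
        significant = peak_lod >= thr

        if gene in ann.index:
            g = ann.loc[gene]
            gene_chrom = str(g["chrom"])
            gene_mid = (float(g["start"]) + float(g["end"])) / 2.0 / 1e6
        else:
            gene_chrom, gene_mid = None, math.nan

        regulation = None
        if significant:
            regulation = classify_cis(
                peak_chrom, float(marker["mbp"]), gene_chrom, gene_mid,
                window_mbp=cis_window_mbp,
            )
        records.append(
            EqtlRecord(
                gene=gene,
                gene_chrom=gene_chrom,
                gene_mid_mbp=gene_mid,
                peak_chrom=peak_chrom,
                peak_cm=peak_cm,
                peak_lod=peak_lod,
                peak_marker=str(marker["marker"]),
                peak_marker_mbp=float(marker["mbp"]),
                threshold=thr,
                significant=bool(significant),
                regulation=regulation,
            )
        )
    return records


# ---------------------------------------------------------------------------
# candidate intersection and report
# ---------------------------------------------------------------------------

@dataclass
class CandidateReport:
    haplotype_genes: set[str]
    de_genes: set[str]
    intersection: list[str]
    venn: dict[str, int]
    evidence: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "haplotype_genes": sorted(self.haplotype_genes),
            "de_genes": sorted(self.de_genes),
            "intersection": self.intersection,
            "venn": self.venn,
            "evidence": self.evidence,
        }


def intersect_candidates(
    haplotype_genes: Iterable[str],
    de_records: pd.DataFrame | Iterable[str],
    universe_size: int | None = None,
) -> CandidateReport:
    """Intersect the haplotype candidate set with the passing DE genes."""
    hap = set(haplotype_genes)
    de = (
        passing_genes(de_records)
        if isinstance(de_records, pd.DataFrame)
        else set(de_records)
    )
    inter = sorted(hap & de)
    venn = {
        "universe": int(universe_size) if universe_size is not None else len(hap | de),
        "haplotype": len(hap),
        "differential_expression": len(de),
        "overlap": len(inter),
    }
    return CandidateReport(hap, de, inter, venn)


def compile_report(
    matches,
    grid,
    shortlist,
    de_records,
    eqtl_records,
    haplotype_genes: Iterable[str],
    config: Mapping | None = None,
    seed: int | None = None,
    universe_size: int | None = None,
    path_json=None,
    path_tsv=None,
) -> dict:
    """Assemble the full pipeline report (JSON-serialisable dict).

    Raises when a required stage output is missing, naming the stage.
    """
    stage_inputs = {
        "cross_comparison": matches,
        "haplotype_windows": grid,
        "variant_shortlist": shortlist,
        "differential_expression": de_records,
        "eqtl": eqtl_records,
    }
    for stage, value in stage_inputs.items():
        if value is None:
            raise ValidationError(f"missing stage output: {stage}")

    candidates = intersect_candidates(haplotype_genes, de_records, universe_size)
    eqtl_by_gene = {r.gene: r for r in eqtl_records}
    de_by_gene = (
        {row["gene"]: row for _, row in de_records.iterrows()}
        if isinstance(de_records, pd.DataFrame)
        else {}
    )
    for gene in candidates.intersection:
        ev: dict = {}
        if gene in de_by_gene:
            row = de_by_gene[gene]
            ev["differential_expression"] = {
                k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                for k, v in row.items()
                if k != "gene"
            }
        if gene in eqtl_by_gene:
            ev["eqtl"] = eqtl_by_gene[gene].to_dict()
        candidates.evidence[gene] = ev

    config_dict = dict(config) if config is not None else {}
    report = {
        "qtl_matches": [m.to_dict() for m in matches],
        "window_track": {
            "chromosome": grid.chromosome,
            "region": list(grid.region),
            "window_size": grid.window_size,
            "threshold": grid.threshold,
            "n_windows": int(grid.n_windows),
            "n_polymorphic": int(grid.windows["polymorphic"].sum()),
            "polymorphic_windows": grid.flagged[["start", "end", "discordant"]]
            .astype(int)
            .to_dict("records"),
        },
        "variant_shortlist": _shortlist_records(shortlist),
        "differential_expression": {
            "n_tested": int(len(de_records)),
            "passing": sorted(passing_genes(de_records)),
        },
        "eqtl": [r.to_dict() for r in eqtl_records],
        "candidates": candidates.to_dict(),
        "provenance": {
            "seed": seed,
            "config": config_dict,
            "config_digest": hashlib.sha256(
                json.dumps(config_dict, sort_keys=True, default=str).encode()
            ).hexdigest(),
        },
    }
    if path_json is not None:
        with open(path_json, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
    if path_tsv is not None:
        _qtl_table(matches).to_csv(path_tsv, sep="\t", index=False)
    return report


def _shortlist_records(shortlist: pd.DataFrame) -> list[dict]:
    cols = [c for c in ("chrom", "pos", "consequence", "sift", "deleterious",
                        "focal_unique") if c in shortlist.columns]
    return json.loads(shortlist[cols].to_json(orient="records"))


def _qtl_table(matches) -> pd.DataFrame:
    rows = []
    for m in matches:
        for s in (m.summary_1, m.summary_2):
            if s is None:
                continue
            a = s.class_stats.get("A")
            h = s.class_stats.get("H")
            rows.append(
                {
                    "locus": m.locus_label,
                    "chrom": s.chromosome,
                    "trait": s.trait,
                    "peak_cm": s.peak_cm,
                    "ci_lo": s.ci_lo,
                    "ci_hi": s.ci_hi,
                    "closest_marker_mbp": s.closest_marker_mbp,
                    "max_lod": s.max_lod,
                    "weeks": ",".join(str(w) for w in s.weeks) if s.weeks else "",
                    "mean_homozygous": a.mean if a else math.nan,
                    "mean_heterozygous": h.mean if h else math.nan,
                    "status": m.status,
                    "origin": m.origin,
                    "cross": s.cross_label,
                }
            )
    return pd.DataFrame(rows)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
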