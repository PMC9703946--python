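"""End-to-end orchestration: simulate-or-load inputs, genome scans with
permutation thresholds, cross comparison, haplotype windows, differential
expression, eQTL and the candidate report, all driven by one configuration
object and one seed.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from . import core_io, cross_compare, expression_candidates, haplotype_windows
from .core_io import ValidationError
from .genoprob import conditional_genotype_probs
from .qtl_scan import (
    em_scan,
    log2_transform,
    permutation_threshold,
    summarize_longitudinal,
)
from .synthetic_data import default_scenario

logger = logging.getLogger(__name__)

_WEEK_RE = re.compile(r"^(?P<family>[A-Za-z0-9]+)_wk(?P<week>\d+)$")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """All tunables of one analysis run.

    Thresholds mirror the standard design: 5% genome-wide significance from
    1000 phenotype permutations, 250-kb haplotype windows flagged above 100
    discordant SNPs, raw P < 0.05 differential-expression screen, SIFT < 0.05
    deleteriousness, 20-Mbp cis window.
    """

    seed: int = 0
    step_cm: float = 1.0
    error_prob: float = 1e-4
    n_perm: int = 1000
    alpha: float = 0.05
    window_size: int = 250_000
    snp_threshold: int = 100
    sift_cutoff: float = 0.05
    de_alpha: float = 0.05
    ci_method: str = "bayes"
    cis_window_mbp: float = 20.0
    # traits scanned genome-wide; None = every <family>_wk<week> column
    scan_traits: list[str] | None = None
    log2_families: tuple[str, ...] = ("bg",)
    region_chrom: str = "14"
    region_start: int = 53_000_000
    region_end: int = 75_000_000
    panel_strains: tuple[str, ...] = ("PANEL1", "PANEL2")
    # input paths; when None the packaged synthetic scenario is generated
    cross_path_1: str | None = None
    cross_path_2: str | None = None
    variants_path: str | None = None
    genes_path: str | None = None
    expression_path: str | None = None
    expression_labels_path: str | None = None
    n_individuals_1: int = 310
    n_individuals_2: int = 307

    def __post_init__(self) -> None:
        if self.n_perm < 100:
            raise ValidationError("n_perm must be >= 100")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if not 0 < self.de_alpha < 1:
            raise ValidationError("de_alpha must be in (0, 1)")
        if self.window_size <= 0:
            raise ValidationError("window_size must be > 0")
        if self.snp_threshold < 0:
            raise ValidationError("snp_threshold must be >= 0")
        if not 0 <= self.sift_cutoff <= 1:
            raise ValidationError("sift_cutoff must be in [0, 1]")
        if self.cis_window_mbp <= 0:
            raise ValidationError("cis_window_mbp must be > 0")
        if self.step_cm < 0:
            raise ValidationError("step_cm must be >= 0")
        if not 0 <= self.error_prob < 0.5:
            raise ValidationError("error_prob must be in [0, 0.5)")
        if self.region_end <= self.region_start:
            raise ValidationError("region_end must exceed region_start")
        if self.ci_method not in ("bayes", "lod_drop"):
            raise ValidationError("ci_method must be 'bayes' or 'lod_drop'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("log2_families", "panel_strains"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["log2_families"] = list(self.log2_families)
        d["panel_strains"] = list(self.panel_strains)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _weekly_traits(cross) -> dict[str, dict[int, str]]:
    """family -> {week: column} for every <family>_wk<week> phenotype."""
    out: dict[str, dict[int, str]] = {}
    for col in cross.traits:
        m = _WEEK_RE.match(col)
        if m:
            out.setdefault(m.group("family"), {})[int(m.group("week"))] = col
    return out


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise PipelineStageError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


@_stage("load_or_simulate")
def _load_inputs(config: RunConfig):
    paths = (config.cross_path_1, config.cross_path_2, config.variants_path,
             config.genes_path, config.expression_path,
             config.expression_labels_path)
    if all(p is not None for p in paths):
        from types import SimpleNamespace

        cross_1 = core_io.read_cross_csv(config.cross_path_1, cross_label="cross1")
        cross_2 = core_io.read_cross_csv(config.cross_path_2, cross_label="cross2")
        return SimpleNamespace(
            cross_c3h=cross_1,
            cross_129=cross_2,
            variants=core_io.read_variant_table(config.variants_path),
            genes=core_io.read_gene_annotation(config.genes_path),
            expression=core_io.read_expression_matrix(
                config.expression_path, config.expression_labels_path
            ),
            truth=None,
        )
    if any(p is not None for p in paths):
        raise ValidationError(
            "either provide all input paths or none (synthetic scenario)"
        )
    return default_scenario(
        config.seed, n_c3h=config.n_individuals_1, n_129=config.n_individuals_2
    )


@_stage("genome_scans")
def _scan_cross(cross, config: RunConfig, seed_base: int):
    """EM scans + permutation thresholds for each weekly trait; longitudinal
    summaries per trait family."""
    probs = conditional_genotype_probs(
        cross, step_cm=config.step_cm, error_prob=config.error_prob
    )
    families = _weekly_traits(cross)
    summaries = []
    scan_curves = {}
    offset = 0
    for family, weeks in sorted(families.items()):
        if config.scan_traits is not None:
            weeks = {w: c for w, c in weeks.items() if c in config.scan_traits}
            if not weeks:
                continue
        scans, thresholds = {}, {}
        for week, col in sorted(weeks.items()):
            y = cross.phenotypes[col]
            transform = None
            if family in config.log2_families:
                y = log2_transform(y)
                transform = "log2"
            scans[week] = em_scan(probs, y, trait=col, transform=transform)
            perm = permutation_threshold(
                probs, y, n_perm=config.n_perm, seed=seed_base + offset,
                method="em", trait=col,
            )
            thresholds[week] = perm.threshold(config.alpha)
            scan_curves[col] = (scans[week], thresholds[week])
            offset += 1
        summaries.extend(
            summarize_longitudinal(scans, thresholds, cross, family,
                                   ci_method=config.ci_method)
        )
    return summaries, scan_curves


@_stage("haplotype_windows")
def _windows(inputs, config: RunConfig):
    grid = haplotype_windows.window_snp_counts(
        inputs.variants, config.region_chrom,
        (config.region_start, config.region_end), config.window_size,
    )
    grid = haplotype_windows.classify_polymorphic_windows(grid, config.snp_threshold)
    hap_genes = haplotype_windows.genes_in_polymorphic_regions(grid, inputs.genes)
    panel = [p for p in config.panel_strains if p in inputs.variants.data.columns]
    shortlist = haplotype_windows.nonsynonymous_shortlist(
        inputs.variants, panel_strains=panel, sift_cutoff=config.sift_cutoff
    )
    return grid, hap_genes, shortlist


def run_pipeline(config: RunConfig, outdir=None) -> dict:
    """Execute the full comparative-cross candidate-gene analysis.

    Returns the report dict; when ``outdir`` is given every stage output is
    persisted there (scan curves, summaries, matches, window grid, DE table,
    eQTL records, report JSON + QTL TSV, config).
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        (out / "scans").mkdir(exist_ok=True)
        config.to_yaml(out / "config.yaml")

    inputs = _load_inputs(config)
    logger.info("inputs ready (seed=%d)", config.seed)

    summaries_1, curves_1 = _scan_cross(inputs.cross_c3h, config, config.seed + 10_000)
    summaries_2, curves_2 = _scan_cross(inputs.cross_129, config, config.seed + 20_000)
    if out is not None:
        for label, curves in (("cross1", curves_1), ("cross2", curves_2)):
            for col, (scan, thr) in curves.items():
                scan.to_tsv(out / "scans" / f"{label}_{col}.tsv")
        _dump_json(out / "summaries.json", {
            "cross1": [s.to_dict() for s in summaries_1],
            "cross2": [s.to_dict() for s in summaries_2],
        })

    try:
        matches = cross_compare.match_qtl(summaries_1, summaries_2)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(f"stage 'cross_comparison' failed: {exc}") from exc
    if out is not None:
        _dump_json(out / "matches.json", [m.to_dict() for m in matches])

    grid, hap_genes, shortlist = _windows(inputs, config)
    if out is not None:
        grid.to_tsv(out / "window_grid.tsv")
        shortlist.to_csv(out / "variant_shortlist.tsv", sep="\t", index=False)

    try:
        de_records = expression_candidates.strain_differential_expression(
            inputs.expression, alpha=config.de_alpha
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(
            f"stage 'differential_expression' failed: {exc}"
        ) from exc
    if out is not None:
        de_records.to_csv(out / "differential_expression.tsv", sep="\t", index=False)

    try:
        eqtl_records = expression_candidates.eqtl_scan_all(
            inputs.cross_c3h, inputs.genes,
            n_perm=config.n_perm, alpha=config.alpha, seed=config.seed + 30_000,
            step_cm=config.step_cm, error_prob=config.error_prob,
            cis_window_mbp=config.cis_window_mbp,
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(f"stage 'eqtl' failed: {exc}") from exc
    if out is not None:
        _dump_json(out / "eqtl.json", [r.to_dict() for r in eqtl_records])

    try:
        report = expression_candidates.compile_report(
            matches, grid, shortlist, de_records, eqtl_records, hap_genes,
            config=asdict(config), seed=config.seed,
            universe_size=len(inputs.genes),
            path_json=None if out is None else out / "report.json",
            path_tsv=None if out is None else out / "report.tsv",
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(f"stage 'report' failed: {exc}") from exc
    return report


def _dump_json(path, obj) -> None:
    from .expression_candidates import _jsonable

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
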