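"""Window-based dissection of a QTL interval into IBD and polymorphic
segments from multi-strain SNPs.

The focal region is tiled with fixed windows (default 250 kb) anchored at
the region start.  In each window two counts are taken: the total number of
variant rows, and the number of *discordant* SNPs — positions where the
focal strain carries an allele differing from **both** lean comparison
strains (a missing call never counts as discordant).  A window whose
discordant count strictly exceeds the threshold (default 100) is flagged
polymorphic; genes overlapping at least one flagged window by >= 1 bp are
the haplotype candidate set.  A nonsynonymous shortlist filters discordant
missense rows and annotates predicted-deleterious (low SIFT score) and
focal-strain-unique flags.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import GeneAnnotation, ValidationError, VariantTable

DEFAULT_WINDOW_SIZE = 250_000
DEFAULT_SNP_THRESHOLD = 100
DEFAULT_SIFT_CUTOFF = 0.05


@dataclass
class WindowGrid:
    """Tiling windows with per-window SNP counts and polymorphic flags.

    ``windows`` columns: start, end (0-based half-open), total, discordant,
    polymorphic.  Windows tile ``region`` without gaps; the last window may
    be partial.
    """

    chromosome: str
    region: tuple[int, int]
    window_size: int
    windows: pd.DataFrame
    threshold: int | None = None

    def __post_init__(self) -> None:
        w = self.windows
        if len(w):
            if (w["discordant"] > w["total"]).any():
                raise ValidationError("discordant count exceeds total count")
            starts = w["start"].to_numpy()
            ends = w["end"].to_numpy()
            if not (starts[1:] == ends[:-1]).all():
                raise ValidationError("windows do not tile the region")

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def flagged(self) -> pd.DataFrame:
        return self.windows[self.windows["polymorphic"]]

    def to_tsv(self, path) -> None:
        df = self.windows.copy()
        df.insert(0, "chrom", self.chromosome)
        df.to_csv(path, sep="\t", index=False)


def window_snp_counts(
    variants: VariantTable,
    chromosome: str,
    region: tuple[int, int],
    window_size: int = DEFAULT_WINDOW_SIZE,
    focal: str = "NZO",
    others: Sequence[str] = ("C3H", "129P2"),
) -> WindowGrid:
    """Count total and discordant SNPs in tiling windows over ``region``.

    A 1-based variant position ``p`` falls in window ``[s, e)`` iff
    ``s <= p - 1 < e``.  Every in-region row contributes to the total count,
    so window totals sum to the number of in-region rows.
    """
    start, end = int(region[0]), int(region[1])
    if end <= start:
        raise ValidationError("region end must exceed region start")
    if window_size <= 0:
        raise ValidationError("window_size must be > 0")
    for col in (focal, *others):
        if col not in variants.data.columns:
            raise ValidationError(f"variant table missing strain column {col!r}")

    edges = np.arange(start, end, window_size, dtype=np.int64)
    ends = np.minimum(edges + window_size, end)

    sub = variants.on(chromosome)
    pos0 = sub["pos"].to_numpy(dtype=np.int64) - 1  # to 0-based
    in_region = (pos0 >= start) & (pos0 < end)
    sub = sub[in_region]
    pos0 = pos0[in_region]

    fa = sub[focal]
    disc = fa.notna()
    for o in others:
        oa = sub[o]
        disc = disc & oa.notna() & (fa != oa)
    disc = disc.to_numpy(dtype=bool) if len(sub) else np.zeros(0, dtype=bool)

    idx = ((pos0 - start) // window_size).astype(int)
    total = np.bincount(idx, minlength=len(edges)) if len(idx) else np.zeros(
        len(edges), dtype=int
    )
    discordant = (
        np.bincount(idx[disc], minlength=len(edges))
        if disc.any()
        else np.zeros(len(edges), dtype=int)
    )
    windows = pd.DataFrame(
        {
            "start": edges,
            "end": ends,
            "total": total.astype(int),
            "discordant": discordant.astype(int),
            "polymorphic": False,
        }
    )
    return WindowGrid(str(chromosome), (start, end), int(window_size), windows)


def classify_polymorphic_windows(
    grid: WindowGrid, threshold: int = DEFAULT_SNP_THRESHOLD
) -> WindowGrid:
    """Flag windows whose discordant count strictly exceeds ``threshold``."""
    windows = grid.windows.copy()
    windows["polymorphic"] = windows["discordant"] > int(threshold)
    return WindowGrid(
        grid.chromosome, grid.region, grid.window_size, windows, int(threshold)
    )


def genes_in_polymorphic_regions(grid: WindowGrid, genes: GeneAnnotation) -> set[str]:
    """Genes overlapping >= 1 bp of a flagged window (half-open semantics)."""
    flagged = grid.flagged
    if flagged.empty:
        return set()
    sub = genes.on(grid.chromosome)
    w_start = flagged["start"].to_numpy()
    w_end = flagged["end"].to_numpy()
    out = set()
    for _, g in sub.iterrows():
        if ((g["start"] < w_end) & (w_start < g["end"])).any():
            out.add(g["name"])
    return out


def nonsynonymous_shortlist(
    variants: VariantTable,
    panel_strains: Sequence[str] = (),
    sift_cutoff: float = DEFAULT_SIFT_CUTOFF,
    focal: str = "NZO",
    others: Sequence[str] = ("C3H", "129P2"),
) -> pd.DataFrame:
    """Missense rows where the focal strain differs from both lean strains.

    Adds ``deleterious`` (SIFT score < cutoff; missing score -> False) and
    ``focal_unique`` (the focal allele is seen in none of the panel strains;
    rows where a panel strain shares the focal allele are flagged False).
    """
    df = variants.data
    if "consequence" not in df.columns:
        raise ValidationError("variant table has no 'consequence' column")
    for col in panel_strains:
        if col not in df.columns:
            raise ValidationError(f"variant table missing panel strain {col!r}")

    cons = df["consequence"].astype(str).str.lower()
    is_missense = cons.str.startswith("missense")
    fa = df[focal]
    disc = fa.notna()
    for o in others:
        disc = disc & df[o].notna() & (fa != df[o])
    out = df[is_missense & disc].copy()

    if "sift" in out.columns:
        out["deleterious"] = (out["sift"] < sift_cutoff).fillna(False)
    else:
        out["deleterious"] = False

    unique = pd.Series(True, index=out.index)
    for p in panel_strains:
        shared = out[p].notna() & (out[p] == out[focal])
        unique &= ~shared
    out["focal_unique"] = unique
    return out.reset_index(drop=True)
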