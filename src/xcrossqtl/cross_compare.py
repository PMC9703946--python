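"""Matching QTL between two backcross populations.

A locus detected in both crosses (same chromosome, same trait family,
overlapping support intervals) points to a variant specific to the shared
recurrent parent; a locus detected in only one cross is most simply
explained by a variant derived from that cross's lean donor strain.  For
shared loci the support intervals can be intersected, which is how a
comparative-cross design refines the mapping resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

from .core_io import ValidationError
from .qtl_scan import QtlSummary

#: trait-family map: weekly body weight, fat/lean mass and blood glucose all
#: belong to one "obesity" family, so a body-weight hit in one cross can
#: match a fat-mass hit in the other
def default_trait_family(trait: str) -> str:
    key = trait.split("_")[0].split(" ")[0].lower()
    if key in {"bw", "bodyweight", "bodywt", "fm", "fatmass", "lm", "leanmass",
               "bg", "glucose", "bloodglucose", "obesity"}:
        return "obesity"
    return key


@dataclass
class QtlMatch:
    """A locus observed in one or both crosses."""

    locus_label: str
    trait_family: str
    chromosome: str
    summary_1: QtlSummary | None
    summary_2: QtlSummary | None
    status: str  # "shared" | "cross-specific"
    origin: str  # "NZO-specific" | "lean-strain-derived(<strain>)"
    refined_interval: tuple[float, float] | None

    def to_dict(self) -> dict:
        return {
            "locus": self.locus_label,
            "trait_family": self.trait_family,
            "chromosome": self.chromosome,
            "status": self.status,
            "origin": self.origin,
            "refined_interval": self.refined_interval,
            "cross_1": self.summary_1.to_dict() if self.summary_1 else None,
            "cross_2": self.summary_2.to_dict() if self.summary_2 else None,
        }


def _overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    """Zero-length (touching) intersections count as overlap."""
    return a[0] <= b[1] and b[0] <= a[1]


def match_qtl(
    summaries_1: Sequence[QtlSummary],
    summaries_2: Sequence[QtlSummary],
    lean_parents: tuple[str, str] = ("C3H", "129P2"),
    focal_strain: str = "NZO",
    trait_family: Callable[[str], str] | Mapping[str, str] = default_trait_family,
) -> list[QtlMatch]:
    """Pair QTL summaries of two crosses.

    Two summaries match iff they sit on the same chromosome, belong to the
    same trait family and their support intervals overlap.  Matched pairs
    are ``shared`` with a focal-strain (recurrent parent) origin; unmatched
    summaries are ``cross-specific`` and attributed to the lean donor strain
    of their own cross.  Every input summary appears in exactly one match.
    """
    if isinstance(trait_family, Mapping):
        mapping = dict(trait_family)

        def family_of(trait: str) -> str:
            if trait not in mapping:
                raise ValidationError(f"no trait-family mapping for {trait!r}")
            return mapping[trait]
    else:
        family_of = trait_family

    matches: list[QtlMatch] = []
    used_2 = [False] * len(summaries_2)

    def key(s: QtlSummary) -> tuple[str, str]:
        return (str(s.chromosome), family_of(s.trait))

    for s1 in sorted(summaries_1, key=lambda s: (s.chromosome, s.peak_cm)):
        partner = None
        for j, s2 in enumerate(summaries_2):
            if used_2[j] or key(s2) != key(s1):
                continue
            if _overlap(s1.interval, s2.interval):
                partner = j
                break
        chrom, family = key(s1)
        if partner is not None:
            used_2[partner] = True
            s2 = summaries_2[partner]
            refined = (
                max(s1.ci_lo, s2.ci_lo),
                min(s1.ci_hi, s2.ci_hi),
            )
            matches.append(
                QtlMatch(
                    locus_label=f"chr{chrom}:{family}",
                    trait_family=family,
                    chromosome=chrom,
                    summary_1=s1,
                    summary_2=s2,
                    status="shared",
                    origin=f"{focal_strain}-specific",
                    refined_interval=refined,
                )
            )
        else:
            matches.append(
                QtlMatch(
                    locus_label=f"chr{chrom}:{family}",
                    trait_family=family,
                    chromosome=chrom,
                    summary_1=s1,
                    summary_2=None,
                    status="cross-specific",
                    origin=f"lean-strain-derived({lean_parents[0]})",
                    refined_interval=None,
                )
            )
    for j, s2 in enumerate(summaries_2):
        if used_2[j]:
            continue
        chrom, family = key(s2)
        matches.append(
            QtlMatch(
                locus_label=f"chr{chrom}:{family}",
                trait_family=family,
                chromosome=chrom,
                summary_1=None,
                summary_2=s2,
                status="cross-specific",
                origin=f"lean-strain-derived({lean_parents[1]})",
                refined_interval=None,
            )
        )
    return matches


def refine_shared_interval(match: QtlMatch) -> tuple[float, float]:
    """Intersection of the two support intervals of a shared locus."""
    if match.status != "shared":
        raise ValidationError("refine_shared_interval needs a shared match")
    assert match.refined_interval is not None
    return match.refined_interval
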