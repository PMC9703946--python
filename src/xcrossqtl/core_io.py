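"""Readers and writers for the cross CSV dialect, variant tables, gene
annotations and expression matrices.

Coordinate conventions
----------------------
* Variant positions are 1-based (as in SNP databases).
* Gene and window intervals are 0-based half-open ``[start, end)``.
* Genetic map positions are centimorgan (cM); physical positions, where
  available, are megabase pairs (Mbp).

The cross file dialect is the common column-per-marker layout: a header row
with an optional ``id`` column, phenotype columns, then one column per
marker; two sub-header rows below the header carry the chromosome and the
cM position of each marker (blank under the non-marker columns).  Genotype
codes are ``A`` (homozygous for the recurrent parent, here NZO) and ``H``
(heterozygous), with a configurable missing token.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class CrossParseError(ValueError):
    """A file could not be parsed; the message names the offending row/cell."""


class ValidationError(ValueError):
    """A parsed object violates a structural invariant."""


GENOTYPE_A = "A"
GENOTYPE_H = "H"

#: default pattern used to recover Mbp positions from marker names such as
#: ``S14_063500000`` (chromosome 14, bp 63,500,000)
MBP_NAME_PATTERN = re.compile(r"^S(?P<chrom>\w+)_(?P<bp>\d{4,})$")


@dataclass(frozen=True)
class CrossDialect:
    """Tunable tokens of the cross CSV dialect."""

    genotype_a: str = "A"
    genotype_h: str = "H"
    missing_genotype: tuple[str, ...] = ("-", "", "NA")
    missing_phenotype: tuple[str, ...] = ("", "NA", "na", "NaN")
    id_column: str = "id"
    #: parse physical positions out of marker names when all names match
    mbp_from_names: bool = True


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------

@dataclass
class GeneticMap:
    """Marker map: one row per marker with chromosome, cM and optional Mbp.

    ``table`` columns: ``marker`` (unique), ``chrom`` (str), ``cm`` (float,
    nondecreasing within chromosome), ``mbp`` (float, NaN when unknown).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"marker", "chrom", "cm"}
        if not required.issubset(t.columns):
            raise ValidationError(f"map table needs columns {sorted(required)}")
        if "mbp" not in t.columns:
            t = t.assign(mbp=np.nan)
        t = t.reset_index(drop=True)
        t["chrom"] = t["chrom"].astype(str)
        if t["marker"].duplicated().any():
            dup = t.loc[t["marker"].duplicated(), "marker"].iloc[0]
            raise ValidationError(f"duplicate marker name {dup!r}")
        if (t["cm"] < 0).any():
            raise ValidationError("negative cM position in map")
        for chrom, sub in t.groupby("chrom", sort=False):
            if (np.diff(sub["cm"].to_numpy()) < 0).any():
                raise ValidationError(
                    f"cM positions not nondecreasing on chromosome {chrom}"
                )
        object.__setattr__(self, "table", t)

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    def markers_on(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chrom"] == str(chrom)]

    def marker_row(self, marker: str) -> pd.Series:
        rows = self.table[self.table["marker"] == marker]
        if rows.empty:
            raise KeyError(f"unknown marker {marker!r}")
        return rows.iloc[0]


# ---------------------------------------------------------------------------
# cross population
# ---------------------------------------------------------------------------

@dataclass
class CrossPopulation:
    """One backcross (N2) population: map, genotypes, phenotypes, metadata.

    ``genotypes``: DataFrame individuals x markers, values ``"A"``/``"H"``
    or NaN.  ``phenotypes``: DataFrame individuals x traits (numeric, NaN
    allowed); longitudinal traits use ``<family>_wk<week>`` column names.
    """

    gmap: GeneticMap
    genotypes: pd.DataFrame
    phenotypes: pd.DataFrame
    cross_label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        markers = list(self.gmap.table["marker"])
        if list(self.genotypes.columns) != markers:
            raise ValidationError(
                "genotype columns do not match marker map "
                f"({len(self.genotypes.columns)} columns vs {len(markers)} markers)"
            )
        vals = self.genotypes.to_numpy(dtype=object)
        ok = (vals == GENOTYPE_A) | (vals == GENOTYPE_H) | pd.isna(vals)
        if not ok.all():
            bad = vals[~ok][0]
            raise ValidationError(f"genotype code {bad!r} not in {{A, H, missing}}")
        if len(self.phenotypes) != len(self.genotypes):
            raise ValidationError(
                "phenotype table length does not match individual count"
            )
        if not self.phenotypes.index.equals(self.genotypes.index):
            raise ValidationError("phenotype and genotype indexes differ")

    @property
    def n_individuals(self) -> int:
        return len(self.genotypes)

    @property
    def individual_ids(self) -> pd.Index:
        return self.genotypes.index

    @property
    def traits(self) -> list[str]:
        return list(self.phenotypes.columns)


# ---------------------------------------------------------------------------
# cross CSV dialect
# ---------------------------------------------------------------------------

def _mbp_from_names(names: Sequence[str]) -> np.ndarray:
    out = np.full(len(names), np.nan)
    for i, name in enumerate(names):
        m = MBP_NAME_PATTERN.match(name)
        if m is None:
            return np.full(len(names), np.nan)
        out[i] = int(m.group("bp")) / 1e6
    return out


def read_cross_csv(
    path,
    dialect: CrossDialect = CrossDialect(),
    cross_label: str = "",
) -> CrossPopulation:
    """Read a cross file in the column-per-marker CSV dialect.

    Non-marker columns (blank chromosome sub-header) become phenotype
    columns, except a column named ``id`` which supplies individual ids.
    """
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 3:
        raise CrossParseError(
            f"{path}: need a header plus two sub-header rows, got {len(rows)} rows"
        )
    header, chrom_row, cm_row = rows[0], rows[1], rows[2]
    if len(chrom_row) != len(header) or len(cm_row) != len(header):
        raise CrossParseError(
            f"{path}: sub-header rows 2-3 must have {len(header)} fields "
            f"(got {len(chrom_row)} and {len(cm_row)})"
        )
    is_marker = [c.strip() != "" for c in chrom_row]
    marker_names = [h for h, m in zip(header, is_marker) if m]
    cm = []
    for h, m, c in zip(header, is_marker, cm_row):
        if not m:
            if c.strip() != "":
                raise CrossParseError(
                    f"{path}: row 3 has a cM value under non-marker column {h!r}"
                )
            continue
        try:
            cm.append(float(c))
        except ValueError:
            raise CrossParseError(
                f"{path}: row 3, non-numeric cM {c!r} under marker {h!r}"
            ) from None
    chroms = [c.strip() for c, m in zip(chrom_row, is_marker) if m]

    mbp = _mbp_from_names(marker_names) if dialect.mbp_from_names else np.full(
        len(marker_names), np.nan
    )
    gmap = GeneticMap(
        pd.DataFrame(
            {"marker": marker_names, "chrom": chroms, "cm": cm, "mbp": mbp}
        )
    )

    pheno_cols = [h for h, m in zip(header, is_marker) if not m]
    data = rows[3:]
    for i, row in enumerate(data):
        if len(row) != len(header):
            raise CrossParseError(
                f"{path}: data row {i + 4} has {len(row)} fields, expected {len(header)}"
            )
    columns = {h: [row[j] for row in data] for j, h in enumerate(header)}

    # individual ids
    id_col = next(
        (c for c in pheno_cols if c.lower() == dialect.id_column.lower()), None
    )
    if id_col is not None:
        ids = pd.Index(columns[id_col], name=id_col)
        pheno_cols = [c for c in pheno_cols if c != id_col]
    else:
        ids = pd.RangeIndex(len(data))

    # genotypes
    geno = {}
    for name in marker_names:
        raw = columns[name]
        col = np.empty(len(raw), dtype=object)
        for i, tok in enumerate(raw):
            tok = tok.strip()
            if tok == dialect.genotype_a:
                col[i] = GENOTYPE_A
            elif tok == dialect.genotype_h:
                col[i] = GENOTYPE_H
            elif tok in dialect.missing_genotype:
                col[i] = np.nan
            else:
                raise CrossParseError(
                    f"{path}: unknown genotype token {tok!r} at data row "
                    f"{i + 4}, marker {name!r}"
                )
        geno[name] = col
    genotypes = pd.DataFrame(geno, index=ids, columns=marker_names)

    # phenotypes
    pheno = {}
    for name in pheno_cols:
        raw = [v.strip() for v in columns[name]]
        vals = [np.nan if v in dialect.missing_phenotype else v for v in raw]
        try:
            pheno[name] = pd.to_numeric(vals)
        except (ValueError, TypeError):
            bad = next(
                v for v in vals if not isinstance(v, float) and _not_numeric(v)
            )
            raise CrossParseError(
                f"{path}: non-numeric phenotype value {bad!r} in column {name!r}"
            ) from None
    phenotypes = pd.DataFrame(pheno, index=ids, columns=pheno_cols, dtype=float)

    return CrossPopulation(gmap, genotypes, phenotypes, cross_label=cross_label)


def _not_numeric(v) -> bool:
    try:
        float(v)
        return False
    except (ValueError, TypeError):
        return True


def write_cross_csv(cross: CrossPopulation, path, dialect: CrossDialect = CrossDialect()) -> None:
    """Write a cross in the dialect read by :func:`read_cross_csv`."""
    t = cross.gmap.table
    header = [dialect.id_column] + list(cross.phenotypes.columns) + list(t["marker"])
    n_pheno = 1 + len(cross.phenotypes.columns)
    chrom_row = [""] * n_pheno + list(t["chrom"])
    cm_row = [""] * n_pheno + [_fmt(v) for v in t["cm"]]
    miss = dialect.missing_genotype[0]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        w.writerow(chrom_row)
        w.writerow(cm_row)
        for idx in cross.individual_ids:
            row = [str(idx)]
            for c in cross.phenotypes.columns:
                v = cross.phenotypes.at[idx, c]
                row.append("" if pd.isna(v) else _fmt(v))
            for m in cross.genotypes.columns:
                g = cross.genotypes.at[idx, m]
                row.append(miss if pd.isna(g) else str(g))
            w.writerow(row)


def _fmt(v: float) -> str:
    return format(float(v), ".10g")


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------

MISSING_ALLELE_TOKENS = ("", ".", "-", "NA")


@dataclass
class VariantTable:
    """Multi-strain SNP rows: chrom, 1-based pos, ref and per-strain alleles.

    Optional columns: ``consequence`` (e.g. ``missense``) and ``sift``
    (score in [0, 1]; low = predicted deleterious).
    """

    data: pd.DataFrame
    strains: tuple[str, ...]

    def __post_init__(self) -> None:
        d = self.data
        required = ["chrom", "pos", "ref", *self.strains]
        for col in required:
            if col not in d.columns:
                raise ValidationError(f"variant table missing column {col!r}")
        if len(d) and (d["pos"] < 1).any():
            raise ValidationError("variant position < 1 (positions are 1-based)")
        if "sift" in d.columns and len(d):
            s = d["sift"].dropna()
            if ((s < 0) | (s > 1)).any():
                raise ValidationError("SIFT score outside [0, 1]")
        d = d.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
        object.__setattr__(self, "data", d)

    def __len__(self) -> int:
        return len(self.data)

    def on(self, chrom: str) -> pd.DataFrame:
        return self.data[self.data["chrom"].astype(str) == str(chrom)]


def read_variant_table(path, strains: Sequence[str] = ("NZO", "C3H", "129P2")) -> VariantTable:
    """Read a TSV of multi-strain SNPs; rows sorted by (chrom, pos)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("chrom", "pos", "ref"):
        if col not in df.columns:
            raise ValidationError(f"{path}: variant table missing column {col!r}")
    for s in strains:
        if s not in df.columns:
            raise ValidationError(f"{path}: missing strain column {s!r}")
    if len(df):
        df["pos"] = pd.to_numeric(df["pos"]).astype(int)
    else:
        df["pos"] = df["pos"].astype(int)
    allele_cols = ["ref", *strains]
    panel = [
        c
        for c in df.columns
        if c not in ("chrom", "pos", "consequence", "sift") and c not in allele_cols
    ]
    for col in allele_cols + panel:
        df[col] = df[col].replace(list(MISSING_ALLELE_TOKENS), np.nan)
    if "sift" in df.columns:
        df["sift"] = pd.to_numeric(df["sift"].replace("", np.nan))
    return VariantTable(df, tuple(strains))


def write_variant_table(table: VariantTable, path) -> None:
    df = table.data.copy()
    if "sift" in df.columns:
        df["sift"] = df["sift"].map(lambda v: "" if pd.isna(v) else format(v, ".6g"))
    df.to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# gene annotations (BED4)
# ---------------------------------------------------------------------------

@dataclass
class GeneAnnotation:
    """Gene intervals, 0-based half-open; names unique per chromosome."""

    data: pd.DataFrame  # columns: chrom, start, end, name[, strand]

    def __post_init__(self) -> None:
        d = self.data.reset_index(drop=True)
        d["chrom"] = d["chrom"].astype(str)
        if len(d):
            if (d["start"] >= d["end"]).any():
                bad = d[d["start"] >= d["end"]].iloc[0]
                raise ValidationError(
                    f"gene {bad['name']!r}: start {bad['start']} >= end {bad['end']}"
                )
            if d.duplicated(["chrom", "name"]).any():
                bad = d[d.duplicated(["chrom", "name"])].iloc[0]
                raise ValidationError(
                    f"duplicate gene {bad['name']!r} on chromosome {bad['chrom']}"
                )
        object.__setattr__(self, "data", d)

    def __len__(self) -> int:
        return len(self.data)

    def on(self, chrom: str) -> pd.DataFrame:
        return self.data[self.data["chrom"] == str(chrom)]


def read_gene_annotation(path) -> GeneAnnotation:
    """Read BED4(+strand) gene intervals."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise CrossParseError(
                    f"{path}: line {lineno}: expected >= 4 BED fields, got {len(fields)}"
                )
            chrom, start, end, name = fields[:4]
            strand = fields[4] if len(fields) > 4 else "."
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise CrossParseError(
                    f"{path}: line {lineno}: non-integer interval bounds"
                ) from None
            if start_i >= end_i:
                raise CrossParseError(
                    f"{path}: line {lineno}: start {start_i} >= end {end_i}"
                )
            records.append((chrom, start_i, end_i, name, strand))
    df = pd.DataFrame(
        records, columns=["chrom", "start", "end", "name", "strand"]
    )
    return GeneAnnotation(df)


def write_gene_annotation(genes: GeneAnnotation, path) -> None:
    genes.data.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples expression values plus a sample -> strain label map."""

    values: pd.DataFrame
    strain_of: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicated gene id {dup!r}")
        for s in self.values.columns:
            if s not in self.strain_of:
                raise ValidationError(f"sample {s!r} has no strain label")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def strains(self) -> list[str]:
        return list(dict.fromkeys(self.strain_of[s] for s in self.values.columns))

    def samples_of(self, strain: str) -> list[str]:
        return [s for s in self.values.columns if self.strain_of[s] == strain]


def read_expression_matrix(path, labels: Mapping[str, str] | str) -> ExpressionMatrix:
    """Read a genes x samples TSV; ``labels`` maps sample -> strain (or is a
    path to a two-column TSV with that mapping)."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    if isinstance(labels, (str, bytes)) or hasattr(labels, "__fspath__"):
        lab = pd.read_csv(labels, sep="\t", index_col=0, header=None).iloc[:, 0]
        labels = lab.to_dict()
    return ExpressionMatrix(values, dict(labels))


def write_expression_matrix(matrix: ExpressionMatrix, path, labels_path=None) -> None:
    matrix.values.to_csv(path, sep="\t")
    if labels_path is not None:
        with open(labels_path, "w") as fh:
            for s in matrix.values.columns:
                fh.write(f"{s}\t{matrix.strain_of[s]}\n")
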