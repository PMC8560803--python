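"""Readers, writers and validated in-memory types for the pipeline's formats.

Formats handled: BED (peak intervals, 0-based half-open), TSV/CSV
(differential-expression tables, TSS annotations, labeled matrices), GMT
(gene sets), and MatrixMarket triplets with separate row/column label files.

Coordinate convention is uniform: every interval leaving this module is
0-based half-open. Inputs in 1-based inclusive convention must be declared
(``one_based=True`` on :func:`read_bed`), which shifts starts on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "TSS_COLUMNS",
    "DETable",
    "GeneSet",
    "read_bed",
    "write_bed",
    "read_de_table",
    "write_de_table",
    "read_tss_table",
    "write_tss_table",
    "read_gene_sets",
    "write_gene_sets",
    "read_matrix",
    "write_matrix",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval, optionally carrying a summit offset."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.end - self.start
        ):
            raise ValueError(
                f"summit_offset {self.summit_offset} outside [0, {self.end - self.start})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


TSS_COLUMNS = ["gene_id", "chrom", "tss", "strand"]


@dataclass
class DETable:
    """One labeled differential-expression comparison.

    ``records`` is a DataFrame indexed by unique gene_id with columns
    log2fc, pvalue, fdr and (optionally) mean_expr. ``fdr_provenance`` may
    declare "BH" or "BY", in which case monotone consistency of fdr with
    pvalue is validated (sorting by pvalue never decreases fdr).
    """

    comparison_label: str
    records: pd.DataFrame
    fdr_provenance: str | None = None

    def __post_init__(self) -> None:
        df = self.records
        required = {"log2fc", "pvalue", "fdr"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"DE table missing columns: {sorted(missing)}")
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene_id in DE table: {dupes[:5]}")
        if (df.index == "").any():
            raise ValueError("empty gene_id in DE table")
        for col in ("pvalue", "fdr"):
            vals = df[col].to_numpy(float)
            if (vals < 0).any() or (vals > 1).any():
                raise ValueError(f"{col} outside [0, 1]")
        if self.fdr_provenance in ("BH", "BY"):
            ordered = df.sort_values(["pvalue", "fdr"])
            fdr_sorted = ordered["fdr"].to_numpy(float)
            if (fdr_sorted < np.maximum.accumulate(fdr_sorted) - 1e-12).any():
                raise ValueError(
                    "fdr not monotone-consistent with pvalue despite "
                    f"{self.fdr_provenance} provenance"
                )

    @property
    def genes(self) -> pd.Index:
        return self.records.index

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str] = field(default_factory=frozenset)
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("GeneSet name must be non-empty")
        object.__setattr__(self, "genes", frozenset(self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def intersection(self, other: "GeneSet") -> "GeneSet":
        return GeneSet(
            name=f"{self.name}&{other.name}",
            genes=self.genes & other.genes,
            description=f"intersection of {self.name} and {other.name}",
        )


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path, one_based: bool = False) -> list[GenomicInterval]:
    """Parse a BED file into 0-based half-open intervals.

    Track/browser/comment lines are skipped; the optional 4th column
    becomes the interval name. ``one_based=True`` declares 1-based
    inclusive input coordinates, shifted to the internal convention on read.
    """
    intervals: list[GenomicInterval] = []
    n_skipped = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                n_skipped += 1
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 tab-separated columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if one_based:
                start -= 1
            name = parts[3] if len(parts) >= 4 else None
            try:
                intervals.append(GenomicInterval(parts[0], start, end, name=name))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    logger.info("read_bed: %d intervals from %s (%d lines skipped)",
                len(intervals), path, n_skipped)
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None:
                cols.append(iv.name)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# DE tables

#: default header aliases; emitters disagree on column naming
DE_COLUMN_ALIASES: Mapping[str, str] = {
    "gene": "gene_id",
    "gene_id": "gene_id",
    "log2FoldChange": "log2fc",
    "log2fc": "log2fc",
    "logFC": "log2fc",
    "PValue": "pvalue",
    "pvalue": "pvalue",
    "p_value": "pvalue",
    "FDR": "fdr",
    "fdr": "fdr",
    "padj": "fdr",
    "mean_expr": "mean_expr",
    "baseMean": "mean_expr",
}


def read_de_table(
    path: str | Path,
    comparison_label: str,
    column_map: Mapping[str, str] | None = None,
    fdr_provenance: str | None = None,
) -> DETable:
    """Read a TSV differential-expression table into a :class:`DETable`.

    ``column_map`` extends/overrides the default header aliases
    (gene→gene_id, log2FoldChange→log2fc, PValue→pvalue, FDR→fdr).
    Duplicate gene ids and non-numeric statistics are errors.
    """
    aliases = dict(DE_COLUMN_ALIASES)
    if column_map:
        aliases.update(column_map)
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={c: aliases[c] for c in df.columns if c in aliases})
    missing = {"gene_id", "log2fc", "pvalue", "fdr"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].unique().tolist()
        raise ValueError(f"{path}: duplicate gene_id {dupes[:5]}")
    for col in ("log2fc", "pvalue", "fdr"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    df = df.set_index("gene_id")
    keep = [c for c in ("log2fc", "pvalue", "fdr", "mean_expr") if c in df.columns]
    return DETable(comparison_label, df[keep], fdr_provenance=fdr_provenance)


def write_de_table(table: DETable, path: str | Path) -> None:
    out = table.records.reset_index()
    out = out.rename(columns={out.columns[0]: "gene_id"})
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# TSS annotations


def read_tss_table(path: str | Path) -> pd.DataFrame:
    """TSS annotation TSV → DataFrame[gene_id, chrom, tss, strand] (0-based)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(TSS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing TSS columns {sorted(missing)}")
    return validate_tss_table(df[TSS_COLUMNS])


def validate_tss_table(df: pd.DataFrame) -> pd.DataFrame:
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_id in TSS table")
    if not df["strand"].isin(["+", "-"]).all():
        bad = df.loc[~df["strand"].isin(["+", "-"]), "strand"].unique()
        raise ValueError(f"invalid strand values: {bad}")
    if (df["tss"].to_numpy(int) < 0).any():
        raise ValueError("negative TSS position")
    return df.reset_index(drop=True)


def write_tss_table(df: pd.DataFrame, path: str | Path) -> None:
    df[TSS_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Parse GMT: ``name<TAB>description<TAB>gene...`` per line.

    Duplicate genes within a set are de-duplicated with a logged warning;
    lines with fewer than 3 fields (i.e. empty sets) are errors.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if len(set(genes)) < len(genes):
                logger.warning("%s:%d: duplicate genes in set %r de-duplicated",
                               path, lineno, name)
            if not genes:
                raise ValueError(f"{path}:{lineno}: empty gene set {name!r}")
            sets.append(GeneSet(name=name, genes=frozenset(genes), description=desc))
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.genes)]) + "\n")


# ---------------------------------------------------------------------------
# labeled matrices


def read_matrix(
    path: str | Path,
    row_labels: str | Path | None = None,
    col_labels: str | Path | None = None,
) -> pd.DataFrame:
    """Read a labeled numeric matrix.

    TSV/CSV: row labels in the first column, column labels in the header;
    empty cells stay NaN (missing, never silently zero). ``.mtx`` triplets
    need separate one-label-per-line row/column files; absent entries are 0
    by MatrixMarket convention.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        if row_labels is None or col_labels is None:
            raise ValueError("MTX input requires row_labels and col_labels files")
        from scipy.io import mmread

        raw = mmread(path)
        mat = np.asarray(raw.toarray() if hasattr(raw, "toarray") else raw)
        rows = Path(row_labels).read_text().split()
        cols = Path(col_labels).read_text().split()
        df = pd.DataFrame(mat, index=rows, columns=cols)
    else:
        sep = "," if path.suffix == ".csv" else "\t"
        lines = [l for l in path.read_text().splitlines() if l.strip()]
        header = lines[0].split(sep)[1:]
        if len(set(header)) < len(header):  # pandas would mangle these
            raise ValueError(f"{path}: duplicate column labels")
        widths = {len(line.split(sep)) for line in lines}
        if len(widths) > 1:
            raise ValueError(f"{path}: ragged rows (column counts {sorted(widths)})")
        df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate row labels")
    if df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate column labels")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix == ".csv" else "\t"
    df.to_csv(path, sep=sep)
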