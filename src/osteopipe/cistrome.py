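"""Peak-set logic and peak→gene association for cistrome comparison.

Two transcription-factor peak sets (e.g. the same factor assayed in two
cell types) are partitioned into cell-type-specific and shared subsets by
≥1 bp interval overlap; peaks are annotated promoter/distal against a TSS
window; and each peak is associated with genes whose basal-plus-extension
regulatory domain it overlaps (basal = 5 kb upstream / 1 kb downstream of
the TSS, extended to the neighbouring genes' basal domains, capped at
1 Mb). Cell-type-specific target genes are the intersection of the
specific-peak-associated genes with an independently derived regulated set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import GeneSet, GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "PeakPartition",
    "partition_peaks",
    "classify_promoter_distal",
    "build_regulatory_domains",
    "assign_peaks_to_genes",
    "derive_cell_type_targets",
]


@dataclass
class PeakPartition:
    a_specific: list[GenomicInterval] = field(default_factory=list)
    b_specific: list[GenomicInterval] = field(default_factory=list)
    shared_a: list[GenomicInterval] = field(default_factory=list)
    shared_b: list[GenomicInterval] = field(default_factory=list)
    label_a: str = "A"
    label_b: str = "B"


def _check_chrom_compat(peaks_a, peaks_b) -> None:
    chroms_a = {p.chrom for p in peaks_a}
    chroms_b = {p.chrom for p in peaks_b}
    if not chroms_a or not chroms_b or chroms_a & chroms_b:
        return
    strip = lambda s: {c[3:] if c.startswith("chr") else c for c in s}
    if strip(chroms_a) & strip(chroms_b):
        raise ValueError(
            "peak sets share no chromosome names but match after stripping a "
            "'chr' prefix — normalize naming (e.g. 'chr1' vs '1') before "
            "partitioning"
        )


def _summit_window(p: GenomicInterval, slop: int) -> tuple[int, int]:
    summit = p.start + (p.summit_offset if p.summit_offset is not None
                        else len(p) // 2)
    return max(0, summit - slop), summit + slop + 1


def partition_peaks(
    peaks_a: list[GenomicInterval],
    peaks_b: list[GenomicInterval],
    label_a: str = "A",
    label_b: str = "B",
    use_summits: bool = False,
    slop: int = 0,
) -> PeakPartition:
    """Split two peak sets into specific and shared subsets.

    A peak of one set is *shared* iff it overlaps any peak of the other set
    by at least 1 bp on half-open intervals (touching ends do not overlap);
    otherwise it is specific. Input order is preserved in every bucket.
    ``use_summits=True`` matches on summit ± ``slop`` windows instead of the
    full intervals (the interval midpoint stands in for a missing summit).
    """
    _check_chrom_compat(peaks_a, peaks_b)
    if use_summits:
        win_a = {id(p): _summit_window(p, slop) for p in peaks_a}
        win_b = {id(p): _summit_window(p, slop) for p in peaks_b}
        span = lambda p, w: w[id(p)]
    else:
        win_a = win_b = None
        span = lambda p, w: (p.start, p.end)

    def trees_of(peaks, wins):
        trees: dict[str, IntervalTree] = {}
        for p in peaks:
            s, e = span(p, wins)
            trees.setdefault(p.chrom, IntervalTree()).addi(s, e)
        return trees

    trees_b = trees_of(peaks_b, win_b)
    trees_a = trees_of(peaks_a, win_a)
    part = PeakPartition(label_a=label_a, label_b=label_b)
    for p in peaks_a:
        s, e = span(p, win_a)
        tree = trees_b.get(p.chrom)
        (part.shared_a if tree is not None and tree.overlaps(s, e)
         else part.a_specific).append(p)
    for p in peaks_b:
        s, e = span(p, win_b)
        tree = trees_a.get(p.chrom)
        (part.shared_b if tree is not None and tree.overlaps(s, e)
         else part.b_specific).append(p)
    logger.info(
        "partition_peaks: %s-specific=%d shared=%d | %s-specific=%d shared=%d",
        label_a, len(part.a_specific), len(part.shared_a),
        label_b, len(part.b_specific), len(part.shared_b),
    )
    return part


def classify_promoter_distal(
    peaks: list[GenomicInterval],
    tss: pd.DataFrame,
    promoter_window: int = 3000,
) -> list[str]:
    """Label each peak promoter/distal against strand-agnostic TSS windows.

    Promoter iff the peak overlaps [tss − window, tss + window) of any
    gene. Peaks on chromosomes absent from the annotation are labeled
    distal with a warning.
    """
    if tss.empty:
        raise ValueError("TSS table is empty")
    trees: dict[str, IntervalTree] = {}
    for _, row in tss.iterrows():
        start = max(0, int(row["tss"]) - promoter_window)
        end = int(row["tss"]) + promoter_window
        if end <= start:  # degenerate window: the TSS base itself
            end = start + 1
        trees.setdefault(row["chrom"], IntervalTree()).addi(start, end)
    labels = []
    missing_chroms = set()
    for p in peaks:
        tree = trees.get(p.chrom)
        if tree is None:
            missing_chroms.add(p.chrom)
            labels.append("distal")
        else:
            labels.append("promoter" if tree.overlaps(p.start, p.end) else "distal")
    if missing_chroms:
        logger.warning("classify_promoter_distal: chromosomes absent from TSS "
                       "annotation labeled distal: %s", sorted(missing_chroms))
    return labels


def build_regulatory_domains(
    tss: pd.DataFrame,
    basal_up: int = 5000,
    basal_down: int = 1000,
    max_ext: int = 1_000_000,
) -> pd.DataFrame:
    """Basal-plus-extension regulatory domains for every gene.

    Basal domain: [tss − basal_up, tss + basal_down) on the + strand,
    mirrored on −. Extended domain: each basal edge grows outward to the
    nearest neighbouring gene's basal domain on that side, capped at
    ``max_ext`` beyond the basal edge; without a neighbour the cap applies.
    Domains are clipped at 0 (no upper clip without chromosome sizes) and
    the extension never shrinks below the basal domain.
    """
    if not {"+", "-"}.issuperset(tss["strand"].unique()):
        raise ValueError("TSS strands must be '+' or '-'")
    rows = []
    for chrom, sub in tss.groupby("chrom", sort=False):
        sub = sub.reset_index(drop=True)
        pos = sub["tss"].to_numpy(int)
        # boundaries are computed on unclipped coordinates (all basal domains
        # then share one width); emitted coordinates are clipped at 0 below
        basal_start = np.where(sub["strand"] == "+", pos - basal_up, pos - basal_down)
        basal_end = np.where(sub["strand"] == "+", pos + basal_down, pos + basal_up)
        # all basal domains share one width, so ordering by start orders ends
        # too: the binding neighbour boundary on each side is the nearest
        # strictly-offset basal domain, clamped at the gene's own basal edge
        # when the neighbour's domain straddles it.
        order = np.argsort(basal_start, kind="stable")
        sorted_start = basal_start[order]
        sorted_end = basal_end[order]
        n = len(sub)
        for i in order:
            bs, be = int(basal_start[i]), int(basal_end[i])
            # nearest neighbour with strictly smaller start (ties = identical
            # domain, which imposes no boundary)
            left = np.searchsorted(sorted_start, basal_start[i], side="left") - 1
            right = np.searchsorted(sorted_start, basal_start[i], side="right")
            ext_start = bs - max_ext
            if left >= 0:
                ext_start = max(ext_start, min(int(sorted_end[left]), bs))
            ext_end = be + max_ext
            if right < n:
                ext_end = min(ext_end, max(int(sorted_start[right]), be))
            rows.append({
                "gene_id": sub.loc[i, "gene_id"],
                "chrom": chrom,
                "basal_start": max(bs, 0),
                "basal_end": be,
                "extended_start": int(max(ext_start, 0)),
                "extended_end": int(ext_end),
            })
    out = pd.DataFrame(rows)
    return out.sort_values(["chrom", "basal_start", "gene_id"]).reset_index(drop=True)


def assign_peaks_to_genes(
    peaks: list[GenomicInterval],
    tss: pd.DataFrame,
    basal_up: int = 5000,
    basal_down: int = 1000,
    max_ext: int = 1_000_000,
) -> list[set[str]]:
    """Associate each peak with every gene whose extended domain it overlaps.

    Returns one gene-id set per input peak (empty set when a peak overlaps
    no domain; the count of such peaks is reported via logging).
    """
    domains = build_regulatory_domains(tss, basal_up, basal_down, max_ext)
    trees: dict[str, IntervalTree] = {}
    for _, row in domains.iterrows():
        trees.setdefault(row["chrom"], IntervalTree()).addi(
            row["extended_start"], row["extended_end"], row["gene_id"]
        )
    out: list[set[str]] = []
    n_orphans = 0
    for p in peaks:
        tree = trees.get(p.chrom)
        genes = ({iv.data for iv in tree.overlap(p.start, p.end)}
                 if tree is not None else set())
        if not genes:
            n_orphans += 1
        out.append(genes)
    if n_orphans:
        logger.info("assign_peaks_to_genes: %d / %d peaks associate with no gene",
                    n_orphans, len(peaks))
    return out


def derive_cell_type_targets(specific_peak_genes: GeneSet,
                             regulated: GeneSet) -> GeneSet:
    """Cell-type-specific targets = peak-associated genes ∩ regulated genes."""
    if len(specific_peak_genes) == 0 or len(regulated) == 0:
        raise ValueError("both input gene sets must be non-empty")
    result = specific_peak_genes.intersection(regulated)
    logger.info("derive_cell_type_targets: |%s|=%d ∩ |%s|=%d -> %d genes",
                specific_peak_genes.name, len(specific_peak_genes),
                regulated.name, len(regulated), len(result))
    if len(result) == 0:
        logger.warning("derive_cell_type_targets: empty intersection")
    return result
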