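"""Cross-atlas permutation gene-set enrichment, ortholog mapping, nosology.

The permutation enrichment asks whether a gene set (e.g. osteocyte marker
genes or transcription-factor targets) is expressed preferentially in one
cell type of an aggregated (pseudobulk) atlas. Per cell type, each gene's
enrichment value is its expression minus the mean over the other cell
types; a gene set is scored by the mean of those values, and significance
comes from an empirical null of equally-sized gene sets sampled uniformly
from the atlas. Nosology enrichment tests marker overlap with curated
disease gene groups via the one-sided hypergeometric tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import bh_adjust, hypergeom_sf
from .io import GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "AtlasMatrix",
    "EnrichmentResult",
    "NosologyGroups",
    "aggregate_major_types",
    "celltype_enrichment_values",
    "celltype_fold_change_values",
    "geneset_score",
    "permutation_null_test",
    "map_orthologs",
    "nosology_enrichment",
]


@dataclass
class AtlasMatrix:
    """Cell-type × gene aggregated expression (log-like scale).

    ``values``: DataFrame with cell types as rows and genes as columns;
    ``major_type_map`` optionally maps subtype labels to major types.
    """

    values: pd.DataFrame
    major_type_map: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("atlas labels must be unique")
        if not np.isfinite(self.values.to_numpy(float)).all():
            raise ValueError("atlas values must be finite")

    @property
    def celltypes(self) -> pd.Index:
        return self.values.index

    @property
    def genes(self) -> pd.Index:
        return self.values.columns


@dataclass
class EnrichmentResult:
    celltype: str
    observed_score: float
    null_scores: np.ndarray
    p_empirical: float
    n_genes_used: int
    n_genes_missing: int
    seed: int


@dataclass
class NosologyGroups:
    """Disease groups: map group_name → set of (human) gene ids."""

    groups: dict[str, frozenset[str]]
    universe: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        self.groups = {k: frozenset(v) for k, v in self.groups.items()}
        self.universe = frozenset().union(*self.groups.values()) \
            if self.groups else frozenset()

    @classmethod
    def from_gene_sets(cls, sets: list[GeneSet]) -> "NosologyGroups":
        return cls({gs.name: gs.genes for gs in sets})


def aggregate_major_types(atlas: AtlasMatrix) -> AtlasMatrix:
    """Average subtype rows into their major types (arithmetic mean)."""
    if atlas.major_type_map is None:
        raise ValueError("atlas has no major_type_map")
    unmapped = [c for c in atlas.celltypes if c not in atlas.major_type_map]
    if unmapped:
        raise ValueError(f"subtypes without a major type: {unmapped}")
    grouped = atlas.values.groupby(
        atlas.values.index.map(atlas.major_type_map)).mean()
    return AtlasMatrix(grouped.sort_index())


def celltype_enrichment_values(atlas: AtlasMatrix) -> pd.DataFrame:
    """value(g, c) = expr(g, c) − mean over the other cell types."""
    vals = atlas.values
    n = len(vals)
    if n < 2:
        raise ValueError("need at least 2 cell types")
    total = vals.sum(axis=0)
    return vals - (total - vals) / (n - 1)


def celltype_fold_change_values(atlas: AtlasMatrix,
                                pseudo: float = 1e-9) -> pd.DataFrame:
    """Alternative scorer input: log2 ratio of linear-scale expression in a
    cell type over the mean of the others (atlas values are exponentiated
    first, so this matches a fold-change reading of the same comparison)."""
    lin = np.exp(atlas.values)
    n = len(lin)
    if n < 2:
        raise ValueError("need at least 2 cell types")
    others = (lin.sum(axis=0) - lin) / (n - 1)
    return np.log2((lin + pseudo) / (others + pseudo))


def geneset_score(values: pd.DataFrame, gene_set: GeneSet,
                  celltype: str) -> tuple[float, int, int]:
    """Mean enrichment value of the set's genes in one cell type.

    Returns (score, n_used, n_missing); genes absent from the atlas are
    counted as missing, zero usable genes is an error.
    """
    present = [g for g in gene_set.genes if g in values.columns]
    missing = len(gene_set) - len(present)
    if not present:
        raise ValueError(f"no genes of {gene_set.name!r} present in the atlas")
    score = float(values.loc[celltype, present].mean())
    return score, len(present), missing


def permutation_null_test(values: pd.DataFrame, gene_set: GeneSet,
                          celltype: str, n_iter: int = 500, seed: int = 0,
                          raw_empirical_p: bool = False) -> EnrichmentResult:
    """Empirical enrichment p-value against uniformly sampled null gene sets.

    Null sets are drawn without replacement from all atlas genes, with the
    same size as the usable observed set, and scored identically. The
    default p uses add-one smoothing, p = (1 + #{null >= observed}) /
    (1 + n_iter), so it can never be 0; ``raw_empirical_p=True`` gives the
    literal #{null >= observed} / n_iter. Ties count against the observed
    set (>=), the conservative reading.
    """
    observed, n_used, n_missing = geneset_score(values, gene_set, celltype)
    universe = values.columns.to_numpy()
    if n_used >= len(universe):
        raise ValueError("gene set size must be smaller than the atlas universe")
    rng = np.random.default_rng(seed)
    row = values.loc[celltype].to_numpy(float)
    null_scores = np.empty(n_iter)
    for i in range(n_iter):
        idx = rng.choice(len(universe), size=n_used, replace=False)
        null_scores[i] = row[idx].mean()
    n_ge = int((null_scores >= observed).sum())
    p = n_ge / n_iter if raw_empirical_p else (1 + n_ge) / (1 + n_iter)
    return EnrichmentResult(
        celltype=celltype, observed_score=observed, null_scores=null_scores,
        p_empirical=float(p), n_genes_used=n_used, n_genes_missing=n_missing,
        seed=seed,
    )


def map_orthologs(gene_set: GeneSet, pairs: set[tuple[str, str]],
                  mode: str = "one-to-one") -> GeneSet:
    """Map a (mouse) gene set to (human) orthologs.

    ``one-to-one`` keeps only genes whose mouse and human symbols each
    occur in exactly one pair (ambiguous genes dropped with a warning);
    ``all-pairs`` keeps every mapped partner. Unmapped genes are counted
    and logged.
    """
    if mode not in ("one-to-one", "all-pairs"):
        raise ValueError(f"unknown mode {mode!r}")
    by_mouse: dict[str, list[str]] = {}
    human_counts: dict[str, int] = {}
    for mouse, human in pairs:
        by_mouse.setdefault(mouse, []).append(human)
        human_counts[human] = human_counts.get(human, 0) + 1
    mapped: set[str] = set()
    n_unmapped = 0
    n_ambiguous = 0
    for gene in gene_set.genes:
        partners = by_mouse.get(gene)
        if not partners:
            n_unmapped += 1
            continue
        if mode == "all-pairs":
            mapped.update(partners)
        else:
            if len(partners) == 1 and human_counts[partners[0]] == 1:
                mapped.add(partners[0])
            else:
                n_ambiguous += 1
    if n_unmapped:
        logger.info("map_orthologs: %d genes of %s unmapped",
                    n_unmapped, gene_set.name)
    if n_ambiguous:
        logger.warning("map_orthologs: %d ambiguous genes dropped in "
                       "one-to-one mode", n_ambiguous)
    return GeneSet(name=f"{gene_set.name}_orthologs", genes=frozenset(mapped),
                   description=f"{mode} ortholog mapping of {gene_set.name}")


def nosology_enrichment(markers: GeneSet, groups: NosologyGroups,
                        bh: bool = False) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of markers in each disease group.

    Universe N = all nosology genes; draws n = markers ∩ universe. For a
    group with K genes and overlap k, p = P(X >= k | N, K, n) (exact tail;
    k = 0 gives p = 1). Expected overlap = n·K/N. Nominal p by default;
    ``bh=True`` adds a BH-adjusted column.
    """
    universe = groups.universe
    draws = markers.genes & universe
    n = len(draws)
    N = len(universe)
    if n == 0:
        logger.warning("nosology_enrichment: no marker genes in the nosology "
                       "universe; all p = 1")
    rows = []
    for name, genes in groups.groups.items():
        K = len(genes)
        k = len(draws & genes)
        p = hypergeom_sf(k, N, K, n) if n else 1.0
        rows.append({"group": name, "n_group": K, "overlap": k,
                     "expected": n * K / N if N else 0.0, "p": p})
    out = pd.DataFrame(rows).set_index("group")
    if bh:
        out["p_bh"] = bh_adjust(out["p"].to_numpy())
    return out
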