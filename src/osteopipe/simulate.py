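"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator is a pure function of its spec (seed included) and emits
the planted truth alongside the data, so downstream recovery, power and
calibration can be scored without any external download. One global seed
expands into independent per-component substreams via
``numpy.random.SeedSequence(seed, spawn_key)``, so adding a generator
never perturbs the outputs of existing ones.

Distributional choices (none are taken from any real dataset):

* DE p-values for non-null genes follow a shifted-normal z-score model,
  |z| ~ Normal(4, 1), p = 2·Φ(−|z|): this emulates differential-expression
  *outputs*, not count-model inference. Null p-values are Uniform(0, 1);
  null log2FC ~ Normal(0, 0.2). FDR columns are Benjamini–Hochberg within
  each table.
* Single-cell counts are gamma-Poisson, i.e. negative binomial
  parameterized by (mean μ, dispersion θ) with variance μ + μ²/θ.
* Atlas entries are baseline + Normal(0, noise_sd) on a log-like
  aggregated-expression scale.
* Morphology features are cell-level Normal(condition mean, 1); condition
  mean vectors are shared-baseline plus per-condition effect vectors
  scaled by ``treatment_effect``, with one condition pair sharing its
  effect vector (the planted similarity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .io import DETable, GeneSet, GenomicInterval
from .sc import CellExperiment

logger = logging.getLogger(__name__)

__all__ = [
    "DESimSpec",
    "ScSimSpec",
    "AtlasSimSpec",
    "simulate_de_pair",
    "simulate_genome_and_peaks",
    "simulate_single_cell_experiment",
    "simulate_atlas",
    "simulate_nosology_and_orthologs",
    "simulate_morphology_wells",
]

# stable substream indices: appending keeps earlier outputs unchanged
_COMPONENTS = {"de": 0, "peaks": 1, "sc": 2, "atlas": 3, "nosology": 4, "wells": 5}


def component_rng(seed: int, component: str) -> np.random.Generator:
    """Independent substream for one generator family under a global seed."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_COMPONENTS[component],)))


# ---------------------------------------------------------------------------
# paired DE tables


@dataclass(frozen=True)
class DESimSpec:
    n_genes: int = 5000
    n_doubly_significant: int = 560
    counter_fraction: float = 0.921
    effect_size_log2: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_doubly_significant > self.n_genes:
            raise ValueError("n_doubly_significant exceeds n_genes")
        if not 0 <= self.counter_fraction <= 1:
            raise ValueError("counter_fraction must lie in [0, 1]")
        if self.effect_size_log2 <= 0:
            raise ValueError("effect_size_log2 must be positive")


def _planted_pvalues(rng: np.random.Generator, n: int) -> np.ndarray:
    z = np.abs(rng.normal(4.0, 1.0, size=n))
    return 2 * stats.norm.sf(z)


def simulate_de_pair(spec: DESimSpec) -> tuple[DETable, DETable, GeneSet]:
    """Paired DE tables (opposite perturbations) with a planted counter set.

    Exactly ``n_doubly_significant`` genes end with FDR < 0.05 in both
    tables; round(counter_fraction · n_ds) of them have opposite log2FC
    signs with |log2FC| >= effect_size_log2, the rest matching signs.
    Because BH significance is a property of the whole table, the sampled
    p-values are repaired deterministically (planted genes that miss the
    threshold are shrunk, null genes that sneak into double significance
    are lifted in one table) until the planted structure holds exactly.
    """
    rng = component_rng(spec.seed, "de")
    n, n_ds = spec.n_genes, spec.n_doubly_significant
    n_counter = round(spec.counter_fraction * n_ds)
    if n_counter > n_ds:
        raise ValueError("rounding made counter count exceed doubly significant")
    genes = np.array([f"gene{i:05d}" for i in range(n)])
    order = rng.permutation(n)
    ds_idx = order[:n_ds]
    counter_idx = ds_idx[:n_counter]
    co_idx = ds_idx[n_counter:]

    tables = {}
    sign_a = rng.choice([-1.0, 1.0], size=n_ds)
    for label, flip in (("perturbation_a", 1.0), ("perturbation_b", -1.0)):
        p = rng.uniform(size=n)
        lfc = rng.normal(0.0, 0.2, size=n)
        p[ds_idx] = _planted_pvalues(rng, n_ds)
        magnitude = spec.effect_size_log2 + np.abs(rng.normal(0.0, 0.3, size=n_ds))
        signs = sign_a.copy()
        if flip < 0:
            # counter genes flip sign in table B, co genes keep it
            flip_mask = np.isin(ds_idx, counter_idx)
            signs = np.where(flip_mask, -sign_a, sign_a)
        lfc[ds_idx] = signs * magnitude
        tables[label] = {"p": p, "lfc": lfc}

    # deterministic repair: enforce the exact doubly-significant set
    for _ in range(200):
        fdr = {k: bh_adjust(v["p"]) for k, v in tables.items()}
        doubly = (fdr["perturbation_a"] < 0.05) & (fdr["perturbation_b"] < 0.05)
        planted = np.zeros(n, dtype=bool)
        planted[ds_idx] = True
        missed = planted & ~doubly
        extra = doubly & ~planted
        if not missed.any() and not extra.any():
            break
        for v in tables.values():
            v["p"][missed] *= 0.1
        if extra.any():
            # lift the table where the intruder's p is larger (less planted-like)
            pa = tables["perturbation_a"]["p"]
            pb = tables["perturbation_b"]["p"]
            lift_a = extra & (pa >= pb)
            lift_b = extra & ~lift_a
            pa[lift_a] = 0.5 + 0.5 * pa[lift_a]
            pb[lift_b] = 0.5 + 0.5 * pb[lift_b]
    else:
        raise RuntimeError("could not enforce the doubly-significant set")

    out = []
    for label in ("perturbation_a", "perturbation_b"):
        p = tables[label]["p"]
        df = pd.DataFrame(
            {"log2fc": tables[label]["lfc"], "pvalue": p, "fdr": bh_adjust(p)},
            index=pd.Index(genes, name="gene_id"),
        )
        out.append(DETable(label, df, fdr_provenance="BH"))
    planted_counter = GeneSet("planted_counter", frozenset(genes[counter_idx]),
                              "genes planted with opposite regulation")
    return out[0], out[1], planted_counter


# ---------------------------------------------------------------------------
# toy genome, TSS annotation, two peak sets


def simulate_genome_and_peaks(
    n_genes: int = 200,
    chrom_length: int = 10_000_000,
    n_peaks_a: int = 300,
    n_peaks_b: int = 200,
    shared_fraction: float = 0.3,
    seed: int = 0,
    peak_width: int = 300,
) -> tuple[pd.DataFrame, list[GenomicInterval], list[GenomicInterval], dict]:
    """One-chromosome toy genome with TSS annotation and two peak sets.

    A ``shared_fraction`` of A peaks is duplicated into B with a jitter of
    at most peak_width − 1 bp (guaranteeing >= 1 bp overlap); all other
    peaks occupy disjoint slots, so the specific/shared truth labels are
    exact by construction. Returns (tss, peaks_a, peaks_b, truth) where
    truth maps 'a'/'b' to per-peak label lists and 'tss' holds the gene
    table used.
    """
    if not 0 <= shared_fraction <= 1:
        raise ValueError("shared_fraction must lie in [0, 1]")
    rng = component_rng(seed, "peaks")
    n_shared = round(shared_fraction * n_peaks_a)
    n_slots = n_peaks_a + (n_peaks_b - n_shared)
    slot_width = 3 * peak_width  # jitter stays inside the slot
    if n_slots * slot_width > chrom_length:
        raise ValueError(
            f"chrom_length {chrom_length} too small for {n_slots} disjoint peaks; "
            f"need at least {n_slots * slot_width}")
    slots = rng.choice(chrom_length // slot_width, size=n_slots, replace=False)
    starts = np.sort(slots) * slot_width + peak_width
    rng.shuffle(starts)

    tss_pos = rng.choice(chrom_length, size=n_genes, replace=False)
    tss = pd.DataFrame({
        "gene_id": [f"gene{i:05d}" for i in range(n_genes)],
        "chrom": "chr1",
        "tss": np.sort(tss_pos),
        "strand": rng.choice(["+", "-"], size=n_genes),
    })

    peaks_a: list[GenomicInterval] = []
    peaks_b: list[GenomicInterval] = []
    labels_a: list[str] = []
    labels_b: list[str] = []
    shared_starts = starts[:n_shared]
    a_only_starts = starts[n_shared:n_peaks_a]
    b_only_starts = starts[n_peaks_a:]
    for i, s in enumerate(shared_starts):
        peaks_a.append(GenomicInterval("chr1", int(s), int(s + peak_width),
                                       name=f"pkA{i:04d}"))
        labels_a.append("shared")
        jitter = int(rng.integers(-(peak_width - 1), peak_width))
        bs = max(0, int(s) + jitter)
        peaks_b.append(GenomicInterval("chr1", bs, bs + peak_width,
                                       name=f"pkB{i:04d}"))
        labels_b.append("shared")
    for i, s in enumerate(a_only_starts):
        peaks_a.append(GenomicInterval("chr1", int(s), int(s + peak_width),
                                       name=f"pkA{n_shared + i:04d}"))
        labels_a.append("A-specific")
    for i, s in enumerate(b_only_starts):
        peaks_b.append(GenomicInterval("chr1", int(s), int(s + peak_width),
                                       name=f"pkB{n_shared + i:04d}"))
        labels_b.append("B-specific")
    truth = {"a": labels_a, "b": labels_b}
    return tss, peaks_a, peaks_b, truth


# ---------------------------------------------------------------------------
# single-cell experiment


@dataclass(frozen=True)
class ScSimSpec:
    n_clusters: int = 8
    cells_per_library: int = 2000
    n_genes: int = 300
    nb_mean: float = 5.0
    nb_dispersion: float = 2.0
    marker_genes_per_cluster: int = 5
    marker_effect: float = 4.0
    proportion_shift: dict = field(default_factory=dict)
    qc_fail_fraction: float = 0.0
    mito_gene_fraction: float = 0.05
    umi_cutoff: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not 0 <= self.qc_fail_fraction <= 1:
            raise ValueError("qc_fail_fraction must lie in [0, 1]")


def _cluster_proportions_for(spec: ScSimSpec, genotype_idx: int) -> np.ndarray:
    """Full proportion vector: pinned clusters from proportion_shift, the
    remaining probability mass split equally over unpinned clusters."""
    clusters = [f"c{i + 1}" for i in range(spec.n_clusters)]
    props = np.full(spec.n_clusters, np.nan)
    for name, pair in spec.proportion_shift.items():
        if name not in clusters:
            raise ValueError(f"unknown cluster {name!r} in proportion_shift")
        props[clusters.index(name)] = pair[genotype_idx]
    pinned = np.nansum(props)
    if pinned > 1 + 1e-9:
        raise ValueError("pinned cluster proportions exceed 1")
    free = np.isnan(props)
    if free.any():
        props[free] = (1 - pinned) / free.sum()
    if abs(props.sum() - 1) > 1e-9:
        raise ValueError("cluster proportions do not sum to 1")
    return props


def simulate_single_cell_experiment(spec: ScSimSpec) -> CellExperiment:
    """Two-genotype clustered negative-binomial counts with planted truth.

    Counts are gamma-Poisson with per-gene mean ``nb_mean`` (markers of the
    cell's cluster multiplied by ``marker_effect``) and dispersion
    ``nb_dispersion``. Cluster assignment per genotype follows the
    proportion vectors derived from ``proportion_shift``. A
    ``qc_fail_fraction`` of cells is planted as QC failures, split evenly
    between low-depth cells (mean scaled so the expected UMI total sits at
    half the cutoff) and high-mitochondrial cells (mitochondrial means
    boosted to ~30% of reads). Truth lives in the metadata: cell_meta
    columns cluster / qc_fail_planted / qc_fail_mode, gene_meta columns
    is_mito / marker_cluster.
    """
    rng = component_rng(spec.seed, "sc")
    n_mito = max(1, int(round(spec.mito_gene_fraction * spec.n_genes)))
    gene_ids = [f"mt-gene{i:04d}" for i in range(n_mito)] + \
               [f"gene{i:04d}" for i in range(spec.n_genes - n_mito)]
    is_mito = np.array([g.startswith("mt-") for g in gene_ids])
    clusters = [f"c{i + 1}" for i in range(spec.n_clusters)]

    marker_cluster = np.array([""] * spec.n_genes, dtype=object)
    non_mito_idx = np.flatnonzero(~is_mito)
    needed = spec.marker_genes_per_cluster * spec.n_clusters
    if needed > len(non_mito_idx):
        raise ValueError("not enough non-mitochondrial genes for markers")
    for ci, cluster in enumerate(clusters):
        block = non_mito_idx[ci * spec.marker_genes_per_cluster:
                             (ci + 1) * spec.marker_genes_per_cluster]
        marker_cluster[block] = cluster

    metas = []
    blocks = []
    for gi, genotype in enumerate(("WT", "KO")):
        props = _cluster_proportions_for(spec, gi)
        assignment = rng.choice(spec.n_clusters, size=spec.cells_per_library, p=props)
        n_cells = spec.cells_per_library
        mu = np.full((spec.n_genes, n_cells), spec.nb_mean)
        for ci, cluster in enumerate(clusters):
            in_cluster = assignment == ci
            marker_rows = marker_cluster == cluster
            mu[np.ix_(marker_rows, in_cluster)] *= spec.marker_effect

        qc_fail = np.zeros(n_cells, dtype=bool)
        qc_mode = np.array([""] * n_cells, dtype=object)
        n_fail = int(round(spec.qc_fail_fraction * n_cells))
        if n_fail:
            fail_idx = rng.choice(n_cells, size=n_fail, replace=False)
            half = n_fail // 2
            low_umi = fail_idx[:half + n_fail % 2]
            high_mito = fail_idx[half + n_fail % 2:]
            expected_umi = mu[:, low_umi].sum(axis=0)
            mu[:, low_umi] *= 0.5 * spec.umi_cutoff / expected_umi
            mito_boost = 0.3 / max(is_mito.mean(), 1e-9)
            mu[np.ix_(is_mito, high_mito)] *= mito_boost
            qc_fail[fail_idx] = True
            qc_mode[low_umi] = "low_umi"
            qc_mode[high_mito] = "high_mito"

        lam = rng.gamma(shape=spec.nb_dispersion,
                        scale=mu / spec.nb_dispersion)
        blocks.append(rng.poisson(lam))
        metas.append(pd.DataFrame({
            "library_id": f"{genotype}_1",
            "genotype": genotype,
            "cluster": [clusters[a] for a in assignment],
            "qc_fail_planted": qc_fail,
            "qc_fail_mode": qc_mode,
        }))

    counts = np.concatenate(blocks, axis=1)
    cell_meta = pd.concat(metas, ignore_index=True)
    gene_meta = pd.DataFrame({
        "gene_id": gene_ids,
        "is_mito": is_mito,
        "marker_cluster": marker_cluster,
    })
    return CellExperiment(counts, cell_meta, gene_meta)


# ---------------------------------------------------------------------------
# pseudobulk atlas

MAJOR_BRAIN_TYPES = [
    "Astrocytes", "ChoroidPlexus", "EndothelialMural", "Ependymal",
    "MicrogliaMacrophages", "Mitotic", "Neurogenesis", "Neurons",
    "Oligodendrocytes",
]


@dataclass(frozen=True)
class AtlasSimSpec:
    n_celltypes: int = 9
    n_genes: int = 2000
    baseline_log_expr: float = 2.0
    noise_sd: float = 0.5
    planted_set_size: int = 77
    planted_celltype: str = "Neurons"
    planted_shift: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_set_size > self.n_genes:
            raise ValueError("planted_set_size exceeds n_genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def simulate_atlas(spec: AtlasSimSpec):
    """Cell-type × gene aggregated atlas with one planted enrichment.

    Entries are baseline + Normal(0, noise_sd) on the aggregated log-like
    scale; ``planted_set_size`` genes get +``planted_shift`` only in
    ``planted_celltype``. Returns (AtlasMatrix, planted GeneSet).
    """
    from .enrich import AtlasMatrix

    rng = component_rng(spec.seed, "atlas")
    if spec.n_celltypes <= len(MAJOR_BRAIN_TYPES):
        celltypes = MAJOR_BRAIN_TYPES[:spec.n_celltypes]
    else:
        celltypes = MAJOR_BRAIN_TYPES + [
            f"type{i}" for i in range(spec.n_celltypes - len(MAJOR_BRAIN_TYPES))]
    if spec.planted_celltype not in celltypes:
        raise ValueError(f"planted_celltype {spec.planted_celltype!r} not present")
    genes = [f"gene{i:05d}" for i in range(spec.n_genes)]
    values = spec.baseline_log_expr + rng.normal(
        0.0, spec.noise_sd, size=(spec.n_celltypes, spec.n_genes))
    planted_idx = rng.choice(spec.n_genes, size=spec.planted_set_size,
                             replace=False)
    row = celltypes.index(spec.planted_celltype)
    values[row, planted_idx] += spec.planted_shift
    atlas = AtlasMatrix(pd.DataFrame(values, index=celltypes, columns=genes))
    planted = GeneSet("planted_set",
                      frozenset(genes[i] for i in planted_idx),
                      f"genes shifted +{spec.planted_shift} in "
                      f"{spec.planted_celltype}")
    return atlas, planted


# ---------------------------------------------------------------------------
# nosology groups and ortholog map


def simulate_nosology_and_orthologs(
    n_groups: int = 10,
    genes_per_group: int = 20,
    n_marker: int = 40,
    planted_overlap: int = 10,
    seed: int = 0,
):
    """Disease groups, a mouse→human ortholog map and a marker set.

    Groups are disjoint over human symbols; the ortholog map is one-to-one
    on group genes (mouse symbol = title-cased human symbol) plus
    many-to-many distractor pairs. The (mouse) marker set shares exactly
    ``planted_overlap`` orthologs with group 1; the remaining markers map
    half to non-group-1 nosology genes (random) and half outside the
    nosology universe. Returns (NosologyGroups, ortholog pair set,
    markers GeneSet).
    """
    from .enrich import NosologyGroups

    if planted_overlap > min(genes_per_group, n_marker):
        raise ValueError("planted_overlap exceeds group or marker size")
    rng = component_rng(seed, "nosology")
    groups: dict[str, frozenset[str]] = {}
    human_genes: list[str] = []
    for g in range(n_groups):
        members = [f"GRP{g + 1:02d}G{i:03d}" for i in range(genes_per_group)]
        groups[f"group{g + 1:02d}"] = frozenset(members)
        human_genes.extend(members)
    outside = [f"OUT{i:04d}" for i in range(max(n_marker, 20))]

    def mouse_of(human: str) -> str:
        return human.capitalize()

    pairs = {(mouse_of(h), h) for h in human_genes + outside}
    # distractor many-to-many pairs on symbols never used as markers
    for i in range(5):
        pairs.add((f"Multi{i}", f"MULTI{i}A"))
        pairs.add((f"Multi{i}", f"MULTI{i}B"))

    group1 = sorted(groups["group01"])
    overlap_humans = [group1[i] for i in
                      rng.choice(genes_per_group, size=planted_overlap,
                                 replace=False)]
    n_rest = n_marker - planted_overlap
    non_group1 = sorted(set(human_genes) - set(group1))
    n_in_universe = n_rest // 2
    rest_humans = list(rng.choice(non_group1, size=min(n_in_universe,
                                                       len(non_group1)),
                                  replace=False))
    rest_humans += outside[:n_rest - len(rest_humans)]
    markers = GeneSet(
        "planted_markers",
        frozenset(mouse_of(h) for h in overlap_humans + rest_humans),
        "mouse markers sharing planted_overlap orthologs with group01",
    )
    return NosologyGroups(groups), pairs, markers


# ---------------------------------------------------------------------------
# morphology wells


def simulate_morphology_wells(
    n_conditions: int = 5,
    replicates_per_condition: int = 6,
    n_features: int = 200,
    n_cells_per_well: int = 50,
    treatment_effect: float = 1.0,
    include_blocklist_names: bool = False,
    n_missing_features: int = 2,
    n_lowvar_features: int = 2,
    n_outlier_features: int = 2,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Single-cell morphology feature table with planted structure.

    Per-cell features ~ Normal(condition mean, 1); condition means are
    per-condition effect vectors (N(0,1) per feature) scaled by
    ``treatment_effect``, and the last two conditions share one effect
    vector — the planted similar pair. With ``treatment_effect=0`` all
    conditions coincide and profile correlations are pure noise. When
    flagged, extra features named to match the manual blocklist are
    appended, as are features carrying missing values, near-zero variance
    or extreme outliers to exercise every selection rule. Returns
    (cells table, truth dict with the planted pair and injected feature
    names).
    """
    if n_features < 10:
        raise ValueError("n_features must be >= 10")
    if n_conditions < 3:
        raise ValueError("need at least 3 conditions to plant a similar pair")
    rng = component_rng(seed, "wells")
    conditions = [f"cond{i + 1:02d}" for i in range(n_conditions)]
    feature_names = [f"Cells_Feature_{i + 1:04d}" for i in range(n_features)]

    effects = rng.normal(0.0, 1.0, size=(n_conditions, n_features))
    effects[-1] = effects[-2]  # planted similar pair
    means = treatment_effect * effects

    rows = []
    meta_rows = []
    well_counter = 0
    for ci, cond in enumerate(conditions):
        for rep in range(replicates_per_condition):
            well = f"{chr(ord('A') + ci)}{rep + 1:02d}"
            cells = means[ci] + rng.normal(0.0, 1.0,
                                           size=(n_cells_per_well, n_features))
            rows.append(cells)
            meta_rows.extend(
                {"Metadata_plate": "P1", "Metadata_well": well,
                 "Metadata_condition": cond,
                 "Metadata_cell_background": "MC3T3_WT",
                 "Metadata_replicate": rep + 1}
                for _ in range(n_cells_per_well))
            well_counter += 1

    data = np.concatenate(rows, axis=0)
    table = pd.concat(
        [pd.DataFrame(meta_rows), pd.DataFrame(data, columns=feature_names)],
        axis=1)

    truth: dict = {
        "similar_pair": (conditions[-2], conditions[-1]),
        "blocklist_features": [],
        "missing_features": [],
        "lowvar_features": [],
        "outlier_features": [],
    }
    n_cells_total = len(table)

    if include_blocklist_names:
        blocked = ["Cells_Granularity_14_Mito", "Cells_Granularity_15_Mito",
                   "Cells_Granularity_16_Mito", "Cells_Correlation_Manders_DNA",
                   "Cells_Correlation_Costes_AGP", "Cells_Correlation_RWC_Mito"]
        for name in blocked:
            table[name] = rng.normal(0.0, 1.0, size=n_cells_total)
        truth["blocklist_features"] = blocked
    n_wells = well_counter
    for i in range(n_missing_features):
        name = f"Cells_Missing_{i + 1:02d}"
        col = rng.normal(0.0, 1.0, size=n_cells_total)
        # blank a whole well so the missing value survives well aggregation
        w = int(rng.integers(n_wells))
        col[w * n_cells_per_well:(w + 1) * n_cells_per_well] = np.nan
        table[name] = col
        truth["missing_features"].append(name)
    for i in range(n_lowvar_features):
        # exactly constant: degenerate in-stratum, NaN-ed by normalization
        name = f"Cells_LowVar_{i + 1:02d}"
        table[name] = 3.0
        truth["lowvar_features"].append(name)
    for i in range(n_outlier_features):
        name = f"Cells_Outlier_{i + 1:02d}"
        col = rng.normal(0.0, 1.0, size=n_cells_total)
        col[rng.integers(n_cells_total)] = 1e4
        table[name] = col
        truth["outlier_features"].append(name)
    return table, truth
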