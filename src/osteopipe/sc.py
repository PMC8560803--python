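"""Downstream single-cell statistics: QC, downsampling, markers, proportions.

Operates on a :class:`CellExperiment` (gene × cell integer counts plus
per-cell metadata with library, genotype and cluster labels). Clustering
itself is consumed as given labels, never computed here. The statistical
pieces are: UMI / mitochondrial-fraction QC filtering, library
downsampling, one-vs-rest Wilcoxon rank-sum marker ranking on
ln(1 + CP10K)-normalized expression, per-cluster 2×2 contingency
construction, and Barnard's unconditional exact test (pooled-z score
statistic, nuisance parameter maximized over a dense grid with local
refinement) for genotype differences in cluster proportions.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._stats import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "CellExperiment",
    "Contingency2x2",
    "BarnardResult",
    "qc_filter_cells",
    "downsample_to_match",
    "rank_markers",
    "top_markers",
    "cluster_proportions",
    "barnard_exact_test",
]

CELL_META_COLUMNS = ["library_id", "genotype", "cluster"]


@dataclass
class CellExperiment:
    """Gene × cell count matrix with cell and gene metadata.

    ``umi_total`` and ``mito_fraction`` are always recomputed from the
    counts (never trusted from input metadata). ``gene_meta`` must carry a
    boolean ``is_mito`` column; ``cell_meta`` must carry library_id,
    genotype and cluster.
    """

    counts: np.ndarray
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D gene × cell matrix")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        n_genes, n_cells = counts.shape
        if len(self.gene_meta) != n_genes or len(self.cell_meta) != n_cells:
            raise ValueError("metadata dimensions do not match counts")
        missing = set(CELL_META_COLUMNS) - set(self.cell_meta.columns)
        if missing:
            raise ValueError(f"cell_meta missing columns {sorted(missing)}")
        if "is_mito" not in self.gene_meta.columns:
            raise ValueError("gene_meta must have an is_mito column")
        self.counts = counts
        meta = self.cell_meta.copy()
        umi = counts.sum(axis=0)
        mito = counts[self.gene_meta["is_mito"].to_numpy(bool)].sum(axis=0)
        meta["umi_total"] = umi
        with np.errstate(invalid="ignore", divide="ignore"):
            meta["mito_fraction"] = np.where(umi > 0, mito / np.maximum(umi, 1), 0.0)
        self.cell_meta = meta.reset_index(drop=True)
        self.gene_meta = self.gene_meta.reset_index(drop=True)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, mask: np.ndarray) -> "CellExperiment":
        return CellExperiment(self.counts[:, mask],
                             self.cell_meta.loc[np.asarray(mask)].copy(),
                             self.gene_meta.copy())

    def to_anndata(self):
        """Cells × genes AnnData view (the orientation scanpy expects)."""
        import anndata

        obs = self.cell_meta.copy()
        obs.index = obs.index.astype(str)
        var = self.gene_meta.copy()
        if "gene_id" in var.columns:
            var = var.set_index("gene_id", drop=False)
        var.index = var.index.astype(str)
        return anndata.AnnData(X=self.counts.T.astype(np.float32), obs=obs, var=var)

    @classmethod
    def from_anndata(cls, adata) -> "CellExperiment":
        X = adata.X
        X = X.toarray() if hasattr(X, "toarray") else np.asarray(X)
        gene_meta = adata.var.reset_index(drop="gene_id" in adata.var.columns)
        if "gene_id" not in gene_meta.columns:
            gene_meta["gene_id"] = adata.var_names.to_numpy()
        return cls(X.T, adata.obs.reset_index(drop=True), gene_meta)


@dataclass(frozen=True)
class Contingency2x2:
    """(in-cluster, total) cell counts for the two genotypes."""

    x1: int
    n1: int
    x2: int
    n2: int

    def __post_init__(self) -> None:
        if not (0 <= self.x1 <= self.n1 and 0 <= self.x2 <= self.n2):
            raise ValueError("require 0 <= x_i <= n_i")
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("group totals must be positive")


@dataclass(frozen=True)
class BarnardResult:
    statistic: float
    pvalue: float
    nuisance_argmax: float
    method: str = "pooled-z"


# ---------------------------------------------------------------------------
# QC and downsampling


def qc_filter_cells(exp: CellExperiment, umi_cutoff: int = 1000,
                    mito_cutoff: float = 0.10) -> CellExperiment:
    """Keep cells with umi_total >= cutoff AND mito_fraction <= cutoff.

    Both boundaries keep the cell (cells are removed when the
    mitochondrial fraction is strictly *greater* than the cutoff).
    """
    meta = exp.cell_meta
    keep = ((meta["umi_total"].to_numpy() >= umi_cutoff)
            & (meta["mito_fraction"].to_numpy() <= mito_cutoff))
    if not keep.any():
        raise ValueError("QC filter removed every cell")
    removed = meta.loc[~keep].groupby("library_id").size()
    for lib, n in removed.items():
        logger.info("qc_filter_cells: removed %d cells from library %s", n, lib)
    return exp.subset_cells(keep)


def downsample_to_match(exp: CellExperiment, reference_library: str,
                        target_library: str, mode: str = "total-cells",
                        seed: int = 0) -> CellExperiment:
    """Subsample the reference library to the target library's cellularity.

    ``mode='total-cells'`` matches total cell number; ``mode='per-cluster'``
    matches each cluster's count. Sampling is without replacement and
    deterministic under ``seed``. Cells of other libraries pass through.
    """
    if mode not in ("total-cells", "per-cluster"):
        raise ValueError(f"unknown mode {mode!r}")
    meta = exp.cell_meta
    for lib in (reference_library, target_library):
        if lib not in set(meta["library_id"]):
            raise ValueError(f"library {lib!r} not present")
    rng = np.random.default_rng(seed)
    ref_idx = np.flatnonzero(meta["library_id"].to_numpy() == reference_library)
    keep = np.ones(exp.n_cells, dtype=bool)
    if mode == "total-cells":
        n_target = int((meta["library_id"] == target_library).sum())
        if n_target > len(ref_idx):
            raise ValueError(
                f"target library larger than reference ({n_target} > {len(ref_idx)})")
        chosen = rng.choice(ref_idx, size=n_target, replace=False)
        keep[ref_idx] = False
        keep[np.sort(chosen)] = True
    else:
        target_counts = (meta.loc[meta["library_id"] == target_library]
                         .groupby("cluster", observed=True).size())
        short = []
        keep[ref_idx] = False
        for cluster, n_target in target_counts.items():
            stratum = ref_idx[meta.loc[ref_idx, "cluster"].to_numpy() == cluster]
            if n_target > len(stratum):
                short.append(str(cluster))
                continue
            chosen = rng.choice(stratum, size=int(n_target), replace=False)
            keep[np.sort(chosen)] = True
        if short:
            raise ValueError("target exceeds reference in strata: " + ", ".join(short))
    return exp.subset_cells(keep)


# ---------------------------------------------------------------------------
# marker ranking


def _log_normalize(counts: np.ndarray) -> np.ndarray:
    """ln(1 + 1e4 · count / umi_total) per cell."""
    umi = counts.sum(axis=0).astype(float)
    umi[umi == 0] = 1.0
    return np.log1p(1e4 * counts / umi)


def _exact_ranksum_pvalue(in_vals: np.ndarray, out_vals: np.ndarray) -> float:
    """Two-sided exact rank-sum p by full enumeration (midranks for ties).

    p = P(|T − μ| >= |T_obs − μ|) over all C(n1+n2, n1) assignments of the
    pooled midranks to the in-group, where μ is the permutation mean.
    """
    pooled = np.concatenate([in_vals, out_vals])
    ranks = stats.rankdata(pooled)
    n1 = len(in_vals)
    t_obs = ranks[:n1].sum()
    mu = n1 * ranks.mean()
    d_obs = abs(t_obs - mu)
    total = 0
    hits = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(ranks[list(combo)].sum() - mu) >= d_obs - 1e-9:
            hits += 1
    return hits / total


def _asymptotic_ranksum_pvalues(X_in: np.ndarray, X_out: np.ndarray) -> np.ndarray:
    """Vectorized two-sided tie-corrected normal-approximation rank-sum.

    X_in: genes × n1 values, X_out: genes × n2. Continuity correction 0.5.
    """
    n1, n2 = X_in.shape[1], X_out.shape[1]
    n = n1 + n2
    pooled = np.concatenate([X_in, X_out], axis=1)
    ranks = stats.rankdata(pooled, axis=1)
    T = ranks[:, :n1].sum(axis=1)
    mu = n1 * (n + 1) / 2.0
    # tie correction: sum of (t^3 - t) over tie groups, per gene
    sorted_vals = np.sort(pooled, axis=1)
    tie_term = np.zeros(pooled.shape[0])
    for g in range(pooled.shape[0]):
        _, counts = np.unique(sorted_vals[g], return_counts=True)
        tie_term[g] = np.sum(counts.astype(float) ** 3 - counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    p = np.ones(pooled.shape[0])
    ok = var > 0
    d = np.abs(T - mu) - 0.5  # continuity correction
    d = np.maximum(d, 0.0)
    z = np.zeros_like(p)
    z[ok] = d[ok] / np.sqrt(var[ok])
    p[ok] = 2 * stats.norm.sf(z[ok])
    return np.minimum(p, 1.0)


def rank_markers(exp: CellExperiment, grouping: str = "cluster",
                 equalize_per_library: bool = False, seed: int = 0,
                 exact_max_n: int = 10) -> pd.DataFrame:
    """Wilcoxon rank-sum marker statistics.

    ``grouping='cluster'``: one-vs-rest per cluster. ``grouping='genotype'``:
    genotype contrast within each cluster. Expression is normalized as
    ln(1 + 1e4·count/umi); logfc is the difference of normalized-expression
    means (in-group − out-group); pct_in/pct_out are expressing-cell
    fractions; BH FDR is computed across genes within each group. The test
    is two-sided with tie correction and continuity correction; when both
    groups have <= ``exact_max_n`` cells the exact permutation distribution
    is enumerated instead. Genes constant across all cells get p = 1.
    ``equalize_per_library=True`` subsamples both sides to the smaller
    group size (seeded) before testing.
    """
    if grouping not in ("cluster", "genotype"):
        raise ValueError(f"unknown grouping {grouping!r}")
    norm = _log_normalize(exp.counts.astype(float))
    meta = exp.cell_meta
    rng = np.random.default_rng(seed)

    contrasts: list[tuple[str, np.ndarray, np.ndarray]] = []
    if grouping == "cluster":
        for cluster in sorted(meta["cluster"].unique(), key=str):
            in_mask = (meta["cluster"] == cluster).to_numpy()
            contrasts.append((str(cluster), in_mask, ~in_mask))
    else:
        genotypes = sorted(meta["genotype"].unique(), key=str)
        if len(genotypes) != 2:
            raise ValueError("genotype grouping requires exactly two genotypes")
        g1, g2 = genotypes
        for cluster in sorted(meta["cluster"].unique(), key=str):
            base = (meta["cluster"] == cluster).to_numpy()
            contrasts.append((str(cluster),
                              base & (meta["genotype"] == g1).to_numpy(),
                              base & (meta["genotype"] == g2).to_numpy()))

    records = []
    gene_ids = (exp.gene_meta["gene_id"].to_numpy()
                if "gene_id" in exp.gene_meta.columns
                else np.array([f"g{i}" for i in range(exp.n_genes)]))
    for group, in_mask, out_mask in contrasts:
        idx_in = np.flatnonzero(in_mask)
        idx_out = np.flatnonzero(out_mask)
        if equalize_per_library:
            k = min(len(idx_in), len(idx_out))
            idx_in = np.sort(rng.choice(idx_in, size=k, replace=False))
            idx_out = np.sort(rng.choice(idx_out, size=k, replace=False))
        if len(idx_in) < 2 or len(idx_out) < 2:
            raise ValueError(f"group {group!r}: fewer than 2 cells per side")
        X_in = norm[:, idx_in]
        X_out = norm[:, idx_out]
        # constancy is judged on raw counts: CP10K normalization makes a
        # constant-count gene vary with library size, but it carries no
        # per-gene signal, so p = 1 and logfc = 0 by convention
        raw = exp.counts[:, np.concatenate([idx_in, idx_out])]
        constant = (raw.min(axis=1) == raw.max(axis=1))
        if max(len(idx_in), len(idx_out)) <= exact_max_n:
            pvals = np.array([
                _exact_ranksum_pvalue(X_in[g], X_out[g])
                for g in range(exp.n_genes)
            ])
        else:
            pvals = _asymptotic_ranksum_pvalues(X_in, X_out)
        logfc = X_in.mean(axis=1) - X_out.mean(axis=1)
        if constant.any():
            pvals[constant] = 1.0
            logfc[constant] = 0.0
            logger.info("rank_markers[%s]: %d constant genes -> p=1",
                        group, int(constant.sum()))
        pct_in = (exp.counts[:, idx_in] > 0).mean(axis=1)
        pct_out = (exp.counts[:, idx_out] > 0).mean(axis=1)
        records.append(pd.DataFrame({
            "gene_id": gene_ids,
            "cluster": group,
            "pvalue": pvals,
            "fdr": bh_adjust(pvals),
            "logfc": logfc,
            "pct_in": pct_in,
            "pct_out": pct_out,
            "pct_diff": pct_in - pct_out,
        }))
    return pd.concat(records, ignore_index=True)


def top_markers(markers: pd.DataFrame, k: int, by: str = "pvalue",
                cluster: str | None = None) -> pd.DataFrame:
    """Top-k marker extraction; ``by`` is 'pvalue' (ascending) or 'pct_diff'
    (descending), the two ranking keys used downstream (top 150 by p for
    atlas enrichment, top 400 by percentage difference for nosology)."""
    if by not in ("pvalue", "pct_diff"):
        raise ValueError(f"unknown ranking key {by!r}")
    df = markers if cluster is None else markers[markers["cluster"] == str(cluster)]
    ascending = by == "pvalue"
    return (df.sort_values([by, "gene_id"], ascending=[ascending, True])
            .head(k).reset_index(drop=True))


# ---------------------------------------------------------------------------
# proportions and Barnard's unconditional exact test


def cluster_proportions(exp: CellExperiment) -> tuple[pd.DataFrame,
                                                      dict[str, Contingency2x2]]:
    """Per-library cluster proportions and per-cluster genotype 2×2 tables.

    Proportions divide in-cluster cells by the library total (they sum to 1
    per library). Contingency tables pool libraries within genotype
    (genotype order = sorted labels) and require exactly two genotypes.
    """
    meta = exp.cell_meta
    counts = (meta.groupby(["library_id", "cluster"], observed=True).size()
              .unstack(fill_value=0))
    proportions = counts.div(counts.sum(axis=1), axis=0)

    genotypes = sorted(meta["genotype"].unique(), key=str)
    tables: dict[str, Contingency2x2] = {}
    if len(genotypes) == 2:
        g1, g2 = genotypes
        n1 = int((meta["genotype"] == g1).sum())
        n2 = int((meta["genotype"] == g2).sum())
        for cluster in counts.columns:
            in_cluster = meta["cluster"] == cluster
            tables[str(cluster)] = Contingency2x2(
                x1=int((in_cluster & (meta["genotype"] == g1)).sum()), n1=n1,
                x2=int((in_cluster & (meta["genotype"] == g2)).sum()), n2=n2,
            )
    else:
        logger.warning("cluster_proportions: %d genotypes present; contingency "
                       "tables need exactly 2", len(genotypes))
    return proportions, tables


def _pooled_z(x1, n1, x2, n2):
    """Pooled-variance score statistic; 0 where the pooled variance vanishes."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    p1 = x1 / n1
    p2 = x2 / n2
    pp = (x1 + x2) / (n1 + n2)
    var = pp * (1 - pp) * (1 / n1 + 1 / n2)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var > 0, (p1 - p2) / np.sqrt(np.where(var > 0, var, 1.0)), 0.0)
    return z


_TRUNC_SIGMAS = 10.0  # excluded binomial mass < 1.5e-23 per side


def _binom_pmf_block(idx: np.ndarray, n: int, pis: np.ndarray,
                     log_comb: np.ndarray) -> np.ndarray:
    """pmf(idx; n, π) for a π vector, via exp(log C + x·logπ + (n−x)·log1mπ)."""
    with np.errstate(divide="ignore"):
        logpi = np.log(pis)[:, None]
        log1m = np.log1p(-pis)[:, None]
    logp = log_comb[idx][None, :] + idx[None, :] * logpi + (n - idx[None, :]) * log1m
    return np.exp(logp)


def _tail_on_grid(extreme: np.ndarray, n1: int, n2: int,
                  pis: np.ndarray) -> np.ndarray:
    """P_π(extreme region) for each nuisance π, truncating each binomial to
    ±10σ around its mean per π-chunk (truncation error < 1e-20)."""
    from scipy.special import gammaln

    out = np.empty(len(pis))
    chunk = 128
    lc1 = gammaln(n1 + 1) - gammaln(np.arange(n1 + 1) + 1) \
        - gammaln(n1 - np.arange(n1 + 1) + 1)
    lc2 = gammaln(n2 + 1) - gammaln(np.arange(n2 + 1) + 1) \
        - gammaln(n2 - np.arange(n2 + 1) + 1)
    for lo in range(0, len(pis), chunk):
        pi = pis[lo:lo + chunk]
        pi_lo, pi_hi = pi[0], pi[-1]

        def rng_for(n):
            sd_hi = math.sqrt(n * 0.25)
            a = max(0, int(n * pi_lo - _TRUNC_SIGMAS * sd_hi) - 1)
            b = min(n, int(n * pi_hi + _TRUNC_SIGMAS * sd_hi) + 1)
            return np.arange(a, b + 1)

        i1 = rng_for(n1)
        i2 = rng_for(n2)
        B1 = _binom_pmf_block(i1, n1, pi, lc1)
        B2 = _binom_pmf_block(i2, n2, pi, lc2)
        E = extreme[np.ix_(i1, i2)].astype(float)
        out[lo:lo + chunk] = ((B1 @ E) * B2).sum(axis=1)
    return out


def _tail_at(extreme: np.ndarray, n1: int, n2: int, pi: float) -> float:
    return float(_tail_on_grid(extreme, n1, n2, np.array([pi, pi]))[0])


def barnard_exact_test(t: Contingency2x2, alternative: str = "two-sided",
                       nuisance_grid: int = 9999) -> BarnardResult:
    """Barnard's unconditional exact test with the pooled-z score statistic.

    The p-value is the supremum over the common-proportion nuisance π of
    the probability of outcome pairs at least as extreme as observed
    (|z| ordering for two-sided; signed z for 'greater'/'less', where
    'greater' means the first group's proportion exceeds the second's).
    π is maximized over a uniform open grid of ``nuisance_grid`` points
    followed by bounded local refinement around the best grid candidates,
    which bounds the under-coverage of a pure grid maximum below ~1e-6.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n1, n2 = t.n1, t.n2
    xs1 = np.arange(n1 + 1)
    xs2 = np.arange(n2 + 1)
    Z = _pooled_z(xs1[:, None], n1, xs2[None, :], n2)
    z_obs = float(_pooled_z(t.x1, n1, t.x2, n2))
    eps = 1e-12
    if alternative == "two-sided":
        extreme = np.abs(Z) >= abs(z_obs) - eps
    elif alternative == "greater":
        extreme = Z >= z_obs - eps
    else:
        extreme = Z <= z_obs + eps

    pis = np.arange(1, nuisance_grid + 1) / (nuisance_grid + 1)
    tails = _tail_on_grid(extreme, n1, n2, pis)
    best = float(tails.max())
    order = np.argsort(tails)[::-1]
    h = 1.0 / (nuisance_grid + 1)
    argmax = float(pis[order[0]])
    # refine around the leading (well-separated) grid candidates
    seen: list[float] = []
    for idx in order[:8]:
        pi0 = float(pis[idx])
        if any(abs(pi0 - s) < 2.5 * h for s in seen):
            continue
        seen.append(pi0)
        if len(seen) > 3:
            break
        res = optimize.minimize_scalar(
            lambda pi: -_tail_at(extreme, n1, n2, pi),
            bounds=(max(pi0 - h, 1e-12), min(pi0 + h, 1 - 1e-12)),
            method="bounded", options={"xatol": 1e-12},
        )
        if -res.fun > best:
            best = float(-res.fun)
            argmax = float(res.x)
    return BarnardResult(statistic=z_obs, pvalue=min(1.0, best),
                         nuisance_argmax=argmax)
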