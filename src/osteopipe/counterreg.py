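"""Counter-regulation calling and stratified rank–rank hypergeometric overlap.

A gene is *counter-regulated* by two opposite perturbations (e.g. knockdown
vs overexpression of the same transcription factor) when it passes the FDR
threshold in both comparisons with opposite log2 fold-change signs. Global
rank concordance between the two comparisons is quantified by a rank–rank
hypergeometric overlap (RRHO) map: genes are ranked by the signed metric
−log10(p)·sign(log2FC) in each comparison, and for every pair of rank
thresholds the overlap between the two top lists is scored with a one-sided
hypergeometric enrichment tail. The stratified (RRHO2) variant restricts
threshold stepping to same-sign strata, with concordant quadrants stepped
from the list heads (up/up) and tails (down/down) and discordant quadrants
mixing a head with a tail, so that depletion artifacts of the original
algorithm cannot masquerade as discordance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import by_adjust, hypergeom_log10_sf
from .io import DETable, GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "filter_expressed",
    "select_significant",
    "classify_counter_regulation",
    "rrho_map",
    "RRHOGrid",
    "QuadrantMap",
]


def filter_expressed(
    table: DETable,
    sample_expr: pd.DataFrame,
    min_expr: float = 0.25,
    min_samples: int = 2,
    literal: bool = False,
) -> DETable:
    """Expression filter applied before differential-expression analysis.

    Standard reading (default): *keep* genes with expression >= ``min_expr``
    in at least ``min_samples`` samples. The source procedure is phrased as
    a double negative ("lower than 0.25 in less than two samples were
    removed"); ``literal=True`` applies that literal reading instead
    (remove genes whose count of samples below ``min_expr`` is smaller
    than ``min_samples``).
    """
    missing = table.genes.difference(sample_expr.index)
    if len(missing):
        raise ValueError(f"genes missing from expression matrix: {list(missing[:5])}")
    expr = sample_expr.loc[table.genes]
    if literal:
        keep = (expr < min_expr).sum(axis=1) >= min_samples
    else:
        keep = (expr >= min_expr).sum(axis=1) >= min_samples
    n_removed = int((~keep).sum())
    logger.info("filter_expressed: removed %d / %d genes (min_expr=%g, min_samples=%d)",
                n_removed, len(table), min_expr, min_samples)
    return DETable(table.comparison_label, table.records.loc[keep.to_numpy()])


def select_significant(
    table: DETable,
    fdr: float = 0.05,
    min_abs_log2fc: float | None = 1.0,
) -> GeneSet:
    """Genes with fdr < threshold and |log2fc| > cutoff (strict inequalities).

    ``min_abs_log2fc=None`` is the relaxed pass that keeps every gene below
    the FDR threshold regardless of effect size.
    """
    df = table.records
    mask = df["fdr"].to_numpy(float) < fdr
    if min_abs_log2fc is not None:
        mask &= np.abs(df["log2fc"].to_numpy(float)) > min_abs_log2fc
    lfc_part = "" if min_abs_log2fc is None else f",|lfc|>{min_abs_log2fc}"
    return GeneSet(
        name=f"{table.comparison_label}_sig(fdr<{fdr}{lfc_part})",
        genes=frozenset(df.index[mask]),
        description=f"significant genes of {table.comparison_label}",
    )


def classify_counter_regulation(
    table_a: DETable,
    table_b: DETable,
    fdr: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Classify every gene of the shared universe as counter/co/single/none.

    counter: significant in both tables with opposite log2fc signs;
    co: significant in both with equal signs; single: significant in
    exactly one; none: neither (or outside the shared universe). A
    doubly-significant gene with log2fc exactly 0 in either table has an
    undefined direction: it is excluded from both counter and co (status
    "none", warned, counted as ``n_excluded_zero_lfc``).

    Returns (calls, summary) where calls has one row per gene of the union
    with columns status/direction_a/direction_b and summary reports
    n_both, n_counter, n_co, n_excluded_zero_lfc and
    fraction_counter = n_counter / n_both.
    """
    shared = table_a.genes.intersection(table_b.genes)
    union = table_a.genes.union(table_b.genes)
    n_unshared = len(union) - len(shared)
    if n_unshared:
        logger.info("classify_counter_regulation: %d genes outside the shared "
                    "universe -> status 'none'", n_unshared)

    a = table_a.records.loc[shared]
    b = table_b.records.loc[shared]
    sig_a = a["fdr"].to_numpy(float) < fdr
    sig_b = b["fdr"].to_numpy(float) < fdr
    lfc_a = a["log2fc"].to_numpy(float)
    lfc_b = b["log2fc"].to_numpy(float)

    def direction(lfc: np.ndarray) -> np.ndarray:
        out = np.where(lfc > 0, "up", np.where(lfc < 0, "down", "flat"))
        return out

    both = sig_a & sig_b
    zero_lfc = both & ((lfc_a == 0) | (lfc_b == 0))
    counter = both & ~zero_lfc & (np.sign(lfc_a) != np.sign(lfc_b))
    co = both & ~zero_lfc & (np.sign(lfc_a) == np.sign(lfc_b))
    single = sig_a ^ sig_b

    if zero_lfc.any():
        logger.warning("classify_counter_regulation: %d doubly-significant genes "
                       "with log2fc == 0 excluded (direction undefined)",
                       int(zero_lfc.sum()))

    status = np.full(len(shared), "none", dtype=object)
    status[single] = "single"
    status[co] = "co"
    status[counter] = "counter"

    calls = pd.DataFrame(
        {
            "status": status,
            "direction_a": direction(lfc_a),
            "direction_b": direction(lfc_b),
        },
        index=shared,
    )
    outside = union.difference(shared)
    if len(outside):
        calls = pd.concat([
            calls,
            pd.DataFrame({"status": "none", "direction_a": "flat",
                          "direction_b": "flat"}, index=outside),
        ])
    calls.index.name = "gene_id"

    n_both = int(both.sum())
    summary = {
        "n_both": n_both,
        "n_counter": int(counter.sum()),
        "n_co": int(co.sum()),
        "n_excluded_zero_lfc": int(zero_lfc.sum()),
        "fraction_counter": float(counter.sum() / n_both) if n_both else float("nan"),
    }
    return calls, summary


# ---------------------------------------------------------------------------
# RRHO


@dataclass
class QuadrantMap:
    """One quadrant of the stratified overlap map.

    ``thresholds_a``/``thresholds_b`` count genes taken from the quadrant's
    end of each ranked list; ``overlap[i, j]`` is the observed intersection
    size, ``log10_p`` the signed −log10 one-sided hypergeometric enrichment
    p (negative where the overlap is below expectation), ``nominal_p`` the
    unsigned enrichment tail itself and ``adj_log10_p`` its magnitude after
    Benjamini–Yekutieli correction across the quadrant's cells.
    """

    name: str
    thresholds_a: np.ndarray
    thresholds_b: np.ndarray
    overlap: np.ndarray
    log10_p: np.ndarray
    nominal_p_log10: np.ndarray
    adj_log10_p: np.ndarray
    universe_size: int


@dataclass
class RRHOGrid:
    step: int
    universe_size: int
    thresholds_a: np.ndarray = field(repr=False, default=None)
    thresholds_b: np.ndarray = field(repr=False, default=None)
    overlap: np.ndarray = field(repr=False, default=None)
    log10_p: np.ndarray = field(repr=False, default=None)
    adj_log10_p: np.ndarray = field(repr=False, default=None)
    quadrants: dict[str, QuadrantMap] = field(default_factory=dict)


def _signed_metric(table: DETable) -> pd.Series:
    p = np.clip(table.records["pvalue"].to_numpy(float), 1e-300, None)
    lfc = table.records["log2fc"].to_numpy(float)
    return pd.Series(-np.log10(p) * np.sign(lfc), index=table.genes)


def _thresholds(n: int, step: int) -> np.ndarray:
    """step, 2·step, …, plus a trailing partial stratum when step ∤ n."""
    ts = list(range(step, n + 1, step))
    if not ts or ts[-1] != n:
        ts.append(n)
    return np.asarray(ts, dtype=int)


def _overlap_grid(pos_a: np.ndarray, pos_b: np.ndarray,
                  ts_a: np.ndarray, ts_b: np.ndarray) -> np.ndarray:
    """overlap[i, j] = #{genes with rank_a < ts_a[i] and rank_b < ts_b[j]}.

    Built as a 2-D cumulative histogram of (rank_a, rank_b) pairs.
    """
    bins_a = np.concatenate([[0], ts_a])
    bins_b = np.concatenate([[0], ts_b])
    hist, _, _ = np.histogram2d(pos_a, pos_b, bins=[bins_a, bins_b])
    return np.cumsum(np.cumsum(hist, axis=0), axis=1).astype(int)


def _score_grid(overlap: np.ndarray, ts_a: np.ndarray, ts_b: np.ndarray,
                N: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (signed log10 map, nominal log10 enrichment p per cell)."""
    log10_p = np.empty(overlap.shape)
    signed = np.empty(overlap.shape)
    for i, K in enumerate(ts_a):
        for j, n in enumerate(ts_b):
            k = int(overlap[i, j])
            lp = hypergeom_log10_sf(k, N, int(K), int(n))
            log10_p[i, j] = lp
            expected = K * n / N
            signed[i, j] = -lp if k >= expected else lp
    return signed, log10_p


def rrho_map(table_a: DETable, table_b: DETable, step: int = 200) -> RRHOGrid:
    """Stratified rank–rank hypergeometric overlap of two DE comparisons.

    Ranks the shared gene universe by −log10(p)·sign(log2fc) in each table
    (descending; ties broken by gene_id for determinism) and scores overlap
    at every threshold pair with the one-sided enrichment tail
    P(X >= k | N, K=i·step, n=j·step). The full-list grid and the four
    stratified quadrant maps (up-up, down-down, up-down, down-up) are
    returned; Benjamini–Yekutieli correction is applied within each family
    of cells (the full grid, and each quadrant separately).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    shared = table_a.genes.intersection(table_b.genes)
    N = len(shared)
    if N == 0:
        raise ValueError("empty shared gene universe")
    if N < 2 * step:
        logger.warning("rrho_map: universe (%d) smaller than 2*step (%d)", N, 2 * step)

    s_a = _signed_metric(DETable(table_a.comparison_label,
                                 table_a.records.loc[shared]))
    s_b = _signed_metric(DETable(table_b.comparison_label,
                                 table_b.records.loc[shared]))

    def ranking(s: pd.Series) -> pd.Index:
        # descending metric, gene_id lexicographic tie-break
        order = np.lexsort((s.index.to_numpy(), -s.to_numpy()))
        return s.index[order]

    order_a = ranking(s_a)
    order_b = ranking(s_b)
    rank_a = pd.Series(np.arange(N), index=order_a)
    rank_b = pd.Series(np.arange(N), index=order_b)

    grid = RRHOGrid(step=step, universe_size=N)

    ts = _thresholds(N, step)
    ov = _overlap_grid(rank_a.loc[shared].to_numpy(),
                       rank_b.loc[shared].to_numpy(), ts, ts)
    signed, log10_p = _score_grid(ov, ts, ts, N)
    adj = by_adjust(np.power(10.0, np.clip(log10_p, -300, 0)))
    grid.thresholds_a = ts
    grid.thresholds_b = ts
    grid.overlap = ov
    grid.log10_p = signed
    grid.adj_log10_p = -np.log10(np.clip(adj, 1e-300, None))

    # stratified quadrants: per-list strata split at the signed-metric zero
    # crossing; genes with metric exactly 0 belong to neither stratum but
    # stay in the universe N.
    up_a = order_a[s_a.loc[order_a].to_numpy() > 0]
    dn_a = order_a[s_a.loc[order_a].to_numpy() < 0][::-1]  # from the tail
    up_b = order_b[s_b.loc[order_b].to_numpy() > 0]
    dn_b = order_b[s_b.loc[order_b].to_numpy() < 0][::-1]

    for name, la, lb in (
        ("up_up", up_a, up_b),
        ("down_down", dn_a, dn_b),
        ("up_down", up_a, dn_b),
        ("down_up", dn_a, up_b),
    ):
        if len(la) == 0 or len(lb) == 0:
            continue
        ts_a = _thresholds(len(la), step)
        ts_b = _thresholds(len(lb), step)
        pa = pd.Series(np.arange(len(la)), index=la)
        pb = pd.Series(np.arange(len(lb)), index=lb)
        common = la.intersection(lb)
        if len(common):
            ovq = _overlap_grid(pa.loc[common].to_numpy(),
                                pb.loc[common].to_numpy(), ts_a, ts_b)
        else:
            ovq = np.zeros((len(ts_a), len(ts_b)), dtype=int)
        signed_q, log10_q = _score_grid(ovq, ts_a, ts_b, N)
        adj_q = by_adjust(np.power(10.0, np.clip(log10_q, -300, 0)))
        grid.quadrants[name] = QuadrantMap(
            name=name,
            thresholds_a=ts_a,
            thresholds_b=ts_b,
            overlap=ovq,
            log10_p=signed_q,
            nominal_p_log10=log10_q,
            adj_log10_p=-np.log10(np.clip(adj_q, 1e-300, None)),
            universe_size=N,
        )
    return grid


def plot_rrho(grid: RRHOGrid, path: str | None = None):
    """2×2 heatmap panel of the stratified quadrant maps (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = ["up_up", "up_down", "down_up", "down_down"]
    fig, axes = plt.subplots(2, 2, figsize=(8, 7))
    for ax, name in zip(axes.ravel(), order):
        q = grid.quadrants.get(name)
        if q is None:
            ax.set_axis_off()
            continue
        im = ax.imshow(q.log10_p, origin="lower", aspect="auto", cmap="RdBu_r")
        ax.set_title(name.replace("_", " / "))
        fig.colorbar(im, ax=ax, label="signed -log10 p")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
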