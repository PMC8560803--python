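"""Morphological-profile processing: aggregate, normalize, select, correlate.

Input is a single-cell (or well-level) feature table in the profiling
convention: metadata columns carry the ``Metadata_`` prefix (plate, well,
condition, cell_background, replicate), every other column is a numeric
feature. The chain is: per-well mean aggregation → robust z normalization
stratified by cell background (median / 1.4826·MAD) → ordered feature
selection (missing values, manual blocklist, low variance, extreme
outliers) → per-condition median collapse and Pearson similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "METADATA_PREFIX",
    "DEFAULT_BLOCKLIST",
    "SimilarityMatrix",
    "feature_columns",
    "aggregate_wells",
    "normalize_features",
    "select_features",
    "collapse_and_correlate",
]

METADATA_PREFIX = "Metadata_"

#: feature-name substrings removed manually: the high-order granularity
#: scales and the colocalization statistics are known noise sources.
DEFAULT_BLOCKLIST = ["Granularity_14", "Granularity_15", "Granularity_16",
                     "Manders", "Costes", "RWC"]

MAD_SCALE = 1.4826  # consistency factor: MAD → σ under normality


@dataclass
class SimilarityMatrix:
    labels: list[str]
    values: pd.DataFrame
    n_features_used: int

    def __post_init__(self) -> None:
        v = self.values.to_numpy(float)
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("similarity matrix must have unit diagonal")
        if (np.abs(v) > 1 + 1e-9).any():
            raise ValueError("correlations must lie in [-1, 1]")


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if not c.startswith(METADATA_PREFIX)]


def aggregate_wells(cells: pd.DataFrame) -> pd.DataFrame:
    """Mean per feature over the single cells of each (plate, well).

    Missing cell values are excluded from the mean; metadata is inherited
    from the well's cells (which must agree within a well).
    """
    feats = feature_columns(cells)
    meta_cols = [c for c in cells.columns if c.startswith(METADATA_PREFIX)]
    keys = [f"{METADATA_PREFIX}plate", f"{METADATA_PREFIX}well"]
    for key in keys:
        if key not in cells.columns:
            raise ValueError(f"missing metadata column {key}")
    grouped = cells.groupby(keys, sort=True, dropna=False)
    agg = grouped[feats].mean()
    meta = grouped[meta_cols].first()
    if (grouped.size() == 0).any():
        raise ValueError("well with zero cells")
    out = pd.concat([meta, agg], axis=1).reset_index(drop=True)
    return out[meta_cols + feats]


def normalize_features(
    wells: pd.DataFrame,
    stratify_by: str = f"{METADATA_PREFIX}cell_background",
    min_stratum_size: int = 3,
) -> pd.DataFrame:
    """Robust z per feature within each stratum: (x − median) / (1.4826·MAD).

    A zero MAD falls back to the standard deviation; if that is also zero
    the feature is degenerate in the stratum and its values are set to NaN
    so the missing-value rule of :func:`select_features` drops it.
    """
    if stratify_by not in wells.columns:
        raise ValueError(f"missing stratification column {stratify_by}")
    feats = feature_columns(wells)
    out = wells.copy()
    for stratum, idx in wells.groupby(stratify_by).groups.items():
        if len(idx) < min_stratum_size:
            raise ValueError(
                f"stratum {stratum!r} has {len(idx)} wells (< {min_stratum_size})")
        block = wells.loc[idx, feats].to_numpy(float)
        med = np.nanmedian(block, axis=0)
        mad = np.nanmedian(np.abs(block - med), axis=0) * MAD_SCALE
        sd = np.nanstd(block, axis=0, ddof=1)
        scale = np.where(mad > 0, mad, sd)
        degenerate = scale == 0
        scale = np.where(degenerate, 1.0, scale)
        normed = (block - med) / scale
        normed[:, degenerate] = np.nan
        if degenerate.any():
            logger.info("normalize_features[%s]: %d degenerate features",
                        stratum, int(degenerate.sum()))
        out.loc[idx, feats] = normed
    return out


def select_features(
    wells: pd.DataFrame,
    variance_floor: float = 1e-5,
    outlier_cutoff: float = 15.0,
    blocklist_patterns: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Ordered feature selection on normalized well profiles.

    Drops, in order: (1) features with any missing value; (2) features
    whose name contains a blocklist pattern (case-sensitive substring);
    (3) features with variance < ``variance_floor``; (4) features with any
    |value| > ``outlier_cutoff``. Returns the reduced table and a report
    mapping rule name → removed feature names.
    """
    if blocklist_patterns is None:
        blocklist_patterns = DEFAULT_BLOCKLIST
    feats = feature_columns(wells)
    report: dict[str, list[str]] = {
        "missing": [], "blocklist": [], "low_variance": [], "outlier": []}
    kept = list(feats)

    def drop(rule: str, names: list[str]) -> None:
        report[rule] = names
        for n in names:
            kept.remove(n)

    vals = wells[kept]
    drop("missing", [c for c in kept if vals[c].isna().any()])
    drop("blocklist", [c for c in kept
                       if any(pat in c for pat in blocklist_patterns)])
    variances = wells[kept].var(ddof=1)
    drop("low_variance", [c for c in kept if variances[c] < variance_floor])
    drop("outlier", [c for c in kept
                     if (wells[c].abs() > outlier_cutoff).any()])
    if not kept:
        raise ValueError("feature selection removed every feature")
    for rule, names in report.items():
        logger.info("select_features: %s removed %d", rule, len(names))
    meta_cols = [c for c in wells.columns if c.startswith(METADATA_PREFIX)]
    return wells[meta_cols + kept], report


def collapse_and_correlate(
    wells: pd.DataFrame,
    condition_key: str = f"{METADATA_PREFIX}condition",
) -> SimilarityMatrix:
    """Median-collapse replicate wells per condition; Pearson-correlate.

    Features constant across all collapsed conditions are excluded from the
    correlation with a warning. The matrix is exactly symmetrized and the
    diagonal set to 1.
    """
    if condition_key not in wells.columns:
        raise ValueError(f"missing condition column {condition_key}")
    feats = feature_columns(wells)
    collapsed = wells.groupby(condition_key, sort=True)[feats].median()
    if len(collapsed) < 2:
        raise ValueError("need at least 2 conditions")
    constant = collapsed.nunique() <= 1
    if constant.any():
        logger.warning("collapse_and_correlate: %d features constant across "
                       "conditions excluded", int(constant.sum()))
        collapsed = collapsed.loc[:, ~constant]
    mat = np.corrcoef(collapsed.to_numpy(float))
    mat = (mat + mat.T) / 2.0
    np.fill_diagonal(mat, 1.0)
    mat = np.clip(mat, -1.0, 1.0)
    labels = [str(c) for c in collapsed.index]
    return SimilarityMatrix(
        labels=labels,
        values=pd.DataFrame(mat, index=labels, columns=labels),
        n_features_used=collapsed.shape[1],
    )
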