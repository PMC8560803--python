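"""Shared numerics: stable hypergeometric tails and multiple-testing helpers.

The hypergeometric upper tail is computed in log space via gammaln +
logsumexp because rank-overlap grids routinely produce p-values far below
the double-precision underflow threshold (identical rankings over a few
hundred genes already give p ~ 1e-180); ``scipy.stats.hypergeom.sf`` would
return 0 there.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

__all__ = [
    "hypergeom_log_sf",
    "hypergeom_log10_sf",
    "hypergeom_sf",
    "bh_adjust",
    "by_adjust",
]

_LN10 = np.log(10.0)


def _log_binom(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_log_sf(k: int, N: int, K: int, n: int) -> float:
    """Natural log of P(X >= k) for X ~ Hypergeom(N, K, n).

    Direct log-space summation of pmf terms; exact to double rounding.
    k <= 0 returns log(1) = 0.
    """
    if n < 0 or K < 0 or N < 0 or K > N or n > N:
        raise ValueError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    hi = min(K, n)
    if k <= max(0, K + n - N):
        return 0.0
    if k > hi:
        return -np.inf
    x = np.arange(k, hi + 1, dtype=np.float64)
    logp = (
        _log_binom(float(K), x)
        + _log_binom(float(N - K), n - x)
        - _log_binom(float(N), float(n))
    )
    return float(logsumexp(logp))


def hypergeom_log10_sf(k: int, N: int, K: int, n: int) -> float:
    """−log10 is the display scale of rank-overlap maps; this is log10 P(X >= k)."""
    return hypergeom_log_sf(k, N, K, n) / _LN10


def hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k), clipped into [0, 1]."""
    return float(min(1.0, np.exp(hypergeom_log_sf(k, N, K, n))))


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (NaN-tolerant, NaN passed through)."""
    return _adjust(pvalues, "fdr_bh")


def by_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Yekutieli adjusted p-values (valid under arbitrary dependence)."""
    return _adjust(pvalues, "fdr_by")


def _adjust(pvalues: np.ndarray, method: str) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    flat = p.ravel()
    mask = np.isfinite(flat)
    if mask.any():
        adj = multipletests(flat[mask], method=method)[1]
        res = out.ravel()
        res[mask] = adj
        out = res.reshape(p.shape)
    return out
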