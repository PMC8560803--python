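"""Independent brute-force oracles used to verify the package's statistics.

Everything here is deliberately naive (exact rational arithmetic, O(n²)
scans, full enumeration) and shares no code path with the implementation
it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
from scipy import optimize, stats


def log10_big(n: int) -> float:
    """log10 of a (possibly huge) positive integer without overflow."""
    bl = n.bit_length()
    shift = max(0, bl - 900)
    return math.log10(n >> shift) + shift * math.log10(2.0)


def exact_hypergeom_log10_sf(k: int, N: int, K: int, n: int) -> float:
    """log10 P(X >= k) by exact rational direct summation (math.comb)."""
    lo = max(k, max(0, K + n - N))
    hi = min(K, n)
    if lo > hi:
        return -math.inf
    num = sum(math.comb(K, x) * math.comb(N - K, n - x) for x in range(lo, hi + 1))
    den = math.comb(N, n)
    if num == den:
        return 0.0
    return log10_big(num) - log10_big(den)


def exact_hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    lo = max(k, max(0, K + n - N))
    hi = min(K, n)
    if lo > hi:
        return 0.0
    num = sum(math.comb(K, x) * math.comb(N - K, n - x) for x in range(lo, hi + 1))
    return float(Fraction(num, math.comb(N, n)))


def brute_force_partition(peaks_a, peaks_b):
    """All-pairs O(n²) shared/specific labels: (labels_a, labels_b)."""
    def label(peaks, others):
        out = []
        for p in peaks:
            shared = any(
                p.chrom == q.chrom and p.start < q.end and q.start < p.end
                for q in others
            )
            out.append("shared" if shared else "specific")
        return out

    return label(peaks_a, peaks_b), label(peaks_b, peaks_a)


def brute_force_domains(tss_df, basal_up: int, basal_down: int, max_ext: int):
    """Per-gene regulatory domains by scanning every other gene.

    The extension on each side stops at the nearest point of any other
    gene's basal domain beyond the own basal edge (a neighbour whose basal
    domain straddles the edge clamps the extension at the edge itself),
    capped at max_ext; coordinates are clipped at 0 only on output.
    Returns {gene_id: (ext_start, ext_end)}.
    """
    genes = tss_df.to_dict("records")
    basal = {}
    for g in genes:
        if g["strand"] == "+":
            s, e = g["tss"] - basal_up, g["tss"] + basal_down
        else:
            s, e = g["tss"] - basal_down, g["tss"] + basal_up
        basal[g["gene_id"]] = (s, e)
    out = {}
    for g in genes:
        bs, be = basal[g["gene_id"]]
        ext_s = bs - max_ext
        ext_e = be + max_ext
        for h in genes:
            if h["gene_id"] == g["gene_id"] or h["chrom"] != g["chrom"]:
                continue
            hs, he = basal[h["gene_id"]]
            if hs < bs:  # neighbour domain reaching in from the left
                ext_s = max(ext_s, min(he, bs))
            if he > be:  # neighbour domain reaching in from the right
                ext_e = min(ext_e, max(hs, be))
        out[g["gene_id"]] = (max(0, ext_s), ext_e)
    return out


_BINOM_CACHE: dict = {}


def _binom_grid(n: int, grid: int) -> tuple[np.ndarray, np.ndarray]:
    """(π grid, pmf matrix of shape (grid, n+1)) — cached per (n, grid)."""
    key = (n, grid)
    if key not in _BINOM_CACHE:
        pis = np.arange(1, grid + 1) / (grid + 1)
        _BINOM_CACHE[key] = (pis, stats.binom.pmf(
            np.arange(n + 1)[None, :], n, pis[:, None]))
    return _BINOM_CACHE[key]


def barnard_brute_force(x1: int, n1: int, x2: int, n2: int,
                        grid: int = 9999) -> float:
    """Two-sided unconditional exact p by full outer-product double sum.

    Enumerates the complete (n1+1)×(n2+1) outcome grid (no truncation),
    masks outcomes at least as extreme (|pooled z| >= |observed|) and
    maximizes the masked double sum over the nuisance grid plus a bounded
    local polish.
    """
    def z(a, b):
        p1, p2 = a / n1, b / n2
        pp = (a + b) / (n1 + n2)
        v = pp * (1 - pp) * (1 / n1 + 1 / n2)
        return 0.0 if v <= 0 else (p1 - p2) / math.sqrt(v)

    z0 = abs(z(x1, x2))
    Z = np.array([[abs(z(a, b)) for b in range(n2 + 1)] for a in range(n1 + 1)])
    mask = (Z >= z0 - 1e-12).astype(float)

    def tail(pi):
        b1 = stats.binom.pmf(np.arange(n1 + 1), n1, pi)
        b2 = stats.binom.pmf(np.arange(n2 + 1), n2, pi)
        return float((np.outer(b1, b2) * mask).sum())

    pis, B1 = _binom_grid(n1, grid)
    _, B2 = _binom_grid(n2, grid)
    tails = np.einsum("gi,gj,ij->g", B1, B2, mask)
    best = float(tails.max())
    i = int(np.argmax(tails))
    h = 1.0 / (grid + 1)
    res = optimize.minimize_scalar(
        lambda p: -tail(p),
        bounds=(max(pis[i] - h, 1e-12), min(pis[i] + h, 1 - 1e-12)),
        method="bounded", options={"xatol": 1e-12},
    )
    return min(1.0, max(best, float(-res.fun)))


def ranksum_two_sided_exact(in_vals, out_vals) -> float:
    """Exact two-sided rank-sum p by dynamic programming over midranks.

    Counts size-n1 subsets of the pooled doubled midranks at each sum, then
    evaluates P(|T − μ| >= |T_obs − μ|) under the permutation distribution.
    """
    pooled = np.concatenate([in_vals, out_vals])
    ranks2 = np.round(stats.rankdata(pooled) * 2).astype(int)  # integers
    n1 = len(in_vals)
    t_obs2 = int(ranks2[:n1].sum())
    total2 = int(ranks2.sum())
    mu2 = Fraction(n1 * total2, len(pooled))
    d_obs = abs(Fraction(t_obs2) - mu2)

    # dp[k][s] = number of k-subsets with doubled-rank sum s
    max_sum = int(ranks2.sum())
    dp = [np.zeros(max_sum + 1, dtype=object) for _ in range(n1 + 1)]
    dp[0][0] = 1
    for r in ranks2:
        for k in range(min(n1, len(pooled)) - 1, -1, -1):
            nz = np.nonzero(dp[k])[0]
            for s in nz[::-1]:
                dp[k + 1][s + r] += dp[k][s]
    counts = dp[n1]
    total = math.comb(len(pooled), n1)
    hits = sum(int(counts[s]) for s in np.nonzero(counts)[0]
               if abs(Fraction(int(s)) - mu2) >= d_obs)
    return hits / total
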