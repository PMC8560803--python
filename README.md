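# osteopipe

Statistics for dual-perturbation transcriptomics, cistrome comparison,
single-cell composition analysis and morphological profiling — the
downstream computational toolkit of a study design built around a bone
transcription factor (Sp7/Osterix) driving the osteoblast-to-osteocyte
transition. The package is aimed at computational biologists who have
upstream outputs in hand (differential-expression tables from edgeR-like
tools, MACS-style peak calls, clustered single-cell count matrices,
CellProfiler-style feature tables) and need the bespoke statistics that
connect them.

## What it computes

**Counter-regulation & RRHO2.** A gene is *counter-regulated* by two
opposite perturbations (knockdown vs overexpression) when it passes
FDR < 0.05 in both comparisons with opposite log2 fold-change signs.
Global concordance is quantified with a stratified rank–rank
hypergeometric overlap map: genes are ranked by
`-log10(p) * sign(log2FC)` in each comparison and every threshold pair
`(i·step, j·step)` is scored with the one-sided tail
`P(X ≥ k | N, K = i·step, n = j·step)` of the hypergeometric
distribution, Benjamini–Yekutieli corrected per quadrant. The tail is
computed in log space (gammaln + logsumexp), so grid cells far below the
float underflow threshold remain exact.

**Cistrome partitioning & peak→gene association.** Two peak sets are split
into cell-type-specific and shared subsets by ≥1 bp half-open interval
overlap; peaks get promoter/distal labels against ±3 kb TSS windows; and
each peak associates with every gene whose *basal-plus-extension*
regulatory domain it overlaps (basal = 5 kb upstream / 1 kb downstream of
the TSS, extended to the nearest neighbouring basal domain, capped at
1 Mb). Cell-type-specific targets are the intersection of the
specific-peak-associated genes with a regulated gene set.

**Single-cell composition & markers.** QC filtering (≥1000 UMIs, ≤10%
mitochondrial reads), library downsampling, one-vs-rest Wilcoxon rank-sum
marker ranking on `ln(1 + 10⁴·count/UMI)` expression (exact enumeration
for tiny groups, tie- and continuity-corrected normal approximation
otherwise), per-cluster 2×2 contingency construction, and **Barnard's
unconditional exact test** with the pooled-z score statistic:

p = sup over π of Σ P(x₁; n₁, π)·P(x₂; n₂, π) over outcomes with |z| ≥ |z_obs|,

with the nuisance π maximized over a 9999-point grid plus bounded local
refinement.

**Cross-atlas permutation enrichment.** On a cell-type × gene pseudobulk
atlas, each gene's enrichment value in cell type *c* is its expression
minus the mean over the other cell types; a gene set is scored by the mean
of these values and compared against 500 random same-size gene sets:
`p = (1 + #{null ≥ observed}) / (1 + 500)`.

**Nosology enrichment.** Marker orthologs (one-to-one mouse→human mapping)
are tested against disease gene groups with the exact one-sided
hypergeometric tail.

**Morphological profiles.** Per-well mean aggregation → robust z
normalization stratified by cell background (median / 1.4826·MAD) →
ordered feature selection (missing values, the manual
Granularity_14/15/16 + Manders/Costes/RWC blocklist, low variance,
|value| > 15 outliers) → per-condition median collapse and Pearson
similarity.

A first-class synthetic-data module generates every input with planted
truth (counter-regulated fractions, shared peak fractions, cluster
proportion shifts, atlas enrichments, disease-group overlaps, similar
condition pairs), so the whole pipeline is testable without downloads.

## Worked example

```python
from osteopipe import DESimSpec, classify_counter_regulation, simulate_de_pair

spec = DESimSpec(n_genes=5000, n_doubly_significant=560,
                 counter_fraction=0.921, seed=1)
kd, oe, planted = simulate_de_pair(spec)
calls, summary = classify_counter_regulation(kd, oe)
print(summary)
```

prints

```
{'n_both': 560, 'n_counter': 516, 'n_co': 44, 'n_excluded_zero_lfc': 0,
 'fraction_counter': 0.9214285714285714}
```

— of the 560 genes significant in both perturbations, 516 (92.1%) moved in
opposite directions, and `calls` recovers the planted counter-regulated
set exactly. The `examples/` directory holds one narrative script per
capability (`01_counter_regulation.py` … `07_morphology.py`); each builds
a small synthetic input, runs the method and explains the numbers it
prints.

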