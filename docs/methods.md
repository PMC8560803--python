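# Methods

This note documents the models, defaults and numerical choices behind
osteopipe, and what the synthetic-data generators do and do not emulate.

## Counter-regulation and the stratified rank–rank overlap map

A gene is classified per comparison pair as **counter** (FDR < threshold
in both tables, opposite log2FC signs), **co** (both significant, equal
signs), **single**, or **none**. Inequalities are strict (`fdr < 0.05`,
`|log2fc| > 1`), matching the conventional printed thresholds. A
doubly-significant gene with log2FC exactly 0 has no direction; it is
excluded from both counter and co (status `none`) and counted separately,
preserving `n_both = n_counter + n_co + n_excluded`.

The expression pre-filter keeps genes with expression ≥ 0.25 in ≥ 2
samples. The procedure it implements is usually stated as a double
negative ("below 0.25 in fewer than two samples are removed"); we
implement the standard reading and expose the literal reading behind
`literal=True`.

The overlap map ranks the shared universe by `-log10(p)·sign(log2fc)`
(nominal p, not FDR; ties broken by gene id for determinism). The full
grid steps thresholds by `step` (default 200) with a trailing partial
stratum when `step ∤ N`. Each cell's score is the one-sided enrichment
tail `P(X ≥ k | N, K, n)`; the displayed value is signed by
enrichment/depletion relative to the expected overlap `K·n/N`. The
stratified quadrants follow the RRHO2 scheme: each list is split at the
signed-metric zero crossing; up/up steps both list heads, down/down both
tails, and the discordant quadrants mix a head with a tail; the
hypergeometric universe stays the full shared list (N), and genes with
metric exactly 0 belong to no stratum but remain in N.
Benjamini–Yekutieli correction (valid under the strong dependence of
nested overlap counts) is applied within each quadrant across its cells,
and separately across the full grid.

Numerics: the tail is computed as `logsumexp` over `gammaln`-based log
pmf terms. This matters because concordant diagonals of even mid-sized
universes produce p-values around 1e-180, far below double underflow if
summed naively; the log-space sum is accurate to ~1e-12 in log10, and the
test suite pins it against an exact big-integer rational oracle at 1e-10.

## Cistrome logic

Peak partitioning declares a peak shared iff it overlaps any peak of the
other set by ≥ 1 bp on 0-based half-open intervals (touching ends do not
overlap) — the default of the standard interval-intersection tools, and
the choice when the coordinates that entered the original intersection
are unknown. A summit-based mode (`use_summits=True`, summit ± `slop`,
interval midpoint standing in for a missing summit) is available for peak
sets where the summit is the meaningful anchor. Sets whose chromosome
names only match after stripping a
`chr` prefix raise an error rather than silently finding zero overlap.

Regulatory domains use the basal-plus-extension rule: basal =
[tss − 5000, tss + 1000) on the + strand (mirrored on −); the extension
grows from each basal edge to the nearest point of any other gene's basal
domain on that side — a neighbour whose basal domain straddles the edge
clamps the extension at the edge itself — capped at 1 Mb per side.
Boundaries are computed on unclipped coordinates (so every basal domain
has the same width and ordering by start orders ends too), then clipped
at 0; there is no upper clip without a chromosome-sizes input. The
promoter/distal annotation uses a strand-agnostic ±3 kb TSS window. All
three parameters are config keys.

## Single-cell statistics

QC keeps cells with `umi_total ≥ 1000` **and** `mito_fraction ≤ 0.10`;
the mitochondrial boundary keeps the cell because removal is defined as
strictly "greater than 10%", and the UMI cutoff is taken as inclusive.
`umi_total` and `mito_fraction` are always recomputed from the count
matrix, never trusted from metadata. Cluster labels are consumed as
given; clustering itself is out of scope.

Markers use a two-sided Wilcoxon rank-sum on `ln(1 + 10⁴·count/UMI)`
values with midranks, tie-corrected variance and a 0.5 continuity
correction; when both groups have ≤ 10 cells the exact permutation
distribution of the rank sum is enumerated instead (p =
P(|T − μ| ≥ |T_obs − μ|)). `logfc` is the difference of normalized-
expression means — the log-normalized-mean convention, pinned here
because marker tools differ. A gene with constant raw counts across all
cells carries no per-gene signal even though depth normalization makes
its values vary, so it returns p = 1 and logfc = 0 by convention. BH FDR
is computed across genes within each group. Two ranking keys are exposed
for top-k extraction: p-value (ascending) and `pct_diff = pct_in −
pct_out` (descending); `pct_diff` was chosen over the in/out ratio
because it is bounded and defined when `pct_out = 0`.

Barnard's unconditional exact test uses the pooled-variance score
statistic z (the common default of the R implementations; CSM and
Boschloo orderings are out of scope). The p-value maximizes the tail
probability over the common-proportion nuisance π on a uniform open grid
of 9999 points, then polishes the best well-separated grid candidates
with bounded scalar minimization (xatol 1e-12), bounding the
under-coverage of a pure grid maximum far below 1e-6. Outcomes tied with
the observed |z| (within 1e-12) count as extreme. For large libraries the
per-π binomial factors are truncated to ±10σ ranges per π-chunk
(excluded mass < 1e-20), which keeps a 2 × 2000-cell table under ~2 s
without affecting the exactness checks, which run untruncated sizes.
Proportions divide in-cluster cells by the library total; contingency
tables pool libraries within genotype and require exactly two genotypes
(order = sorted labels).

## Atlas permutation enrichment

`value(g, c) = expr(g, c) − mean_{c'≠c} expr(g, c')` on the aggregated
log-like scale; a gene set scores the mean of its genes' values in one
cell type (genes missing from the atlas are counted and dropped). The
null resamples same-size gene sets uniformly from **all** atlas genes —
matching the stated procedure; an expression-matched sampler was
considered and rejected as a change of null hypothesis, though callers
can pass any restricted `values` matrix. The empirical p uses add-one
smoothing `(1 + b)/(1 + N)` so it can never be 0; the literal `b/N` is
available (`raw_empirical_p=True`). Ties count against the observed set
(≥), the conservative reading. A per-gene rank test between single
aggregated profiles is statistically ill-posed (one value per cell type),
so the mean-difference path is the primary scorer; a linear-scale
fold-change transform (`celltype_fold_change_values`) is provided as the
alternative sensitivity scorer.

Ortholog mapping defaults to one-to-one (a gene is kept only when its
mouse and human symbols each occur in exactly one pair); `all-pairs`
keeps every partner. Nosology enrichment uses the nosology universe as N,
draws = markers ∩ universe, and the exact one-sided hypergeometric tail
per group; nominal p by default with an optional BH column, since the
groups form one small pre-registered family.

## Morphological profiles

Metadata columns carry the `Metadata_` prefix (the profiling-community
convention); everything else is a feature. Aggregation is the per-well
mean with missing values excluded. Normalization is a robust z per
feature within each cell-background stratum — (x − median)/(1.4826·MAD),
falling back to the standard deviation when the MAD is 0 and marking the
feature degenerate (NaN) when both vanish, so the missing-value rule
removes it. Selection applies, in order: any-missing, blocklist
substring match (Granularity_14/15/16, Manders, Costes, RWC —
case-sensitive), variance < 1e-5, any |value| > 15. The variance floor
and outlier cutoff are the profiling framework's published defaults;
after robust-z the variance rule is mostly a safety net (MAD
normalization bounds the post-normalization variance from below), and
degenerate features exit via the missing-value rule instead. Collapse is
the per-condition median over however many replicate wells exist (the
replicate count is data, not a constraint), followed by Pearson
correlation across features; the matrix is exactly symmetrized with a
unit diagonal, and features constant across collapsed conditions are
excluded with a warning. One global selection follows stratified
normalization; per-stratum selection is possible by slicing the table
before the call.

## Synthetic data: what it emulates, and what it does not

Every generator is a pure function of its spec; one global seed expands
into fixed per-component substreams (`SeedSequence(seed, spawn_key)`), so
adding a generator never perturbs existing outputs.

* **DE pairs** emulate DE *outputs*, not count-model inference: non-null
  p-values come from |z| ~ Normal(4, 1) (p = 2·Φ(−|z|)), null p-values
  are Uniform(0, 1), null log2FC ~ Normal(0, 0.2), planted effect sizes
  are `effect ± |Normal(0, 0.3)|`, and FDR is BH within each table.
  Because BH significance is a whole-table property, a deterministic
  repair loop shrinks planted p-values that miss the threshold and lifts
  null genes that reach double significance until the planted structure
  holds exactly — the generator's contract is the planted truth, not the
  letter of the sampling model. Defaults (5000 genes, 560 doubly
  significant, 92.1% counter) mirror the rescue-design scale the
  pipeline targets.
* **Genomes/peaks** place all peaks on disjoint slots of one toy
  chromosome, duplicating a `shared_fraction` of the first set into the
  second with < peak-width jitter (≥ 1 bp overlap guaranteed), so
  specific/shared truth is exact by construction. Real peak sets have
  width/score distributions and nested overlaps this does not model.
* **Single-cell counts** are gamma-Poisson (negative binomial
  parameterized by mean μ and dispersion θ, variance μ + μ²/θ — the
  (mean, dispersion) convention, stated to avoid the two-convention
  trap), uniform means across genes, multiplicative in-cluster marker
  effects, planted cluster proportions per genotype, and planted QC
  failures (low-depth cells scaled to half the UMI cutoff in
  expectation; high-mito cells boosted to ~30% mitochondrial reads).
  No batch effects beyond genotype, no library-size confounding, no
  doublets.
* **Atlases** are baseline + Normal noise with one additive planted
  shift; **nosology** groups are disjoint with a one-to-one ortholog
  backbone plus many-to-many distractors; **wells** draw cell features
  from Normal(condition mean, 1) where condition means are per-condition
  effect vectors scaled by `treatment_effect` and the last two conditions
  share one vector (the planted similar pair — with `treatment_effect=0`
  all conditions coincide and profile correlations are pure noise).

Passing tests on these inputs demonstrates the *statistics* (exactness
against oracles, calibration under nulls, power against planted effects),
not robustness to the messiness of real data (overdispersed atlases,
correlated features, ambiguous orthologs, imbalanced libraries).

## Problem sizes used by the test suite and acceptance script

Oracle-equivalence checks run at universes of ~600 genes (overlap map),
all 2×2 tables with n ≤ 12 plus a fuzz sample (Barnard), group sizes ≤ 8
(exact rank-sum), and 1000 random toy genomes/peak instances (interval
logic). Calibration runs use 100–200 replicates (null overlap maps at
N = 4000, null atlas sets, profile seeds) and a 20,000-rep type-I
simulation at n = 30/30; the power check uses 100 simulated experiments
with 2000 cells per library. These sizes make the full suite complete in
a few minutes on one CPU while keeping every Monte-Carlo band at ≥ 3σ
separation from its threshold.
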