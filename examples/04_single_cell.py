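"""Single-cell QC, cluster proportions and Barnard's exact test.

Simulates a two-genotype experiment (2000 cells per library, 8 clusters)
with a planted drop of cluster c6 from 10% (WT) to 3% (KO) and 5% planted
QC failures, then runs the QC filter, per-library proportions and the
unconditional exact test per cluster.
"""

from osteopipe import (
    ScSimSpec,
    barnard_exact_test,
    cluster_proportions,
    qc_filter_cells,
    rank_markers,
    simulate_single_cell_experiment,
    top_markers,
)

exp = simulate_single_cell_experiment(ScSimSpec(
    n_clusters=8, cells_per_library=2000, n_genes=300,
    proportion_shift={"c6": (0.10, 0.03)}, qc_fail_fraction=0.05, seed=4))

filtered = qc_filter_cells(exp, umi_cutoff=1000, mito_cutoff=0.10)
print(f"cells: {exp.n_cells} -> {filtered.n_cells} after QC")

props, tables = cluster_proportions(filtered)
print(props.round(3).to_string())
for cluster in sorted(tables):
    res = barnard_exact_test(tables[cluster])
    flag = " *" if res.pvalue < 0.05 else ""
    print(f"  {cluster}: z = {res.statistic:+6.2f}  p = {res.pvalue:.3g}{flag}")
# Only the planted cluster (c6) should reject: its proportion differs
# between genotypes far beyond binomial sampling noise.

wt = filtered.subset_cells((filtered.cell_meta["genotype"] == "WT").to_numpy())
markers = rank_markers(wt, grouping="cluster", seed=0)
print("top c6 markers by p-value:")
print(top_markers(markers, 5, by="pvalue", cluster="c6")
      [["gene_id", "pvalue", "logfc", "pct_diff"]].to_string(index=False))
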