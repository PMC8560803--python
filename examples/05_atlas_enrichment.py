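"""Permutation gene-set enrichment against a pseudobulk atlas.

Simulates a 9-cell-type atlas with a 77-gene set planted +0.5 log-units in
the Neurons column, computes each gene's mean expression difference vs the
other cell types, and scores the set against 500 random same-size gene
sets (the empirical null).
"""

from osteopipe import (
    AtlasSimSpec,
    celltype_enrichment_values,
    permutation_null_test,
    simulate_atlas,
)

atlas, planted = simulate_atlas(AtlasSimSpec(
    n_celltypes=9, n_genes=2000, planted_set_size=77,
    planted_celltype="Neurons", planted_shift=0.5, noise_sd=0.1, seed=5))

values = celltype_enrichment_values(atlas)
for celltype in atlas.celltypes:
    res = permutation_null_test(values, planted, celltype, n_iter=500, seed=5)
    mark = " <- planted" if celltype == "Neurons" else ""
    print(f"{celltype:20s} score {res.observed_score:+.3f}  "
          f"p = {res.p_empirical:.3f}{mark}")

# The planted cell type reaches the smoothed floor p = 1/501 ~ 0.002; all
# others sit in the null body. The add-one smoothing keeps the empirical p
# strictly positive regardless of how extreme the observed score is.
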