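"""Single-cell QC, downsampling, markers, proportions, Barnard's test."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import barnard_exact as scipy_barnard

from _oracles import barnard_brute_force, ranksum_two_sided_exact
from osteopipe import (
    CellExperiment,
    Contingency2x2,
    ScSimSpec,
    barnard_exact_test,
    cluster_proportions,
    downsample_to_match,
    qc_filter_cells,
    rank_markers,
    simulate_single_cell_experiment,
    top_markers,
)


def tiny_experiment(counts, libraries, genotypes, clusters, mito_rows=()):
    counts = np.asarray(counts)
    return CellExperiment(
        counts,
        pd.DataFrame({"library_id": libraries, "genotype": genotypes,
                      "cluster": clusters}),
        pd.DataFrame({"gene_id": [f"g{i}" for i in range(counts.shape[0])],
                      "is_mito": [i in mito_rows for i in range(counts.shape[0])]}),
    )


class TestCellExperiment:
    def test_umi_and_mito_recomputed(self):
        exp = tiny_experiment([[5, 0], [5, 10]], ["L1", "L1"], ["WT", "WT"],
                              ["c1", "c1"], mito_rows=(0,))
        assert list(exp.cell_meta["umi_total"]) == [10, 10]
        assert list(exp.cell_meta["mito_fraction"]) == [0.5, 0.0]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            tiny_experiment([[-1]], ["L1"], ["WT"], ["c1"])

    def test_anndata_roundtrip(self):
        exp = tiny_experiment([[5, 1], [2, 3]], ["L1", "L2"], ["WT", "KO"],
                              ["c1", "c2"], mito_rows=(1,))
        back = CellExperiment.from_anndata(exp.to_anndata())
        np.testing.assert_array_equal(back.counts, exp.counts)
        assert list(back.cell_meta["genotype"]) == ["WT", "KO"]


class TestQC:
    def make(self, umis, mito_boost=None):
        n = len(umis)
        counts = np.zeros((2, n), dtype=int)
        counts[1] = umis
        if mito_boost:
            for i, frac in mito_boost.items():
                total = umis[i]
                counts[0, i] = int(round(total * frac))
                counts[1, i] = total - counts[0, i]
        return tiny_experiment(counts, ["L1"] * n, ["WT"] * n, ["c1"] * n,
                               mito_rows=(0,))

    def test_umi_boundary(self):
        exp = self.make([999, 1000, 2000])
        out = qc_filter_cells(exp)
        assert list(out.cell_meta["umi_total"]) == [1000, 2000]

    def test_mito_boundary_kept_at_exact_cutoff(self):
        exp = self.make([2000, 2000], mito_boost={0: 0.10, 1: 0.11})
        out = qc_filter_cells(exp)
        assert out.n_cells == 1
        assert out.cell_meta["mito_fraction"].iloc[0] == pytest.approx(0.10)

    def test_vacuous_cutoffs_identity_and_idempotence(self):
        exp = self.make([5, 10, 2000])
        out = qc_filter_cells(exp, umi_cutoff=0, mito_cutoff=1.0)
        assert out.n_cells == 3
        once = qc_filter_cells(exp)
        twice = qc_filter_cells(once)
        np.testing.assert_array_equal(once.counts, twice.counts)

    def test_all_removed_errors(self):
        with pytest.raises(ValueError):
            qc_filter_cells(self.make([5, 6]))


class TestDownsample:
    @pytest.fixture
    def exp(self):
        rng = np.random.default_rng(0)
        n_wt, n_ko = 300, 150
        counts = rng.poisson(5, size=(10, n_wt + n_ko))
        return tiny_experiment(
            counts,
            ["WT_1"] * n_wt + ["KO_1"] * n_ko,
            ["WT"] * n_wt + ["KO"] * n_ko,
            list(np.r_[["c1"] * 200, ["c2"] * 100, ["c1"] * 50, ["c2"] * 100]),
        )

    def test_total_mode(self, exp):
        out = downsample_to_match(exp, "WT_1", "KO_1", "total-cells", seed=1)
        assert (out.cell_meta["library_id"] == "WT_1").sum() == 150

    def test_per_cluster_mode(self, exp):
        out = downsample_to_match(exp, "WT_1", "KO_1", "per-cluster", seed=1)
        wt = out.cell_meta[out.cell_meta["library_id"] == "WT_1"]
        assert wt.groupby("cluster").size().to_dict() == {"c1": 50, "c2": 100}
        ko = out.cell_meta[out.cell_meta["library_id"] == "KO_1"]
        assert len(ko) == 150  # target library untouched

    def test_deterministic_under_seed(self, exp):
        a = downsample_to_match(exp, "WT_1", "KO_1", "total-cells", seed=7)
        b = downsample_to_match(exp, "WT_1", "KO_1", "total-cells", seed=7)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_target_larger_errors(self, exp):
        with pytest.raises(ValueError):
            downsample_to_match(exp, "KO_1", "WT_1", "total-cells", seed=0)
        with pytest.raises(ValueError, match="c1"):
            downsample_to_match(exp, "KO_1", "WT_1", "per-cluster", seed=0)


class TestMarkers:
    def test_exact_example_and_all_ties(self):
        # gene 0: counts 1,2,3 in-cluster vs 4,5,6 out; gene 1 constant
        # filler so normalized gene-0 values track the count fraction.
        counts = np.array([[1, 2, 3, 4, 5, 6], [10] * 6])
        exp = tiny_experiment(counts, ["L1"] * 6, ["WT"] * 6,
                              ["c1"] * 3 + ["c2"] * 3)
        mk = rank_markers(exp, grouping="cluster")
        g0c1 = mk[(mk.gene_id == "g0") & (mk.cluster == "c1")].iloc[0]
        assert g0c1.pvalue == pytest.approx(2 / 20)  # 2 / C(6,3)
        g1c1 = mk[(mk.gene_id == "g1") & (mk.cluster == "c1")].iloc[0]
        assert g1c1.pvalue == 1.0 and g1c1.logfc == pytest.approx(0.0)

    def test_exact_mode_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n1, n2 = rng.integers(2, 7, size=2)
            counts = np.vstack([rng.integers(0, 6, size=n1 + n2),
                                np.full(n1 + n2, 8)])
            exp = tiny_experiment(counts, ["L1"] * (n1 + n2),
                                  ["WT"] * (n1 + n2),
                                  ["c1"] * n1 + ["c2"] * n2)
            mk = rank_markers(exp, grouping="cluster")
            row = mk[(mk.gene_id == "g0") & (mk.cluster == "c1")].iloc[0]
            norm = np.log1p(1e4 * counts[0] / counts.sum(axis=0))
            expected = ranksum_two_sided_exact(norm[:n1], norm[n1:])
            assert row.pvalue == pytest.approx(expected, abs=1e-12)

    def test_planted_markers_recovered(self):
        exp = simulate_single_cell_experiment(
            ScSimSpec(n_clusters=4, cells_per_library=150, n_genes=120,
                      marker_genes_per_cluster=4, marker_effect=6.0, seed=8))
        mk = rank_markers(exp, grouping="cluster", seed=0)
        truth = set(exp.gene_meta.loc[exp.gene_meta.marker_cluster == "c2",
                                      "gene_id"])
        top = top_markers(mk, 4, by="pvalue", cluster="c2")
        assert set(top.gene_id) == truth

    def test_pct_diff_ranking_key(self):
        exp = simulate_single_cell_experiment(
            ScSimSpec(n_clusters=3, cells_per_library=100, n_genes=60,
                      nb_mean=0.5, marker_effect=8.0, seed=4))
        mk = rank_markers(exp, grouping="cluster", seed=0)
        top = top_markers(mk, 10, by="pct_diff", cluster="c1")
        assert (top.pct_diff.to_numpy() == np.sort(top.pct_diff)[::-1]).all()

    def test_genotype_grouping_and_equalize(self):
        exp = simulate_single_cell_experiment(
            ScSimSpec(n_clusters=2, cells_per_library=100, n_genes=50, seed=5))
        mk = rank_markers(exp, grouping="genotype", equalize_per_library=True,
                          seed=1)
        assert set(mk.cluster) == {"c1", "c2"}
        assert (mk.pct_in.between(0, 1) & mk.pct_out.between(0, 1)).all()


class TestProportions:
    def test_proportions_and_contingency(self):
        exp = tiny_experiment(
            np.ones((2, 300), dtype=int),
            ["WT_1"] * 100 + ["KO_1"] * 200,
            ["WT"] * 100 + ["KO"] * 200,
            ["c1"] * 30 + ["c2"] * 70 + ["c1"] * 20 + ["c2"] * 180,
        )
        props, tables = cluster_proportions(exp)
        assert props.loc["WT_1", "c1"] == pytest.approx(0.30)
        assert np.allclose(props.sum(axis=1), 1.0, atol=1e-12)
        t = tables["c1"]
        # genotype order is sorted: KO first
        assert (t.x1, t.n1, t.x2, t.n2) == (20, 200, 30, 100)
        # cell conservation per cluster
        for tab in tables.values():
            assert tab.n1 + tab.n2 == 300


class TestBarnard:
    def test_balanced_table_p_one(self):
        r = barnard_exact_test(Contingency2x2(5, 10, 5, 10))
        assert r.statistic == 0.0 and r.pvalue == pytest.approx(1.0)

    def test_hand_enumerated_minimal_table(self):
        # 4 outcomes; the extreme set is {(1,0),(0,1)} with probability
        # 2π(1−π), maximized at π = 1/2 -> p = 1/2.
        r = barnard_exact_test(Contingency2x2(1, 1, 0, 1))
        assert r.pvalue == pytest.approx(0.5, abs=1e-9)
        assert r.nuisance_argmax == pytest.approx(0.5, abs=1e-6)

    def test_label_swap_invariance(self):
        a = barnard_exact_test(Contingency2x2(12, 30, 4, 25))
        b = barnard_exact_test(Contingency2x2(4, 25, 12, 30))
        assert a.pvalue == pytest.approx(b.pvalue, abs=1e-10)
        assert a.statistic == pytest.approx(-b.statistic)

    def test_matches_brute_force_oracle_sample(self):
        rng = np.random.default_rng(2)
        for _ in range(8):
            n1, n2 = rng.integers(2, 13, size=2)
            x1, x2 = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
            mine = barnard_exact_test(Contingency2x2(int(x1), int(n1),
                                                     int(x2), int(n2)))
            assert mine.pvalue == pytest.approx(
                barnard_brute_force(int(x1), int(n1), int(x2), int(n2)),
                abs=1e-9)

    def test_one_sided_alternatives(self):
        t = Contingency2x2(9, 10, 2, 10)
        two = barnard_exact_test(t).pvalue
        greater = barnard_exact_test(t, alternative="greater").pvalue
        less = barnard_exact_test(t, alternative="less").pvalue
        assert greater < two <= 1.0
        assert less > 0.5  # observed effect is in the 'greater' direction

    def test_against_scipy_cross_check(self):
        # scipy's pooled-Wald variant excludes some symmetric ties from the
        # extreme region, so agreement is approximate and ours is >= scipy's
        for (x1, n1, x2, n2) in [(12, 30, 4, 30), (3, 8, 7, 9), (1, 5, 4, 5)]:
            mine = barnard_exact_test(Contingency2x2(x1, n1, x2, n2)).pvalue
            ref = scipy_barnard(np.array([[x1, x2], [n1 - x1, n2 - x2]]),
                                pooled=True, n=64).pvalue
            assert mine >= ref - 1e-8
            assert mine == pytest.approx(ref, rel=0.05, abs=5e-3)

    def test_invalid_tables(self):
        with pytest.raises(ValueError):
            Contingency2x2(5, 4, 0, 3)
        with pytest.raises(ValueError):
            Contingency2x2(0, 0, 0, 3)
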