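"""Atlas enrichment values, permutation test, orthologs, nosology."""

import numpy as np
import pandas as pd
import pytest

from _oracles import exact_hypergeom_sf
from osteopipe import (
    AtlasMatrix,
    GeneSet,
    NosologyGroups,
    aggregate_major_types,
    celltype_enrichment_values,
    geneset_score,
    map_orthologs,
    nosology_enrichment,
    permutation_null_test,
)
from osteopipe.enrich import celltype_fold_change_values


def atlas_from(values, celltypes, genes, major_map=None):
    return AtlasMatrix(pd.DataFrame(values, index=celltypes, columns=genes),
                       major_type_map=major_map)


class TestAggregate:
    def test_mean_of_subtypes(self):
        atlas = atlas_from([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
                           ["n1", "n2", "a1"], ["g1", "g2"],
                           {"n1": "Neurons", "n2": "Neurons", "a1": "Astro"})
        out = aggregate_major_types(atlas)
        assert out.values.loc["Neurons", "g1"] == 2.0
        assert out.values.loc["Astro", "g2"] == 6.0

    def test_identity_map(self):
        atlas = atlas_from([[1.0], [2.0]], ["a", "b"], ["g"],
                           {"a": "a", "b": "b"})
        out = aggregate_major_types(atlas)
        pd.testing.assert_frame_equal(out.values, atlas.values)

    def test_unmapped_subtype_errors(self):
        atlas = atlas_from([[1.0], [2.0]], ["a", "b"], ["g"], {"a": "A"})
        with pytest.raises(ValueError, match="b"):
            aggregate_major_types(atlas)


class TestEnrichmentValues:
    def test_flat_gene_is_zero(self):
        atlas = atlas_from(np.full((4, 2), 3.0), list("abcd"), ["g1", "g2"])
        vals = celltype_enrichment_values(atlas)
        assert np.allclose(vals.to_numpy(), 0.0)

    def test_two_celltype_antisymmetry(self):
        atlas = atlas_from([[1.0, 4.0], [3.0, 0.0]], ["a", "b"], ["g1", "g2"])
        vals = celltype_enrichment_values(atlas)
        assert np.allclose(vals.loc["a"], -vals.loc["b"])

    def test_mean_difference_example(self):
        atlas = atlas_from([[5.0], [1.0], [1.0], [1.0]], list("abcd"), ["g"])
        vals = celltype_enrichment_values(atlas)
        assert vals.loc["a", "g"] == pytest.approx(4.0)

    def test_single_celltype_errors(self):
        with pytest.raises(ValueError):
            celltype_enrichment_values(atlas_from([[1.0]], ["a"], ["g"]))

    def test_fold_change_scorer_sign_agrees(self):
        atlas = atlas_from([[5.0, 1.0], [1.0, 1.0], [1.0, 1.0]],
                           list("abc"), ["g1", "g2"])
        fc = celltype_fold_change_values(atlas)
        assert fc.loc["a", "g1"] > 0
        assert fc.loc["a", "g2"] == pytest.approx(0.0, abs=1e-6)


class TestGenesetScore:
    @pytest.fixture
    def vals(self):
        rng = np.random.default_rng(0)
        return celltype_enrichment_values(
            atlas_from(rng.normal(size=(3, 10)), list("abc"),
                       [f"g{i}" for i in range(10)]))

    def test_singleton(self, vals):
        s, used, missing = geneset_score(vals, GeneSet("s", {"g3"}), "a")
        assert s == pytest.approx(vals.loc["a", "g3"])
        assert (used, missing) == (1, 0)

    def test_all_genes_is_row_mean(self, vals):
        s, used, _ = geneset_score(
            vals, GeneSet("s", set(vals.columns)), "b")
        assert s == pytest.approx(vals.loc["b"].mean())

    def test_missing_counted(self, vals):
        s, used, missing = geneset_score(
            vals, GeneSet("s", {"g1", "nope"}), "a")
        assert (used, missing) == (1, 1)

    def test_no_usable_genes_errors(self, vals):
        with pytest.raises(ValueError):
            geneset_score(vals, GeneSet("s", {"zz"}), "a")


class TestPermutationTest:
    @pytest.fixture
    def vals(self):
        rng = np.random.default_rng(1)
        return celltype_enrichment_values(
            atlas_from(rng.normal(size=(4, 200)), list("abcd"),
                       [f"g{i}" for i in range(200)]))

    def test_p_floor_and_ceiling(self, vals):
        # plant an extreme positive score -> floor; extreme negative -> 1
        v = vals.copy()
        v.loc["a", ["g0", "g1", "g2"]] = 100.0
        res = permutation_null_test(v, GeneSet("s", {"g0", "g1", "g2"}), "a",
                                    n_iter=100, seed=0)
        assert res.p_empirical == pytest.approx(1 / 101)
        v.loc["a", ["g0", "g1", "g2"]] = -100.0
        res = permutation_null_test(v, GeneSet("s", {"g0", "g1", "g2"}), "a",
                                    n_iter=100, seed=0)
        assert res.p_empirical == 1.0

    def test_invariant_of_result(self, vals):
        res = permutation_null_test(vals, GeneSet("s", {"g0", "g5"}), "b",
                                    n_iter=50, seed=3)
        n_ge = int((res.null_scores >= res.observed_score).sum())
        assert res.p_empirical == (1 + n_ge) / 51
        assert res.n_genes_used + res.n_genes_missing == 2

    def test_bit_reproducible(self, vals):
        r1 = permutation_null_test(vals, GeneSet("s", {"g0", "g5"}), "a",
                                   n_iter=50, seed=9)
        r2 = permutation_null_test(vals, GeneSet("s", {"g0", "g5"}), "a",
                                   n_iter=50, seed=9)
        np.testing.assert_array_equal(r1.null_scores, r2.null_scores)

    def test_raw_empirical_flag(self, vals):
        v = vals.copy()
        v.loc["a", ["g0", "g1", "g2"]] = 1000.0
        res = permutation_null_test(v, GeneSet("s", {"g0", "g1", "g2"}), "a",
                                    n_iter=100, seed=0, raw_empirical_p=True)
        assert res.p_empirical == 0.0  # the literal b/N estimate can be 0

    def test_null_rejection_rate_in_binomial_band(self):
        """Under a null atlas the p <= 0.05 rejection rate over 1000
        replicate sets stays inside the binomial 99% band [0.03, 0.07]."""
        from osteopipe import AtlasSimSpec, simulate_atlas

        atlas, _ = simulate_atlas(AtlasSimSpec(planted_shift=0.0, seed=77))
        v = celltype_enrichment_values(atlas)
        genes = np.asarray(v.columns)
        rng = np.random.default_rng(7)
        rejected = 0
        for i in range(1000):
            members = rng.choice(genes, size=40, replace=False)
            res = permutation_null_test(v, GeneSet(f"s{i}", set(members)),
                                        "Neurons", n_iter=500, seed=i)
            rejected += res.p_empirical <= 0.05
        assert 0.03 <= rejected / 1000 <= 0.07

    def test_set_as_large_as_universe_errors(self, vals):
        with pytest.raises(ValueError):
            permutation_null_test(vals, GeneSet("s", set(vals.columns)), "a")


class TestOrthologs:
    PAIRS = {("m1", "H1"), ("m2", "H2"), ("m2", "H3"), ("m4", "H4"),
             ("m5", "H4")}

    def test_one_to_one(self):
        out = map_orthologs(GeneSet("s", {"m1"}), self.PAIRS)
        assert out.genes == frozenset({"H1"})

    def test_ambiguous_dropped_one_to_one(self):
        out = map_orthologs(GeneSet("s", {"m2", "m4"}), self.PAIRS)
        # m2 maps to two humans; m4's human is shared with m5
        assert out.genes == frozenset()

    def test_all_pairs_mode(self):
        out = map_orthologs(GeneSet("s", {"m2"}), self.PAIRS, mode="all-pairs")
        assert out.genes == frozenset({"H2", "H3"})

    def test_unmapped_empty(self):
        out = map_orthologs(GeneSet("s", {"zz"}), self.PAIRS)
        assert len(out) == 0

    def test_output_never_larger_in_one_to_one(self):
        s = GeneSet("s", {"m1", "m2", "m4", "zz"})
        out = map_orthologs(s, self.PAIRS)
        assert len(out) <= len(s)


class TestNosology:
    def test_closed_form_single_term(self):
        groups = NosologyGroups({
            "g1": frozenset(f"A{i}" for i in range(5)),
            "g2": frozenset(f"B{i}" for i in range(15)),
        })
        markers = GeneSet("m", {f"A{i}" for i in range(5)})
        tab = nosology_enrichment(markers, groups)
        # N=20, K=5, n=5, k=5 -> p = 1/C(20,5)
        assert tab.loc["g1", "p"] == pytest.approx(1 / 15504, rel=1e-12)

    def test_zero_overlap_p_one(self):
        groups = NosologyGroups({"g1": frozenset({"A"}),
                                 "g2": frozenset({"B"})})
        tab = nosology_enrichment(GeneSet("m", {"B"}), groups)
        assert tab.loc["g1", "p"] == 1.0

    def test_empty_draws_warns_all_one(self, caplog):
        groups = NosologyGroups({"g1": frozenset({"A"})})
        with caplog.at_level("WARNING"):
            tab = nosology_enrichment(GeneSet("m", {"ZZ"}), groups)
        assert (tab["p"] == 1.0).all()

    def test_matches_exact_oracle_random_configs(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n_groups = int(rng.integers(2, 6))
            sizes = rng.integers(3, 15, size=n_groups)
            pool = [f"G{i}" for i in range(int(sizes.sum()))]
            idx = 0
            groups = {}
            for gi, size in enumerate(sizes):
                groups[f"grp{gi}"] = frozenset(pool[idx:idx + int(size)])
                idx += int(size)
            ng = NosologyGroups(groups)
            n_draw = int(rng.integers(1, len(pool)))
            markers = GeneSet("m", set(rng.choice(pool, size=n_draw,
                                                  replace=False)))
            tab = nosology_enrichment(markers, ng)
            for name, genes in groups.items():
                k = len(markers.genes & genes)
                expected = exact_hypergeom_sf(k, len(pool), len(genes), n_draw)
                assert tab.loc[name, "p"] == pytest.approx(expected,
                                                           rel=1e-12, abs=1e-15)
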