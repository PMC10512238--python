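"""Duplication-aware strict and evolutionary gene-tree distances."""

import numpy as np
import pytest

from coevoclust.synthdata import (
    SyntheticFamilyConfig,
    simulate_coevolved_family,
    simulate_independent_genes,
    simulate_species_tree,
)
from coevoclust.treedist import (
    DistanceMatrixSet,
    annotate_duplications,
    evolutionary_distance,
    pairwise_matrices,
    prune_to_forest,
    strict_distance,
)
from coevoclust.trees import annotate_species, parse_newick


def tree(text, gene_id="g"):
    return annotate_species(parse_newick(text, gene_id))


class TestDuplicationAnnotation:
    def test_paralog_tree_root_is_duplication(self):
        ann = annotate_duplications(tree("((Hsap_1,Mmus_1),(Hsap_2,Mmus_2));"))
        assert ann.tree.event == "duplication"
        assert [c.event for c in ann.tree.children] == ["speciation", "speciation"]

    def test_single_copy_tree_has_no_duplication(self):
        ann = annotate_duplications(tree("((Aa_1,Bb_1),(Cc_1,Dd_1));"))
        events = [n.event for n in ann.tree.traverse() if not n.is_tip()]
        assert set(events) == {"speciation"}

    def test_nested_duplication(self):
        ann = annotate_duplications(tree("(Hsap_1,(Hsap_2,Mmus_1));"))
        inner = [c for c in ann.tree.children if not c.is_tip()][0]
        assert inner.event == "speciation"
        assert ann.tree.event == "duplication"

    def test_unannotated_tree_rejected(self):
        with pytest.raises(Exception, match="annotated"):
            annotate_duplications(parse_newick("(Aa_1,Bb_1);"))


class TestPrunedForest:
    def test_single_copy_tree_is_its_own_forest(self):
        f = prune_to_forest(annotate_duplications(tree("((Aa_1,Bb_1),(Cc_1,Dd_1));")))
        assert len(f.subtrees) == 1
        assert f.subtrees[0].species == {"Aa", "Bb", "Cc", "Dd"}

    def test_two_by_two_paralog_tree_splits_in_two(self):
        f = prune_to_forest(
            annotate_duplications(tree("((Hsap_1,Mmus_1),(Hsap_2,Mmus_2));"))
        )
        assert len(f.subtrees) == 2
        assert all(s.species == {"Hsap", "Mmus"} for s in f.subtrees)

    def test_same_species_pair_gives_two_singletons(self):
        f = prune_to_forest(annotate_duplications(tree("(Aa_1,Aa_2);")))
        assert sorted(len(s.species) for s in f.subtrees) == [1, 1]

    def test_deep_duplication_keeps_backbone(self):
        # one duplicated cherry inside a 6-species tree: two resolutions,
        # each spanning all six species
        t = tree(
            "((Aa_1,Bb_1),((Cc_1,Dd_1),((Ee_1,Ff_1),(Ee_2,Ff_2))));"
        )
        f = prune_to_forest(annotate_duplications(t))
        assert len(f.subtrees) == 2
        assert all(len(s.species) == 6 for s in f.subtrees)

    def test_no_species_repeated_within_subtree(self):
        fam = simulate_coevolved_family(
            simulate_species_tree(10, seed=5), 4,
            SyntheticFamilyConfig(n_species=10, duplication_rate=0.3, seed=5),
        )
        for gt in fam:
            f = prune_to_forest(annotate_duplications(gt))
            for s in f.subtrees:
                # clades are species sets; the leaf clades must be unique
                singletons = [c for c in s.clades if len(c) == 1]
                assert len(singletons) == len(set(singletons)) == len(s.species)


class TestStrictDistance:
    def test_identical_trees_distance_zero(self):
        a = tree("((Aa_1,Bb_1),(Cc_1,Dd_1));")
        assert strict_distance(a, a) == 0.0

    def test_conflicting_quartets_distance_one(self):
        a = tree("((Aa_1,Bb_1),(Cc_1,Dd_1));")
        b = tree("((Aa_1,Cc_1),(Bb_1,Dd_1));")
        assert strict_distance(a, b) == 1.0

    def test_three_shared_species_is_na(self):
        a = tree("((Aa_1,Bb_1),(Cc_1,Gg_1));")
        b = tree("((Aa_1,Bb_1),(Cc_1,Hh_1));")
        assert np.isnan(strict_distance(a, b))

    def test_symmetry_and_range_on_random_trees(self):
        trees = simulate_independent_genes(6, 8, seed=11)
        for i in range(len(trees)):
            for j in range(i + 1, len(trees)):
                d1 = strict_distance(trees[i], trees[j])
                d2 = strict_distance(trees[j], trees[i])
                assert d1 == d2
                assert 0.0 <= d1 <= 1.0

    def test_agrees_with_independent_rf_oracle(self):
        """Normalized RF against dendropy's bipartition-based computation."""
        import dendropy
        from dendropy.calculate import treecompare

        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(4, 9))
            a, b = simulate_independent_genes(2, n, seed=int(rng.integers(2**31)))
            tns = dendropy.TaxonNamespace()
            # compare in species space: strip the per-gene label suffix
            da = dendropy.Tree.get(
                data=a.to_newick().replace("_g1", ""), schema="newick",
                taxon_namespace=tns,
            )
            db = dendropy.Tree.get(
                data=b.to_newick().replace("_g2", ""), schema="newick",
                taxon_namespace=tns,
            )
            for t in (da, db):
                t.is_rooted = False
                t.update_bipartitions()
            rf = treecompare.symmetric_difference(da, db)
            expected = rf / (2 * (n - 3)) if n > 3 else 0.0
            assert strict_distance(a, b) == pytest.approx(expected, abs=1e-12)


class TestEvolutionaryDistance:
    def test_identical_trees_identical_species_sets(self):
        a = tree("((Aa_1,Bb_1),(Cc_1,Dd_1));")
        assert evolutionary_distance(a, a) == 0.0

    def test_extra_species_penalised(self):
        # same topology on the 4 shared species; one tree carries 2 extra of 6
        p = tree("((Aa_1,Bb_1),(Cc_1,Dd_1));")
        q = tree("(((Aa_1,Bb_1),(Cc_1,Dd_1)),(Ee_1,Ff_1));")
        assert evolutionary_distance(p, q) == pytest.approx(1 - 4 / 6)

    def test_equals_strict_when_species_sets_coincide(self):
        trees = simulate_independent_genes(4, 9, seed=3)
        for i in range(len(trees)):
            for j in range(i + 1, len(trees)):
                assert evolutionary_distance(trees[i], trees[j]) == pytest.approx(
                    strict_distance(trees[i], trees[j])
                )

    def test_range_and_symmetry(self):
        fam = simulate_coevolved_family(
            simulate_species_tree(9, seed=2), 4,
            SyntheticFamilyConfig(n_species=9, duplication_rate=0.2, seed=2),
        )
        for i in range(4):
            for j in range(i + 1, 4):
                d = evolutionary_distance(fam[i], fam[j])
                assert d == evolutionary_distance(fam[j], fam[i])
                assert 0.0 <= d <= 1.0


class TestPairwiseMatrices:
    def test_identical_trees_give_zero_matrix(self):
        base = tree("((Aa_1,Bb_1),(Cc_1,Dd_1));", "g1")
        copies = [
            tree("((Aa_1,Bb_1),(Cc_1,Dd_1));", f"g{i}") for i in range(1, 4)
        ]
        mats = pairwise_matrices(copies)
        assert np.allclose(mats.strict, 0.0)
        assert np.allclose(mats.evolutionary, 0.0)

    def test_fewer_than_two_trees_rejected(self):
        with pytest.raises(ValueError):
            pairwise_matrices([tree("(Aa_1,Bb_1);")])

    def test_permutation_invariance(self):
        trees = simulate_independent_genes(5, 8, seed=7)
        mats = pairwise_matrices(trees)
        perm = [3, 1, 4, 0, 2]
        mats_p = pairwise_matrices([trees[i] for i in perm])
        assert np.allclose(mats.strict[np.ix_(perm, perm)], mats_p.strict)
        assert mats_p.gene_ids == [trees[i].gene_id for i in perm]

    def test_entries_match_pairwise_calls(self):
        trees = simulate_independent_genes(4, 8, seed=9)
        mats = pairwise_matrices(trees)
        assert mats.strict[0, 2] == strict_distance(trees[0], trees[2])
        assert mats.evolutionary[1, 3] == evolutionary_distance(trees[1], trees[3])

    def test_tsv_round_trip_with_na(self, tmp_path):
        mats = DistanceMatrixSet(
            gene_ids=["a", "b", "c"],
            strict=np.array([[0, 0.5, np.nan], [0.5, 0, 1.0], [np.nan, 1.0, 0]]),
            evolutionary=np.zeros((3, 3)),
        )
        path = tmp_path / "strict.tsv"
        mats.write_tsv("strict", path)
        assert "NA" in path.read_text()
        df = DistanceMatrixSet.matrix_from_tsv(path)
        assert list(df.index) == ["a", "b", "c"]
        assert np.isnan(df.iloc[0, 2])
        assert df.iloc[1, 0] == 0.5
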