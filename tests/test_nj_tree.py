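import dendropy
import numpy as np
import pytest

from barcodeid import (
    bootstrap_support,
    build_nj_tree,
    check_monophyly,
    nj_tree_from_alignment,
    read_newick,
    write_newick,
)
from barcodeid.distance import DistanceMatrix
from barcodeid.nj_tree import PhyloTree

from conftest import make_alignment


def matrix(ids, values):
    return DistanceMatrix(ids=list(ids), values=np.asarray(values, dtype=float))


def tree_from_newick(s):
    return PhyloTree(tree=dendropy.Tree.get(data=s, schema="newick"))


def random_additive_matrix(rng, n_taxa):
    """Random additive (tree-metric) matrix built from path sums on a
    random binary tree; returns (ids, matrix, splits of the true tree)."""
    labels = [f"t{i:02d}" for i in range(n_taxa)]
    # cluster structure: each active node holds {leaf: distance to node}
    active = [{lab: 0.0} for lab in labels]
    D = {}
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        li = 0.05 + rng.random() * 0.5
        lj = 0.05 + rng.random() * 0.5
        a, b = active[i], active[j]
        for la, da in a.items():
            for lb, db in b.items():
                D[frozenset((la, lb))] = da + li + db + lj
        merged = {k: v + li for k, v in a.items()}
        merged.update({k: v + lj for k, v in b.items()})
        active = [active[k] for k in range(len(active)) if k not in (i, j)]
        active.append(merged)
    values = np.zeros((n_taxa, n_taxa))
    for x in range(n_taxa):
        for y in range(x + 1, n_taxa):
            values[x, y] = values[y, x] = D[frozenset((labels[x], labels[y]))]
    return labels, values


class TestBuildNJ:
    def test_three_taxon_closed_form(self):
        m = matrix(["A", "B", "C"],
                   [[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]])
        tree = build_nj_tree(m)
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.tree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx(0.05)
        assert lengths["B"] == pytest.approx(0.15)
        assert lengths["C"] == pytest.approx(0.25)

    def test_four_taxon_additive_topology_and_lengths(self):
        # tree ((A:0.1,B:0.2):0.05,C:0.15,D:0.3) -> path-sum matrix
        ids = ["A", "B", "C", "D"]
        v = np.array([
            [0, 0.3, 0.3, 0.45],
            [0.3, 0, 0.4, 0.55],
            [0.3, 0.4, 0, 0.45],
            [0.45, 0.55, 0.45, 0],
        ])
        tree = build_nj_tree(matrix(ids, v))
        assert tree.splits() == {frozenset({"C", "D"})} or \
               tree.splits() == {frozenset({"A", "B"})}
        pdm = tree.tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.tree.taxon_namespace}
        for x in range(4):
            for y in range(x + 1, 4):
                assert pdm.patristic_distance(taxa[ids[x]], taxa[ids[y]]) == \
                       pytest.approx(v[x, y], abs=1e-9)

    @pytest.mark.parametrize("n_taxa", [4, 6, 8, 12])
    def test_recovers_random_additive_trees_exactly(self, n_taxa):
        rng = np.random.default_rng(100 + n_taxa)
        for _ in range(3):
            ids, v = random_additive_matrix(rng, n_taxa)
            tree = build_nj_tree(matrix(ids, v))
            pdm = tree.tree.phylogenetic_distance_matrix()
            taxa = {t.label: t for t in tree.tree.taxon_namespace}
            for x in range(n_taxa):
                for y in range(x + 1, n_taxa):
                    assert pdm.patristic_distance(taxa[ids[x]], taxa[ids[y]]) \
                        == pytest.approx(v[x, y], abs=1e-9)

    def test_agrees_with_scikit_bio_on_random_additive_matrix(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(55)
        ids, v = random_additive_matrix(rng, 7)
        ours = build_nj_tree(matrix(ids, v)).splits()
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(v, ids))
        all_leaves = frozenset(ids)
        ref = min(all_leaves)
        theirs = set()
        for node in sk_tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if ref in side:
                side = all_leaves - side
            if 1 < len(side) < len(ids) - 1:
                theirs.add(side)
        assert ours == theirs

    def test_zero_matrix_yields_zero_branch_lengths(self):
        m = matrix(list("ABCD"), np.zeros((4, 4)))
        tree = build_nj_tree(m)
        for edge in tree.tree.preorder_edge_iter():
            assert not edge.length or edge.length == pytest.approx(0.0)

    def test_deterministic_under_ties(self):
        m = matrix(list("ABCD"), np.zeros((4, 4)))
        s1 = build_nj_tree(m).as_newick()
        s2 = build_nj_tree(m).as_newick()
        assert s1 == s2

    def test_missing_entry_names_the_pair(self):
        v = np.zeros((3, 3))
        v[0, 1] = v[1, 0] = np.nan
        with pytest.raises(ValueError, match="'A'.*'B'"):
            build_nj_tree(matrix(list("ABC"), v))


class TestBootstrap:
    def test_two_clear_clusters_get_full_support(self):
        a = "A" * 30 + "C" * 30
        b = "A" * 30 + "C" * 27 + "T" * 3
        c = "A" * 15 + "G" * 15 + "C" * 30
        d = "A" * 15 + "G" * 15 + "C" * 24 + "T" * 3 + "C" * 3
        aln = make_alignment(
            [("a1", "A", a), ("a2", "A", a), ("a3", "A", b),
             ("c1", "C", c), ("c2", "C", c), ("c3", "C", d)]
        )
        tree = bootstrap_support(aln, n_replicates=50, seed=4)
        cluster_split = frozenset({"c1", "c2", "c3"})
        assert tree.supports[cluster_split] == 100.0

    def test_single_replicate_supports_are_zero_or_hundred(self):
        rng = np.random.default_rng(1)
        from conftest import random_clean_alignment
        aln = random_clean_alignment(rng, 6, 80)
        tree = bootstrap_support(aln, n_replicates=1, seed=9)
        assert set(tree.supports.values()) <= {0.0, 100.0}

    def test_reproducible_given_seed(self, two_species_alignment):
        aln = two_species_alignment
        t1 = bootstrap_support(aln, n_replicates=20, seed=42)
        t2 = bootstrap_support(aln, n_replicates=20, seed=42)
        assert t1.supports == t2.supports


class TestMonophyly:
    def test_clean_clade_is_monophyletic(self):
        t = tree_from_newick("(((A1,A2),B1),OUT);")
        flags = check_monophyly(
            t, {"A": ["A1", "A2"], "B": ["B1"], "Out": ["OUT"]},
            outgroup_species="Out")
        assert flags == {"A": True, "B": True}

    def test_interleaved_species_are_not_monophyletic(self):
        t = tree_from_newick("(((A1,B1),(A2,B2)),OUT);")
        flags = check_monophyly(
            t, {"A": ["A1", "A2"], "B": ["B1", "B2"], "Out": ["OUT"]},
            outgroup_species="Out")
        assert flags == {"A": False, "B": False}

    def test_species_spanning_the_outgroup_side_is_rejected(self):
        # A1+A2 are a split side only together with the outgroup leaf
        t = tree_from_newick("((A1,OUT),(A2,(B1,B2)));")
        flags = check_monophyly(
            t, {"A": ["A1", "A2"], "B": ["B1", "B2"], "Out": ["OUT"]},
            outgroup_species="Out")
        assert flags["A"] is False and flags["B"] is True

    def test_missing_species_leaves_raise(self):
        t = tree_from_newick("((A1,A2),OUT);")
        with pytest.raises(ValueError):
            check_monophyly(t, {"A": ["A1", "ZZ"], "Out": ["OUT"]},
                            outgroup_species="Out")


class TestNewickIO:
    def test_three_taxon_newick_string(self):
        m = matrix(["A", "B", "C"],
                   [[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]])
        tree = build_nj_tree(m)
        s = tree.as_newick()
        assert s.endswith(";")
        # same topology and branch lengths as the closed-form tree
        ref = dendropy.Tree.get(data="(A:0.05,B:0.15,C:0.25);", schema="newick",
                                taxon_namespace=tree.tree.taxon_namespace)
        pdm1 = tree.tree.phylogenetic_distance_matrix()
        pdm2 = ref.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.tree.taxon_namespace}
        for x, y in (("A", "B"), ("A", "C"), ("B", "C")):
            assert pdm1.patristic_distance(taxa[x], taxa[y]) == pytest.approx(
                pdm2.patristic_distance(taxa[x], taxa[y]), abs=1e-12)

    def test_round_trip_preserves_lengths_and_supports(self, tmp_path):
        aln = make_alignment(
            [("a1", "A", "AAAAACCCCCGGGGG"), ("a2", "A", "AAAAACCCCCGGGGT"),
             ("b1", "B", "TTTAACCCGGGGGGG"), ("b2", "B", "TTTAACCCGGGGGGC")]
        )
        tree = bootstrap_support(aln, n_replicates=10, seed=0)
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        assert set(back.leaf_ids) == set(tree.leaf_ids)
        assert back.splits() == tree.splits()
        for split, support in (back.supports or {}).items():
            assert support == pytest.approx(tree.supports[split], abs=0.5)
        pdm1 = tree.tree.phylogenetic_distance_matrix()
        pdm2 = back.tree.phylogenetic_distance_matrix()
        t1 = {t.label: t for t in tree.tree.taxon_namespace}
        t2 = {t.label: t for t in back.tree.taxon_namespace}
        for x in ("a1", "a2", "b1"):
            for y in ("b2",):
                assert pdm1.patristic_distance(t1[x], t1[y]) == pytest.approx(
                    pdm2.patristic_distance(t2[x], t2[y]), abs=1e-9)
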