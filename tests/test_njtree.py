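import io

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from ytriage import njtree
from ytriage.njtree import DistanceMatrix, TreeNode


def random_additive_tree(rng, n):
    """A random binary tree with branch lengths in [0.01, 0.5]."""
    nodes = [TreeNode(name=f"t{i}") for i in range(n)]
    while len(nodes) > 3:
        j = int(rng.integers(1, len(nodes)))
        i = int(rng.integers(0, j))
        b, a = nodes.pop(j), nodes.pop(i)
        for node in (a, b):
            node.length = float(rng.uniform(0.01, 0.5))
        nodes.append(TreeNode(children=[a, b]))
    for node in nodes:
        node.length = float(rng.uniform(0.01, 0.5))
    return TreeNode(children=nodes)


def rf_distance(newick_a: str, newick_b: str) -> int:
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns)
    tb = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return treecompare.symmetric_difference(ta, tb)


class TestPDistance:
    def test_identical_pair(self):
        dm = njtree.p_distance([("a", "ACGT"), ("b", "ACGT")])
        assert dm.d[0, 1] == 0.0

    def test_single_mismatch(self):
        dm = njtree.p_distance([("a", "ACGT"), ("b", "ACGA")])
        assert dm.d[0, 1] == pytest.approx(0.25)

    def test_gap_and_n_columns_excluded(self):
        dm = njtree.p_distance([("a", "AC-TNG"), ("b", "ACGTAG")])
        # comparable columns: A,C,T,G -> 0 mismatches over 4
        assert dm.d[0, 1] == 0.0

    def test_matches_exhaustive_count(self, rng):
        bases = np.array(list("ACGT-N"))
        seqs = ["".join(rng.choice(bases, size=300)) for _ in range(4)]
        named = [(f"s{i}", s) for i, s in enumerate(seqs)]
        dm = njtree.p_distance(named)
        for i in range(4):
            for j in range(i + 1, 4):
                mism = total = 0
                for x, y in zip(seqs[i], seqs[j]):
                    if x in "-N" or y in "-N":
                        continue
                    total += 1
                    mism += x != y
                assert dm.d[i, j] == pytest.approx(mism / total)

    def test_no_comparable_columns_rejected(self):
        with pytest.raises(ValueError, match="no comparable columns"):
            njtree.p_distance([("a", "NNNN"), ("b", "ACGT")])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            njtree.p_distance([("a", "ACG"), ("b", "ACGT")])

    def test_jukes_cantor_monotone(self):
        dm = njtree.p_distance([("a", "A" * 80 + "C" * 20), ("b", "A" * 100)])
        jc = njtree.jukes_cantor(dm)
        assert jc.d[0, 1] > dm.d[0, 1]


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 6.0], [4.0, 6.0, 0.0]])
        tree = njtree.neighbor_joining(DistanceMatrix(("a", "b", "c"), d))
        back = njtree.leaf_distance_matrix(tree, ("a", "b", "c"))
        assert np.allclose(back.d, d)

    def test_additive_four_taxon_exact(self):
        # tree: ((a:1,b:2):1,(c:3,d:4)) -> pairwise path lengths
        d = np.array(
            [
                [0.0, 3.0, 5.0, 6.0],
                [3.0, 0.0, 6.0, 7.0],
                [5.0, 6.0, 0.0, 7.0],
                [6.0, 7.0, 7.0, 0.0],
            ]
        )
        tree = njtree.neighbor_joining(DistanceMatrix(("a", "b", "c", "d"), d))
        back = njtree.leaf_distance_matrix(tree, ("a", "b", "c", "d"))
        assert np.allclose(back.d, d, atol=1e-12)

    @pytest.mark.parametrize("trial", range(8))
    def test_additive_recovery_up_to_twelve_taxa(self, trial):
        rng = np.random.default_rng(500 + trial)
        n = int(rng.integers(4, 13))
        source = random_additive_tree(rng, n)
        taxa = tuple(sorted(source.leaf_names()))
        dm = njtree.leaf_distance_matrix(source, taxa)
        rebuilt = njtree.neighbor_joining(dm)
        back = njtree.leaf_distance_matrix(rebuilt, taxa)
        assert np.allclose(back.d, dm.d, atol=1e-9)

    def test_tie_breaks_to_lowest_index_pair(self):
        d = np.full((4, 4), 2.0)
        np.fill_diagonal(d, 0.0)
        tree = njtree.neighbor_joining(DistanceMatrix(("a", "b", "c", "d"), d))
        first = tree.newick()
        assert "(a:" in first and "b:" in first.split(")")[0]
        assert tree.newick() == njtree.neighbor_joining(DistanceMatrix(("a", "b", "c", "d"), d)).newick()

    def test_leaf_permutation_isomorphic(self):
        rng = np.random.default_rng(77)
        source = random_additive_tree(rng, 8)
        taxa = tuple(sorted(source.leaf_names()))
        dm = njtree.leaf_distance_matrix(source, taxa)
        perm = list(rng.permutation(len(taxa)))
        dm_perm = DistanceMatrix(tuple(taxa[i] for i in perm), dm.d[np.ix_(perm, perm)])
        assert rf_distance(njtree.neighbor_joining(dm).newick(), njtree.neighbor_joining(dm_perm).newick()) == 0

    def test_matches_reference_nj_topology(self):
        rng = np.random.default_rng(123)
        source = random_additive_tree(rng, 9)
        taxa = tuple(sorted(source.leaf_names()))
        dm = njtree.leaf_distance_matrix(source, taxa)
        noisy = dm.d + rng.normal(0, 0.005, dm.d.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0.0)
        noisy = np.abs(noisy)
        mine = njtree.neighbor_joining(DistanceMatrix(taxa, noisy)).newick()
        header = "x," + ",".join(taxa)
        rows = [f"{t}," + ",".join(f"{v:.10f}" for v in noisy[i]) for i, t in enumerate(taxa)]
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=io.StringIO(header + "\n" + "\n".join(rows) + "\n"), delimiter=","
        )
        reference = pdm.nj_tree().as_string(schema="newick", suppress_rooting=True)
        assert rf_distance(mine, reference) == 0

    def test_asymmetric_input_rejected(self):
        d = np.array([[0.0, 1.0, 2.0], [1.5, 0.0, 1.0], [2.0, 1.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(("a", "b", "c"), d)

    def test_fewer_than_three_taxa_rejected(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="at least 3"):
            njtree.neighbor_joining(DistanceMatrix(("a", "b"), d))


class TestRooting:
    def test_midpoint_two_leaf_tree_halves_branch(self):
        a = TreeNode(name="a")
        b = TreeNode(name="b", length=4.0)
        a.children = [b]
        rooted = njtree.root_tree(a, midpoint=True)
        lengths = sorted(c.length for c in rooted.children)
        assert lengths == pytest.approx([2.0, 2.0])

    def test_outgroup_rooting_makes_ingroup_monophyletic(self):
        # camelid-like pair closest to each other, distant from the rest
        d = np.array(
            [
                [0.0, 0.1, 0.8, 0.9],
                [0.1, 0.0, 0.8, 0.9],
                [0.8, 0.8, 0.0, 0.3],
                [0.9, 0.9, 0.3, 0.0],
            ]
        )
        taxa = ("camel1", "camel2", "human", "mouse")
        tree = njtree.neighbor_joining(DistanceMatrix(taxa, d))
        rooted = njtree.root_tree(tree, outgroup={"camel1", "camel2"})
        sides = [set(c.leaf_names()) for c in rooted.children]
        assert {"human", "mouse"} in sides and {"camel1", "camel2"} in sides

    def test_outgroup_must_be_proper_subset(self):
        tree = njtree.neighbor_joining(
            DistanceMatrix(("a", "b", "c"), np.array([[0, 1, 2], [1, 0, 2], [2, 2, 0]], dtype=float))
        )
        with pytest.raises(ValueError, match="every taxon"):
            njtree.root_tree(tree, outgroup={"a", "b", "c"})

    def test_non_monophyletic_outgroup_names_split(self):
        rng = np.random.default_rng(9)
        source = random_additive_tree(rng, 6)
        taxa = tuple(sorted(source.leaf_names()))
        dm = njtree.leaf_distance_matrix(source, taxa)
        tree = njtree.neighbor_joining(dm)
        # pick two leaves that are not siblings in the built tree
        for bad in [{taxa[0], taxa[3]}, {taxa[1], taxa[4]}]:
            try:
                rooted = njtree.root_tree(tree, outgroup=bad)
            except ValueError as exc:
                assert "not monophyletic" in str(exc) and "split" in str(exc)
                break
        else:
            pytest.skip("both candidate outgroups happened to be clades")

    def test_fixture_homologs_midpoint_separates_camelids(self, small_fixture):
        dm = njtree.p_distance(small_fixture.homolog_alignment)
        rooted = njtree.root_tree(njtree.neighbor_joining(dm), midpoint=True)
        sides = [set(c.leaf_names()) for c in rooted.children]
        camelids = {t for t in dm.taxa if "human" not in t and "mouse" not in t}
        assert camelids in sides

    def test_outgroup_rooting_on_fixture_homologs(self, small_fixture):
        dm = njtree.p_distance(small_fixture.homolog_alignment)
        tree = njtree.neighbor_joining(dm)
        rooted = njtree.root_tree(tree, outgroup={"human_Y", "mouse_Y"})
        sides = [set(c.leaf_names()) for c in rooted.children]
        assert {"human_Y", "mouse_Y"} in sides
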