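"""Trimming, distances, neighbor joining, bootstrap, consensus, clade calls."""

import io
import math

import dendropy
import numpy as np
import pytest
from conftest import (
    path_distances,
    random_additive_tree,
    tree_splits_from_adjacency,
)

from tetrarab.phylo import (
    AlignmentTooShortError,
    DistanceMatrix,
    InfiniteDistanceError,
    MsAlignment,
    TrimConfig,
    bootstrap_support,
    classify_conservation,
    compute_distances,
    majority_consensus,
    neighbor_joining,
    read_newick,
    smallest_supported_clade,
    tree_splits,
    trim_alignment,
    write_newick,
)
from tetrarab.simulate import rab_scaffold_protein, simulate_family


def _splits(tree) -> set:
    return set(tree_splits(tree))


class TestTrimAlignment:
    def test_gapless_alignment_with_zero_trim_is_identity(self):
        aln = MsAlignment(["a", "b"], ["MKVLITGAGQ", "MKVLITGAGW"])
        out = trim_alignment(aln, TrimConfig(cterm_trim=0))
        assert out.rows == aln.rows

    def test_single_gap_column_removed(self):
        aln = MsAlignment(["a", "b"], ["MKVLITGAG-Q", "MKVLITGAGWQ"])
        out = trim_alignment(aln, TrimConfig(cterm_trim=0))
        assert out.ncols == aln.ncols - 1
        assert out.rows == ["MKVLITGAGQ", "MKVLITGAGQ"]

    def test_auto_trim_removes_planted_hypervariable_tails(self):
        rng = np.random.default_rng(0)
        root, _ = rab_scaffold_protein(rng, tail_length=0, terminal="SNLL")
        tree = "((a:0.02,b:0.02):0.02,c:0.02,d:0.02);"
        aln, _ = simulate_family(tree, seed=1, root_seq=root, tail_length=40)
        out = trim_alignment(aln)
        assert out.ncols <= aln.ncols - 40
        # the motif region itself survives
        assert out.ncols >= 28

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        root, _ = rab_scaffold_protein(rng, tail_length=0, terminal="SNLL")
        aln, _ = simulate_family(
            "((a:0.05,b:0.05):0.05,c:0.05,d:0.05);", seed=2,
            root_seq=root, tail_length=35,
        )
        once = trim_alignment(aln)
        twice = trim_alignment(once)
        assert twice.rows == once.rows

    def test_overtrimming_raises(self):
        aln = MsAlignment(["a", "b"], ["MKVLITGAGQ", "MKVLITGAGW"])
        with pytest.raises(AlignmentTooShortError):
            trim_alignment(aln, TrimConfig(cterm_trim=5))


class TestDistances:
    def test_identical_rows_have_zero_distance(self):
        aln = MsAlignment(list("abc"), ["MKVL" * 3] * 3)
        assert compute_distances(aln).matrix.sum() == 0.0

    def test_p_distance_hand_count(self):
        aln = MsAlignment(
            list("abc"), ["AAAAAAAAAA", "AAAAAAAACC", "AAAAAAAAAA"]
        )
        d = compute_distances(aln, "p")
        assert d.matrix[0, 1] == pytest.approx(0.2)

    def test_poisson_closed_form(self):
        aln = MsAlignment(
            list("abc"), ["AAAAAAAAAA", "AAAAAAAACC", "AAAAAAAAAA"]
        )
        d = compute_distances(aln, "poisson")
        assert d.matrix[0, 1] == pytest.approx(-math.log(0.8))

    def test_pairwise_deletion_ignores_gapped_sites(self):
        aln = MsAlignment(list("abc"), ["A-AAA", "AAAAC", "AAAAA"])
        d = compute_distances(aln, "p")
        assert d.matrix[0, 1] == pytest.approx(0.25)  # 4 compared, 1 mismatch

    def test_saturated_poisson_raises(self):
        aln = MsAlignment(list("abc"), ["AAAA", "CCCC", "AAAA"])
        with pytest.raises(InfiniteDistanceError):
            compute_distances(aln, "poisson")


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = DistanceMatrix(list("abc"), np.array(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]], float
        ))
        tree = neighbor_joining(d)
        lengths = {
            l.taxon.label: l.edge.length for l in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # topology ((a,b),(c,d)) with explicit branch lengths
        d = DistanceMatrix(
            list("abcd"),
            np.array(
                [[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]],
                float,
            ),
        )
        tree = neighbor_joining(d)
        assert _splits(tree) == {frozenset({"c", "d"})}
        pdm = tree.phylogenetic_distance_matrix()
        tns = tree.taxon_namespace
        for i, x in enumerate("abcd"):
            for j, y in enumerate("abcd"):
                if i < j:
                    assert pdm.patristic_distance(
                        tns.get_taxon(x), tns.get_taxon(y)
                    ) == pytest.approx(d.matrix[i, j], abs=1e-9)

    def test_equidistant_taxa_deterministic(self):
        d = np.full((4, 4), 1.0)
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(list("abcd"), d)
        first = write_newick(neighbor_joining(dm))
        for _ in range(3):
            assert write_newick(neighbor_joining(dm)) == first

    def test_additive_matrices_recovered_on_random_trees(self):
        """NJ is exact on additive distances (randomized oracle, n<=12)."""
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.integers(4, 13))
            adj, leaves = random_additive_tree(rng, n)
            d = path_distances(adj, leaves)
            tree = neighbor_joining(DistanceMatrix(list(leaves), d))
            assert _splits(tree) == tree_splits_from_adjacency(adj, leaves)
            pdm = tree.phylogenetic_distance_matrix()
            tns = tree.taxon_namespace
            for i in range(n):
                for j in range(i + 1, n):
                    assert pdm.patristic_distance(
                        tns.get_taxon(leaves[i]), tns.get_taxon(leaves[j])
                    ) == pytest.approx(d[i, j], abs=1e-9)

    def test_agrees_with_dendropy_nj_topology(self):
        """Independent cross-check against dendropy's NJ implementation."""
        rng = np.random.default_rng(5)
        for _ in range(5):
            adj, leaves = random_additive_tree(rng, 8)
            d = path_distances(adj, leaves)
            mine = neighbor_joining(DistanceMatrix(list(leaves), d))
            csv = "," + ",".join(leaves) + "\n" + "\n".join(
                leaves[i] + "," + ",".join(str(v) for v in d[i])
                for i in range(len(leaves))
            )
            pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
                io.StringIO(csv), delimiter=","
            )
            theirs = pdm.nj_tree()
            their_splits = {
                frozenset(
                    sorted(l.taxon.label for l in nd.leaf_iter())
                )
                for nd in theirs.preorder_node_iter()
                if not nd.is_leaf() and nd.parent_node is not None
            }
            # canonicalize to the side not containing the reference leaf
            leafset = frozenset(leaves)
            ref = min(leafset)
            canon = {
                frozenset(leafset - s) if ref in s else s
                for s in their_splits
                if 1 < len(s) < len(leafset) - 1
            }
            assert _splits(mine) == canon

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(list("ab"), np.array([[0, 1], [2, 0]], float))
        with pytest.raises(ValueError):
            DistanceMatrix(list("ab"), np.array([[0, -1], [-1, 0]], float))


class TestBootstrap:
    def test_congruent_alignment_gives_full_support(self):
        # every column supports the split {a,b} | {c,d,e}
        aln = MsAlignment(
            list("abcde"),
            ["AAAA" * 10, "AAAG" * 10, "CCCC" * 10, "CCCG" * 10, "CCGG" * 10],
        )
        tree = bootstrap_support(aln, n_reps=100, seed=0)
        supports = {
            frozenset(s): float(node.label)
            for s, node in tree_splits(tree).items()
        }
        # canonical key: the split side not containing the reference leaf "a"
        assert supports[frozenset({"c", "d", "e"})] == 100.0

    def test_supports_within_bounds_and_seed_reproducible(self):
        aln, _ = simulate_family(
            "((a:0.2,b:0.2):0.1,(c:0.2,d:0.2):0.1,e:0.3);", seed=4,
            seq_length=120,
        )
        t1 = bootstrap_support(aln, n_reps=50, seed=9)
        t2 = bootstrap_support(aln, n_reps=50, seed=9)
        assert write_newick(t1) == write_newick(t2)
        for _, node in tree_splits(t1).items():
            assert 0.0 <= float(node.label) <= 100.0

    def test_true_splits_outscore_false_ones_on_simulated_family(self):
        gen = "((a:0.15,b:0.15):0.1,((c:0.15,d:0.15):0.1,(e:0.1,f:0.1):0.1)" \
              ":0.05,(g:0.15,h:0.15):0.1);"
        aln, _ = simulate_family(gen, rate=1.0, seed=8, seq_length=300)
        tree = bootstrap_support(aln, n_reps=100, seed=8)
        true_splits = _splits(read_newick(gen))
        supports = {
            s: float(node.label) for s, node in tree_splits(tree).items()
        }
        true_sup = [v for s, v in supports.items() if s in true_splits]
        false_sup = [v for s, v in supports.items() if s not in true_splits]
        assert true_sup and np.mean(true_sup) > (
            np.mean(false_sup) if false_sup else 0.0
        )

    def test_invalid_rep_count(self):
        aln = MsAlignment(list("abc"), ["AAAA", "AAAC", "CCCC"])
        with pytest.raises(ValueError):
            bootstrap_support(aln, n_reps=0)


class TestConsensus:
    def test_identical_trees_full_support(self):
        trees = [read_newick("((a,b),(c,d),e);") for _ in range(3)]
        cons = majority_consensus(trees)
        assert _splits(cons) == _splits(trees[0])
        for _, node in tree_splits(cons).items():
            assert float(node.label) == 100.0

    def test_two_of_three_split_retained_at_66_7(self):
        trees = [
            read_newick("((a,b),(c,d),e);"),
            read_newick("((a,b),(c,e),d);"),
            read_newick("((a,c),(b,d),e);"),
        ]
        cons = majority_consensus(trees)
        supports = {s: float(n.label) for s, n in tree_splits(cons).items()}
        # {a,b}|{c,d,e} is in trees 1 and 2; canonically keyed by {c,d,e}
        assert supports == {
            frozenset({"c", "d", "e"}): pytest.approx(200 / 3, abs=0.05)
        }

    def test_incompatible_quartet_resolutions_give_star(self):
        trees = [
            read_newick("((a,b),(c,d));"),
            read_newick("((a,c),(b,d));"),
            read_newick("((a,d),(b,c));"),
        ]
        cons = majority_consensus(trees)
        assert _splits(cons) == set()

    def test_mismatched_leaf_sets_rejected(self):
        with pytest.raises(ValueError):
            majority_consensus(
                [read_newick("((a,b),c,d);"), read_newick("((a,b),c,e);")]
            )


class TestConservationClassification:
    @pytest.fixture
    def lineage(self):
        return {
            "q": "ciliate", "p1": "ciliate", "p2": "ciliate",
            "hs": "human", "dm": "fly", "at": "plant",
        }

    def test_query_with_supported_human_neighbor_is_conserved(self, lineage):
        trees = [
            read_newick("((q:1,hs:1)90:1,(p1:1,p2:1)85:1,(dm:1,at:1)80:1);")
            for _ in range(3)
        ]
        (call,) = classify_conservation(["q"], trees, lineage)
        assert call.status == "conserved"
        assert call.supporting_methods == 3
        assert all(m == frozenset({"q", "hs"}) for m in call.clade_members)

    def test_query_grouping_only_with_ciliates_is_lineage_restricted(
        self, lineage
    ):
        trees = [
            read_newick("((q:1,p1:1)95:1,(hs:1,dm:1)85:1,(p2:1,at:1)80:1);")
            for _ in range(3)
        ]
        (call,) = classify_conservation(["q"], trees, lineage)
        assert call.status == "lineage-restricted"

    def test_unsupported_attachment_is_divergent(self, lineage):
        trees = [
            read_newick("((q:1,hs:1)30:1,(p1:1,p2:1)85:1,(dm:1,at:1)80:1);")
            for _ in range(3)
        ]
        (call,) = classify_conservation(["q"], trees, lineage)
        assert call.status == "divergent"

    def test_two_of_three_quorum(self, lineage):
        conserved_tree = read_newick(
            "((q:1,hs:1)90:1,(p1:1,p2:1)85:1,(dm:1,at:1)80:1);"
        )
        restricted_tree = read_newick(
            "((q:1,p1:1)95:1,(hs:1,dm:1)85:1,(p2:1,at:1)80:1);"
        )
        (call,) = classify_conservation(
            ["q"], [conserved_tree, conserved_tree, restricted_tree], lineage
        )
        assert call.status == "conserved" and call.supporting_methods == 2

    def test_invariant_to_tree_order_and_leaf_permutation(self, lineage):
        t1 = read_newick("((q:1,hs:1)90:1,(p1:1,p2:1)85:1,(dm:1,at:1)80:1);")
        t2 = read_newick("((hs:1,q:1)90:1,(at:1,dm:1)80:1,(p2:1,p1:1)85:1);")
        t3 = read_newick("((q:1,p1:1)95:1,(hs:1,dm:1)85:1,(p2:1,at:1)80:1);")
        a = classify_conservation(["q"], [t1, t2, t3], lineage)[0]
        b = classify_conservation(["q"], [t3, t2, t1], lineage)[0]
        assert a.status == b.status == "conserved"

    def test_query_absent_from_tree_raises(self, lineage):
        tree = read_newick("((p1:1,p2:1)85:1,hs:1,dm:1);")
        with pytest.raises(ValueError):
            smallest_supported_clade(tree, "q")
        with pytest.raises(ValueError):
            classify_conservation(["q"], [], lineage)


class TestNewickRoundTrip:
    def test_topology_lengths_and_supports_preserved(self, tmp_path):
        aln, _ = simulate_family(
            "((a:0.2,b:0.2):0.1,(c:0.2,d:0.2):0.1,e:0.3);", seed=6,
            seq_length=100,
        )
        tree = bootstrap_support(aln, n_reps=25, seed=1)
        path = tmp_path / "t.nwk"
        write_newick(tree, str(path))
        back = read_newick(str(path))
        assert _splits(back) == _splits(tree)
        orig = {s: float(n.label) for s, n in tree_splits(tree).items()}
        reread = {s: float(n.label) for s, n in tree_splits(back).items()}
        assert reread == orig
        for leaf in tree.leaf_node_iter():
            twin = [
                l for l in back.leaf_node_iter()
                if l.taxon.label == leaf.taxon.label
            ][0]
            assert twin.edge.length == pytest.approx(leaf.edge.length, abs=1e-6)

    def test_phylip_relaxed_input(self, tmp_path):
        path = tmp_path / "aln.phy"
        path.write_text(" 3 8\nseqA  MKVLITGA\nseqB  MKVLITGC\nseqC  MKVLITGW\n")
        aln = MsAlignment.from_phylip(str(path))
        assert aln.ids == ["seqA", "seqB", "seqC"]
        assert aln.ncols == 8
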