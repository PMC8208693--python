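import itertools
import random

import networkx as nx
import pytest

from hgt_evidence.phylo_congruence import (CongruenceResult, TreeError,
                                           collapse_low_support,
                                           congruence_check, distance_matrix,
                                           parse_newick, patristic_distance,
                                           write_newick)


def random_tree_edges(rng, n_leaves):
    """Random binary tree built directly as an edge list (independent of
    any Newick parsing); returns (newick, edges, leaf names)."""
    counter = itertools.count()
    nodes = [(f"L{i}", f"L{i}:{round(rng.uniform(0.1, 3.0), 3)}")
             for i in range(n_leaves)]
    edges = []

    def new_internal():
        return f"I{next(counter)}"

    while len(nodes) > 2:
        i, j = sorted(rng.sample(range(len(nodes)), 2))
        (nb, nwkb) = nodes.pop(j)
        (na, nwka) = nodes.pop(i)
        parent = new_internal()
        la = float(nwka.rsplit(":", 1)[1].rstrip(");"))
        edges.append((parent, na, la))
        lb = float(nwkb.rsplit(":", 1)[1].rstrip(");"))
        edges.append((parent, nb, lb))
        plen = round(rng.uniform(0.1, 3.0), 3)
        nodes.append((parent, f"({nwka},{nwkb}):{plen}"))
    (na, nwka), (nb, nwkb) = nodes
    root = new_internal()
    edges.append((root, na, float(nwka.rsplit(':', 1)[1])))
    edges.append((root, nb, float(nwkb.rsplit(':', 1)[1])))
    newick = f"({nwka},{nwkb});"
    return newick, edges, [f"L{i}" for i in range(n_leaves)]


def path_length_oracle(edges, a, b):
    g = nx.Graph()
    for parent, child, length in edges:
        g.add_edge(parent, child, weight=length)
    return nx.shortest_path_length(g, a, b, weight="weight")


class TestParseNewick:
    def test_basic_topology(self):
        tree = parse_newick("((A:1,B:2):3,C:4);")
        assert sorted(tree.leaf_labels) == ["A", "B", "C"]

    def test_per_mille_support_scale_detected(self):
        tree = parse_newick("((A:1,B:2)950:3,C:4);")
        assert tree.support_scale == "permille"

    def test_percent_scale_default(self):
        tree = parse_newick("((A:1,B:2)95:3,C:4);")
        assert tree.support_scale == "percent"

    def test_unbalanced_parentheses_rejected(self):
        with pytest.raises(TreeError):
            parse_newick("((A:1,B:2:3,C:4);")

    def test_duplicate_leaf_labels_rejected(self):
        with pytest.raises(TreeError, match="duplicate"):
            parse_newick("((A:1,A:2):3,C:4);")

    def test_missing_branch_lengths_imputed_with_flag(self):
        tree = parse_newick("((A,B),C);")
        assert tree.missing_lengths_imputed
        assert patristic_distance(tree, "A", "C") == 3.0

    def test_round_trip_random_trees(self, rng):
        for _ in range(100):
            newick, _, leaves = random_tree_edges(rng, rng.randrange(3, 10))
            tree = parse_newick(newick)
            back = parse_newick(write_newick(tree))
            assert sorted(back.leaf_labels) == sorted(leaves)
            for a, b in itertools.combinations(leaves, 2):
                assert patristic_distance(back, a, b) == pytest.approx(
                    patristic_distance(tree, a, b))


class TestPatristicDistance:
    def test_hand_summed_example(self):
        tree = parse_newick("((A:1,B:2):3,C:4);")
        assert patristic_distance(tree, "A", "C") == 8.0
        assert patristic_distance(tree, "A", "B") == 3.0

    def test_self_distance_zero(self):
        tree = parse_newick("((A:1,B:2):3,C:4);")
        assert patristic_distance(tree, "C", "C") == 0.0

    def test_unknown_label_rejected(self):
        tree = parse_newick("((A:1,B:2):3,C:4);")
        with pytest.raises(TreeError):
            patristic_distance(tree, "A", "Z")

    def test_matrix_equals_graph_shortest_path_oracle(self, rng):
        for _ in range(25):
            newick, edges, leaves = random_tree_edges(rng, rng.randrange(4, 13))
            tree = parse_newick(newick)
            mat = distance_matrix(tree)
            for a, b in itertools.combinations(leaves, 2):
                assert mat[(a, b)] == pytest.approx(
                    path_length_oracle(edges, a, b))

    def test_metric_axioms_on_random_trees(self, rng):
        for _ in range(10):
            newick, _, leaves = random_tree_edges(rng, 8)
            mat = distance_matrix(parse_newick(newick))
            for a, b in itertools.combinations(leaves, 2):
                assert mat[(a, b)] >= 0
                assert mat[(a, b)] == pytest.approx(mat[(b, a)])
            for a, b, c in itertools.combinations(leaves, 3):
                assert mat[(a, c)] <= mat[(a, b)] + mat[(b, c)] + 1e-9


class TestCollapseLowSupport:
    NEWICK = "(((A:1,B:1)650:2,C:1)900:1,(D:1,E:1)800:1);"

    def test_weak_node_collapsed_into_polytomy(self):
        tree = parse_newick(self.NEWICK)
        with pytest.warns(UserWarning):
            out = collapse_low_support(tree, 700)
        # A and B now attach to the 900-support node: a polytomy with C
        assert sorted(out.leaf_labels) == ["A", "B", "C", "D", "E"]
        assert "(A:1.0,B:1.0)" not in out.as_newick().replace(" ", "")

    def test_all_strong_nodes_unchanged(self):
        tree = parse_newick(self.NEWICK)
        out = collapse_low_support(tree, 600)
        assert distance_matrix(out) == pytest.approx(distance_matrix(tree))

    def test_threshold_zero_never_collapses(self):
        tree = parse_newick(self.NEWICK)
        out = collapse_low_support(tree, 0)
        assert distance_matrix(out) == pytest.approx(distance_matrix(tree))

    def test_leaf_set_preserved(self):
        tree = parse_newick(self.NEWICK)
        with pytest.warns(UserWarning):
            out = collapse_low_support(tree, 1000)
        assert sorted(out.leaf_labels) == sorted(tree.leaf_labels)

    def test_zero_length_contraction_preserves_distances(self):
        tree = parse_newick("(((A:1,B:1)650:0.0,C:1)900:1,D:2);")
        with pytest.warns(UserWarning):
            out = collapse_low_support(tree, 700)
        assert distance_matrix(out) == pytest.approx(distance_matrix(tree))

    def test_redistribute_preserves_distances_across_collapsed_edge(self):
        # redistribution keeps every path that crossed the contracted edge
        # intact; paths wholly inside the collapsed clade gain 2x its length
        tree = parse_newick(self.NEWICK)
        out = collapse_low_support(tree, 700, redistribute=True)
        before, after = distance_matrix(tree), distance_matrix(out)
        for pair in (("A", "C"), ("A", "D"), ("B", "E"), ("C", "D")):
            assert after[pair] == pytest.approx(before[pair])
        assert after[("A", "B")] == pytest.approx(before[("A", "B")] + 2 * 2)

    def test_threshold_outside_scale_rejected(self):
        tree = parse_newick(self.NEWICK)
        with pytest.raises(TreeError):
            collapse_low_support(tree, 1500)


class TestCongruenceCheck:
    def test_grafted_transfer_leaf_is_congruent(self):
        newick = "(((query:0.01,donor:0.01)900:0.3,donor2:0.4)950:0.5,(r1:0.3,r2:0.2)800:0.5);"
        res = congruence_check(parse_newick(newick), "query", "donor")
        assert res.congruent
        assert res.nearest_leaf == "donor"
        assert not res.tied
        assert res.sister_leaves == ("donor",)

    def test_incongruent_when_blast_best_differs(self):
        newick = "(((query:0.01,donor:0.01)900:0.3,donor2:0.4)950:0.5,(r1:0.3,r2:0.2)800:0.5);"
        res = congruence_check(parse_newick(newick), "query", "r1")
        assert not res.congruent

    def test_star_tree_tie_flagged_lexicographic(self):
        res = congruence_check(parse_newick("(q:1,b:1,a:1,c:1);"), "q", "a")
        assert res.tied
        assert res.nearest_leaf == "a"
        assert res.congruent

    def test_candidate_restriction(self):
        newick = "(((query:0.01,paralog:0.01)900:0.3,donor:0.4)950:0.5,r1:0.5);"
        res = congruence_check(parse_newick(newick), "query", "donor",
                               candidate_set={"donor", "r1"})
        assert res.nearest_leaf == "donor"
        assert res.congruent

    def test_empty_candidates_rejected(self):
        tree = parse_newick("(A:1,B:1);")
        with pytest.raises(TreeError):
            congruence_check(tree, "A", "B", candidate_set={"A"})

    def test_rerooting_invariance(self, rng):
        import dendropy

        for _ in range(10):
            newick, _, leaves = random_tree_edges(rng, 8)
            tree = parse_newick(newick)
            base = congruence_check(tree, leaves[0], leaves[1])
            dtree = dendropy.Tree.get(data=newick, schema="newick",
                                      suppress_internal_node_taxa=True)
            node = dtree.find_node_with_taxon_label(leaves[3])
            half = node.edge.length / 2
            dtree.reroot_at_edge(node.edge, length1=half, length2=half,
                                 update_bipartitions=True)
            rerooted = parse_newick(dtree.as_string(schema="newick"))
            res = congruence_check(rerooted, leaves[0], leaves[1])
            assert res.nearest_leaf == base.nearest_leaf
            assert res.nearest_distance == pytest.approx(base.nearest_distance)
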