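"""Gene-tree and network parsing, validation and serialization."""

import itertools

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from netcoal import (GeneTree, NewickParseError, PhyloError, StructureError,
                     parse_gene_trees, parse_network, write_network)
from netcoal.phylo import PhyloNetwork
from netcoal.search import add_reticulation, enumerate_trees


class TestGeneTreeParsing:
    def test_basic_structure(self):
        (t,) = parse_gene_trees("((A,B),C);")
        assert t.n_leaves == 3
        assert len(t.internal_nodes) == 2
        assert t.leaf_labels == {"A", "B", "C"}

    def test_multiline_input_preserves_order(self):
        trees = parse_gene_trees("((A,(B,C)),D);\n(A,((B,C),D));\n")
        assert len(trees) == 2
        assert all(t.leaf_labels == {"A", "B", "C", "D"} for t in trees)
        assert trees[0].canonical() == "(((B,C),A),D);"
        assert trees[1].canonical() == "(((B,C),D),A);"

    def test_branch_lengths_ignored(self):
        (t,) = parse_gene_trees("((A:0.1,B:2.3):4,C:1);")
        assert t.canonical() == "((A,B),C);"

    @pytest.mark.parametrize("bad,err", [
        ("((A,B,C),D);", StructureError),       # polytomy
        ("((A,B),A);", PhyloError),             # duplicate labels
        ("((A,B),C", NewickParseError),         # unbalanced
    ])
    def test_rejects_invalid(self, bad, err):
        with pytest.raises(err):
            parse_gene_trees(bad)

    def test_error_carries_line_number(self):
        with pytest.raises(PhyloError, match="line 2"):
            parse_gene_trees("((A,B),C);\n((A,B,C),D);")

    def test_leaf_count_invariant(self):
        # n leaves imply exactly n-1 internal nodes in a binary tree
        for s in ("(A,B);", "((A,B),(C,D));", "(((A,B),C),(D,(E,F)));"):
            (t,) = parse_gene_trees(s)
            assert len(t.internal_nodes) == t.n_leaves - 1


class TestNetworkParsing:
    def test_one_reticulation(self):
        net = parse_network("((A,(B)#H1),(C,#H1));")
        assert net.n_reticulations == 1
        assert net.leaf_labels == {"A", "B", "C"}
        r = net.reticulations[0]
        assert len(net.parents[r]) == 2

    def test_species_tree_special_case(self):
        net = parse_network("((A,B),C);")
        assert net.is_tree
        assert net.n_reticulations == 0

    def test_parallel_parent_edges_accepted(self):
        # both parent edges of the hybrid share head and tail
        net = parse_network("((A)#H1,#H1);")
        assert net.n_reticulations == 1

    def test_gamma_annotation(self):
        net = parse_network("((A,(B)#H1:1.0::0.3),(C,#H1:2.0::0.7));")
        r = net.reticulations[0]
        assert net.gamma[r] == pytest.approx(0.3)
        assert net.lengths[net.b1_edge(r)] == pytest.approx(1.0)

    def test_gamma_out_of_range(self):
        with pytest.raises(PhyloError):
            parse_network("((A,(B)#H1:::1.3),(C,#H1));")

    def test_inconsistent_gammas(self):
        with pytest.raises(PhyloError):
            parse_network("((A,(B)#H1:::0.3),(C,#H1:::0.3));")

    def test_reticulation_bad_outdegree(self):
        with pytest.raises(StructureError):
            parse_network("((A,(B,C)#H1),(D,#H1));")

    def test_structural_validator(self):
        # node with indegree 3
        children = {0: [1, 2, 3], 1: [4], 2: [4], 3: [4], 4: []}
        with pytest.raises(StructureError):
            PhyloNetwork(children, {4: "A"})


def _to_digraph(net):
    g = nx.DiGraph()
    for v in net.children:
        g.add_node(v, label=net.labels.get(v, ""))
        for c in net.children[v]:
            g.add_edge(v, c)
    return g


def _isomorphic(n1, n2):
    return nx.is_isomorphic(
        _to_digraph(n1), _to_digraph(n2),
        node_match=lambda a, b: a["label"] == b["label"])


class TestSerialization:
    def test_canonical_tree(self):
        assert parse_network("((B,A),C);").canonical_topology() == "((A,B),C);"

    def test_roundtrip_all_small_networks(self):
        """parse(write(net)) is isomorphic to net, and canonical forms of
        isomorphic inputs coincide, over every <=4-taxon topology with
        <=1 reticulation and every 5-taxon tree."""
        nets = []
        for tree in enumerate_trees("ABCD"):
            nets.append(tree)
            edges = tree.edges()
            for te, he in itertools.product(edges, repeat=2):
                cand = add_reticulation(tree, te, he)
                if cand is not None:
                    nets.append(cand)
        nets.extend(enumerate_trees("ABCDE"))
        for net in nets:
            back = parse_network(write_network(net))
            assert back.canonical_topology() == net.canonical_topology()
            assert _isomorphic(back, net)

    def test_isomorphic_networks_serialize_identically(self):
        # same network entered with different node orderings
        a = parse_network("((C,#H1),((B)#H1,A));")
        b = parse_network("((A,(B)#H1),(#H1,C));")
        assert _isomorphic(a, b)
        assert a.canonical_topology() == b.canonical_topology()

    def test_distinct_networks_serialize_differently(self, indistinct_pair):
        n1, n2 = indistinct_pair
        assert not _isomorphic(n1, n2)
        assert n1.canonical_topology() != n2.canonical_topology()

    def test_parameters_roundtrip(self):
        text = "((A:1,(B)#H1:2::0.25):3,(C:4,#H1:5::0.75):6);"
        net = parse_network(text)
        back = parse_network(write_network(net))
        r = back.reticulations[0]
        assert back.gamma[r] == pytest.approx(0.25)
        assert sorted(back.lengths.values()) == sorted(net.lengths.values())


@st.composite
def nested_topologies(draw, max_leaves=6):
    n = draw(st.integers(min_value=2, max_value=max_leaves))
    labels = [f"T{i}" for i in range(n)]
    items = list(labels)
    while len(items) > 1:
        i = draw(st.integers(min_value=0, max_value=len(items) - 2))
        a = items.pop(i)
        b = items.pop(draw(st.integers(min_value=0,
                                       max_value=len(items) - 1)))
        items.append((a, b))
    return items[0]


@settings(max_examples=50, derandomize=True)
@given(nested_topologies())
def test_random_tree_roundtrip(nested):
    """Random topologies survive write -> parse with identical canonical
    form, and GeneTree/PhyloNetwork canonicalizations agree on trees."""
    g = GeneTree.from_nested(nested)
    net = parse_network(g.canonical())
    assert net.canonical_topology() == g.canonical()
    assert parse_network(write_network(net)).canonical_topology() \
        == g.canonical()
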