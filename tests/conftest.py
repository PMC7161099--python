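import pytest

from netcoal import GeneTree, parse_network
from netcoal.search import enumerate_trees


@pytest.fixture(scope="session")
def tree3():
    """3-taxon species tree ((A,B),C) with unit branch lengths."""
    return parse_network("((A,B),C);").with_lengths(1.0)


@pytest.fixture(scope="session")
def gene3():
    """The three rooted gene-tree topologies on {A, B, C}."""
    return [GeneTree.from_newick(s) for s in
            ("((A,B),C);", "((A,C),B);", "((B,C),A);")]


@pytest.fixture(scope="session")
def net1ret():
    """3-taxon, 1-reticulation network: B descends from a hybrid node."""
    return parse_network("((A,(B)#H1),(C,#H1));")


@pytest.fixture(scope="session")
def indistinct_pair():
    """Two non-isomorphic 4-taxon, 1-reticulation networks displaying
    exactly {((A,(B,C)),D), (A,((B,C),D))} with opposite reticulation
    directions."""
    n1 = parse_network("((A,((B,C))#H1),(#H1,D));")
    n2 = parse_network("((A,((B,C),(D)#H1)),#H1);")
    return n1, n2


@pytest.fixture(scope="session")
def all_trees4():
    return list(enumerate_trees("ABCD"))


@pytest.fixture(scope="session")
def all_gene4(all_trees4):
    return [GeneTree.from_newick(t.canonical_topology()) for t in all_trees4]


@pytest.fixture(scope="session")
def discordant_loci():
    """Three equal-frequency 4-taxon gene trees on which the MDC-optimal
    species tree is unique and disjoint from the (two-fold) optimum under
    the integrated NCM likelihood."""
    return [GeneTree.from_newick(s) for s in
            ("(((A,B),C),D);", "(((A,D),C),B);", "((A,C),(B,D));")]
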