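"""Network utilities: displayed trees, indistinguishability, distances.

A network with ``l`` reticulations displays at most ``2^l`` rooted trees:
one per selection of a single parent edge at every reticulation, after
deleting the unselected edges and suppressing the resulting degree-two
nodes.  Two networks with the same displayed-tree set generate the same
gene-tree topology distribution when one allele is sampled per species and
only topologies are observed — the indistinguishability behind the
reticulation-direction errors that topology-only inference can make.

``network_distance`` is a hardwired-cluster dissimilarity: the normalized
symmetric difference of the multisets of descendant-leaf sets of all
edges.  It is zero iff the cluster multisets coincide and is symmetric; it
is a surrogate for reduction-based network metrics, sufficient to score
whether an inferred network equals the truth.
"""

from __future__ import annotations

import warnings
from collections import Counter
from itertools import product

from .phylo import GeneTree, PhyloError, PhyloNetwork

__all__ = ["displayed_trees", "same_displayed_set", "network_distance"]


def _extract_tree(net: PhyloNetwork, keep: dict[int, int]) -> str:
    """Canonical topology of the tree displayed by keeping parent
    ``keep[r]`` at each reticulation ``r``."""
    children = {v: list(ks) for v, ks in net.children.items()}
    for r, p in keep.items():
        for q in net.parents[r]:
            if q != p:
                children[q].remove(r)
    # prune non-leaf nodes that lost all children, bottom-up
    changed = True
    while changed:
        changed = False
        for v in list(children):
            if not children[v] and v not in net.labels:
                for q in list(children):
                    if v in children[q]:
                        children[q].remove(v)
                        changed = True
                del children[v]
                changed = True

    def rec(v: int) -> str:
        kids = children[v]
        if not kids:
            return net.labels[v]
        if len(kids) == 1:  # suppress degree-2 / former reticulation nodes
            return rec(kids[0])
        return "(" + ",".join(sorted(rec(c) for c in kids)) + ")"

    root = net.root
    while root not in net.labels and len(children[root]) == 1:
        root = children[root][0]
    return rec(root) + ";"


def displayed_trees(net: PhyloNetwork) -> frozenset[str]:
    """The set of canonical topologies of all trees displayed by ``net``."""
    rets = net.reticulations
    out = set()
    for choice in product(*(net.parents[r] for r in rets)):
        keep = dict(zip(rets, choice))
        out.add(_extract_tree(net, keep))
    return frozenset(out)


def displayed_gene_trees(net: PhyloNetwork) -> list[GeneTree]:
    """Displayed trees as GeneTree objects (canonical order)."""
    return [GeneTree.from_newick(s) for s in sorted(displayed_trees(net))]


def same_displayed_set(net1: PhyloNetwork, net2: PhyloNetwork) -> bool:
    """True iff the two networks display exactly the same tree set."""
    if net1.leaf_labels != net2.leaf_labels:
        warnings.warn("networks have different leaf sets",
                      stacklevel=2)
        return False
    return displayed_trees(net1) == displayed_trees(net2)


def _cluster_multiset(net: PhyloNetwork) -> Counter:
    return Counter(net.descendant_labels(c) for _p, c in net.edges())


def network_distance(net1: PhyloNetwork, net2: PhyloNetwork) -> float:
    """Normalized symmetric difference of hardwired-cluster multisets.

    0 iff the multisets coincide; symmetric; in [0, 1].
    """
    if net1.leaf_labels != net2.leaf_labels:
        raise PhyloError("networks must share a leaf set")
    c1 = _cluster_multiset(net1)
    c2 = _cluster_multiset(net2)
    sym = sum(((c1 - c2) + (c2 - c1)).values())
    return sym / (sum(c1.values()) + sum(c2.values()))
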