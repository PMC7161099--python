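"""Independent oracles used by the test suite.

These deliberately avoid the library's own algorithms: coalescent
histories by exhaustive node-to-edge map filtering, lineage-count
transition probabilities by matrix exponential of the pure-death chain,
integrated quantities by adaptive quadrature, and deep-coalescence costs
by the cluster-counting formula.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.integrate import quad
from scipy.linalg import expm

ROOT = ("root", "root")


# -- coalescent histories (species trees only) ------------------------------

def brute_force_history_maps(g, tree):
    """All maps of gene-tree internal nodes to tree edges (plus the virtual
    root edge) satisfying the leaf-anchoring and ancestry conditions.

    Returns a set of frozensets of (gene node, edge) pairs.
    """
    edges = tree.edges()
    label_to_leaf = {tree.labels[v]: v for v in tree.leaves}

    # ancestor-or-equal relation on tree nodes
    anc: dict[int, set[int]] = {}

    def fill(v, above):
        anc[v] = above | {v}
        for c in tree.children[v]:
            fill(c, anc[v])

    fill(tree.root, set())

    def weakly_below(e1, e2):
        """edge e1 lies in the subtree hanging from edge e2 (or equal)."""
        if e2 == ROOT:
            return True
        if e1 == ROOT:
            return False
        return e2[1] in anc[e1[1]]

    # pendant edge of each gene leaf is pinned by the label
    pend = {}
    for v in g.leaves:
        leaf = label_to_leaf[g.labels[v]]
        pend[v] = (tree.parents[leaf][0], leaf)

    internals = sorted(g.internal_nodes)
    out = set()
    for assign in itertools.product(edges + [ROOT], repeat=len(internals)):
        h = dict(zip(internals, assign))

        def edge_of(v):
            return h[v] if v in h else pend[v]

        ok = True
        for v in internals:
            for c in g.children[v]:
                if not weakly_below(edge_of(c), edge_of(v)):
                    ok = False
                    break
            if not ok:
                break
        if ok:
            out.add(frozenset(h.items()))
    return out


# -- lineage-count transition probability -----------------------------------

def p_uv_expm(u: int, v: int, t: float) -> float:
    """Pure-death-chain oracle: states u..1, rate k(k-1)/2 from k to k-1."""
    n = u
    q = np.zeros((n, n))
    for k in range(2, u + 1):
        rate = k * (k - 1) / 2.0
        i = u - k  # row index of state k
        q[i, i] = -rate
        q[i, i + 1] = rate
    p = expm(q * t)
    return float(p[0, u - v])


def p_uv_quad(u: int, v: int, tau: float, rate: float = 1.0) -> float:
    """Quadrature of p_uv against the (truncated) exponential prior."""
    if math.isinf(tau):
        norm = 1.0
        upper = np.inf
    else:
        norm = 1.0 - math.exp(-rate * tau)
        upper = tau
    val, _err = quad(
        lambda t: p_uv_expm(u, v, t) * rate * math.exp(-rate * t) / norm,
        0, upper, limit=200)
    return val


# -- deep coalescence --------------------------------------------------------

def mdc_clusters(g, tree) -> int:
    """Cluster-counting deep-coalescence cost for species trees: on every
    branch, one fewer than the number of maximal gene-tree clades whose
    leaves fit inside the branch's cluster."""
    gclades = set()

    def rec(v):
        kids = g.children[v]
        s = (frozenset([g.labels[v]]) if not kids
             else frozenset().union(*(rec(c) for c in kids)))
        gclades.add(s)
        return s

    rec(g.root)
    total = 0
    for _p, c in tree.edges():
        cluster = tree.descendant_labels(c)
        if len(cluster) < 2:
            continue
        inside = [s for s in gclades if s <= cluster]
        maximal = [s for s in inside if not any(s < t for t in inside)]
        total += len(maximal) - 1
    return total


# -- displayed trees by recursive deletion -----------------------------------

def displayed_by_deletion(net) -> frozenset[str]:
    """Independent displayed-tree oracle: recursively pick a reticulation,
    delete each parent edge in turn, and recurse until tree."""
    from netcoal.search import delete_reticulation

    rets = net.reticulations
    if not rets:
        return frozenset([net.canonical_topology()])
    r = rets[0]
    out = set()
    for p in net.parents[r]:
        sub = delete_reticulation(net, (p, r))
        if sub is not None:
            out |= displayed_by_deletion(sub)
    return frozenset(out)
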