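"""Coalescent histories of a gene tree within a species network.

A coalescent history assigns every gene-tree coalescence to an edge of the
species phylogeny (or to the root, treated as a virtual edge of infinite
duration) and, on networks, additionally routes each gene lineage arriving
at a reticulation node along one of its two parent edges.  Histories are
enumerated generatively: network nodes are processed children-first, the
set of gene lineages entering each edge is tracked, and every feasible
subset of gene-tree coalescences on every edge (and every routing at every
reticulation) is branched over.

Per-edge lineage counts: ``u`` lineages enter an edge at its child end and
``v = u - #coalescences`` exit at its parent end.  The combinatorial terms
``w``/``d`` give the fraction of orderings of the ``u - v`` pairwise
coalescent events that agree with the gene-tree topology:

* ``d = prod_{k=v+1..u} C(k, 2)`` counts all event sequences;
* ``w`` counts linear extensions of the ancestry partial order among the
  coalescences assigned to the edge (descendant events first), computed by
  the hook-length formula for forests, ``|T|! / prod_t |T_t|``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import factorial

from .phylo import GeneTree, LabelMismatchError, PhyloError, PhyloNetwork

__all__ = ["CoalescentHistory", "enumerate_histories", "wd_edge_terms",
           "order_counts"]

#: Sentinel "edge" for coalescences above the network root.
ROOT = ("root", "root")

#: Guards against the super-exponential blow-up of enumeration.
MAX_LEAVES = 10
MAX_RETICULATIONS = 3


@dataclass(frozen=True)
class CoalescentHistory:
    """One coalescent history of a gene tree in a network.

    ``edge_records`` holds, for every network edge traversed by at least
    one gene lineage, the tuple ``(edge, u, v, merges)`` where ``merges``
    is the frozenset of gene-tree internal nodes whose coalescence the
    history places on that edge.  ``root_record`` is ``(u, merges)`` for
    the virtual root edge.  ``routing`` holds, per reticulation node, the
    frozensets of lineages sent up the major (b1) and minor (b2) parent
    edges.
    """

    edge_records: tuple[tuple[tuple[int, int], int, int, frozenset[int]], ...]
    root_record: tuple[int, frozenset[int]]
    routing: tuple[tuple[int, frozenset[int], frozenset[int]], ...]

    def node_map(self, g: GeneTree) -> dict[int, tuple[int, int]]:
        """Map each gene-tree internal node to the network edge (or the
        ROOT sentinel) on which the history places its coalescence."""
        out: dict[int, tuple[int, int]] = {}
        for edge, _u, _v, merges in self.edge_records:
            for m in merges:
                out[m] = edge
        for m in self.root_record[1]:
            out[m] = ROOT
        return out

    def ret_counts(self, r: int) -> tuple[int, int]:
        """Lineage counts (u_b1, u_b2) entering the two parent edges of
        reticulation node ``r``."""
        for node, s1, s2 in self.routing:
            if node == r:
                return len(s1), len(s2)
        raise KeyError(r)


# ---------------------------------------------------------------------------
# w / d combinatorics
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _d_count(u: int, v: int) -> int:
    d = 1
    for k in range(v + 1, u + 1):
        d *= k * (k - 1) // 2
    return d


def _w_count(merges: frozenset[int], g: GeneTree) -> int:
    """Linear extensions of the coalescence poset restricted to ``merges``."""
    n = len(merges)
    if n <= 1:
        return 1
    denom = 1
    for t in merges:
        denom *= len(g.internal_descendants(t) & merges)
    return factorial(n) // denom


def order_counts(u: int, v: int, merges: frozenset[int],
                 g: GeneTree) -> tuple[int, int]:
    """Return ``(w, d)`` for an edge entered by ``u`` lineages, exited by
    ``v``, with coalescences ``merges`` assigned to it."""
    if not (1 <= v <= u) or u - v != len(merges):
        raise PhyloError(
            f"inconsistent lineage counts: u={u}, v={v}, merges={len(merges)}")
    return _w_count(merges, g), _d_count(u, v)


def wd_edge_terms(h: CoalescentHistory, edge: tuple[int, int],
                  g: GeneTree) -> tuple[int, int]:
    """``(w, d)`` for one network edge under history ``h``; the ROOT
    sentinel addresses the virtual root edge (v = 1)."""
    if edge == ROOT:
        u, merges = h.root_record
        return order_counts(u, 1, merges, g)
    for e, u, v, merges in h.edge_records:
        if e == edge:
            return order_counts(u, v, merges, g)
    raise KeyError(f"edge {edge} carries no lineages under this history")


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------


def _merge_outcomes(entering: frozenset[int], g: GeneTree):
    """All ``(exiting, merges)`` pairs reachable from ``entering`` by
    coalescing sibling lineage pairs (in any number, zero included)."""
    out = []
    seen = {entering}
    stack = [(entering, frozenset())]
    while stack:
        cur, merged = stack.pop()
        out.append((cur, merged))
        for x in cur:
            p = g.parent.get(x)
            if p is None:
                continue
            a, b = g.children[p]
            sib = b if x == a else a
            if x == a and sib in cur:  # visit each pair once
                nxt = (cur - {a, b}) | {p}
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append((nxt, merged | {p}))
    return out


def _full_closure(entering: frozenset[int], g: GeneTree) -> frozenset[int]:
    """Coalesce everything: the forced merge set above the root."""
    cur = set(entering)
    merged = set()
    changed = True
    while changed:
        changed = False
        for x in list(cur):
            p = g.parent.get(x)
            if p is None:
                continue
            a, b = g.children[p]
            if a in cur and b in cur:
                cur -= {a, b}
                cur.add(p)
                merged.add(p)
                changed = True
    if len(cur) != 1:
        raise PhyloError("gene lineages failed to fully coalesce at the root")
    return frozenset(merged)


def _subsets(s: frozenset[int]):
    items = sorted(s)
    n = len(items)
    for mask in range(1 << n):
        yield frozenset(items[i] for i in range(n) if mask >> i & 1)


def enumerate_histories(g: GeneTree, net: PhyloNetwork,
                        max_leaves: int = MAX_LEAVES,
                        max_rets: int = MAX_RETICULATIONS
                        ) -> list[CoalescentHistory]:
    """Exhaustively enumerate the coalescent histories of ``g`` in ``net``.

    Output order is deterministic (network nodes in topological order,
    branching choices in canonical order).  Two histories that differ only
    in reticulation routing are distinct.
    """
    if g.leaf_labels != net.leaf_labels:
        raise LabelMismatchError(
            f"gene tree labels {sorted(g.leaf_labels)} != network labels "
            f"{sorted(net.leaf_labels)}")
    if g.n_leaves > max_leaves:
        raise PhyloError(
            f"{g.n_leaves} leaves exceeds the enumeration cap of "
            f"{max_leaves}; raise max_leaves explicitly to override")
    if net.n_reticulations > max_rets:
        raise PhyloError(
            f"{net.n_reticulations} reticulations exceeds the enumeration "
            f"cap of {max_rets}; raise max_rets explicitly to override")

    label_to_gene = {lab: v for v, lab in g.labels.items()}
    order = net.topological_order()  # children before parents
    # index nodes for the recursion
    histories: list[CoalescentHistory] = []

    def visit(i: int, exiting: dict[tuple[int, int], frozenset[int]],
              records: tuple, routing: tuple) -> None:
        v = order[i]
        kids = net.children[v]
        if not net.parents[v]:  # root
            entering = frozenset().union(*(exiting[(v, c)] for c in kids))
            merges = _full_closure(entering, g)
            histories.append(CoalescentHistory(
                edge_records=records,
                root_record=(len(entering), merges),
                routing=routing))
            return
        if len(net.parents[v]) == 2:  # reticulation: split, then two edges
            s = exiting[(v, kids[0])]
            b1 = net.b1_edge(v)
            b2 = net.b2_edge(v)
            for s1 in _subsets(s):
                s2 = s - s1
                for e1, m1 in _merge_outcomes(s1, g):
                    for e2, m2 in _merge_outcomes(s2, g):
                        new_exiting = dict(exiting)
                        new_exiting[b1] = e1
                        new_exiting[b2] = e2
                        new_records = records
                        if s1:
                            new_records += ((b1, len(s1), len(e1), m1),)
                        if s2:
                            new_records += ((b2, len(s2), len(e2), m2),)
                        visit(i + 1, new_exiting, new_records,
                              routing + ((v, s1, s2),))
            return
        # leaf or internal tree node: one parent edge
        if not kids:
            entering = frozenset({label_to_gene[net.labels[v]]})
        else:
            entering = frozenset().union(*(exiting[(v, c)] for c in kids))
        edge = (net.parents[v][0], v)
        for ex, merges in _merge_outcomes(entering, g):
            new_exiting = dict(exiting)
            new_exiting[edge] = ex
            visit(i + 1, new_exiting,
                  records + ((edge, len(entering), len(ex), merges),),
                  routing)

    visit(0, {}, (), ())
    return histories
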