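"""Gene trees and rooted phylogenetic networks.

A phylogenetic network is a rooted directed acyclic graph whose leaves are
bijectively labeled by taxa.  Nodes partition into the root (indegree 0),
leaves (indegree 1, outdegree 0), internal tree nodes (indegree 1,
outdegree >= 2) and reticulation nodes (indegree 2, outdegree 1).  Each
reticulation node ``r`` has a designated "major" parent edge carrying the
inheritance probability ``gamma``; the other parent edge carries
``1 - gamma``.  A species tree is the special case with no reticulations.

Gene trees are rooted, binary, leaf-labeled topologies; branch lengths on
gene-tree input are ignored because the likelihood is defined on topologies
alone.

Serialization uses Newick for trees and extended (Rich) Newick for
networks: reticulation nodes are written once in full, tagged ``#H<k>``,
and referenced by tag elsewhere; inheritance probabilities ride in the
fourth colon-separated field of the major parent edge
(``child:length:support:gamma``).
"""

from __future__ import annotations

import io
from typing import Iterator

import dendropy

__all__ = [
    "PhyloError",
    "NewickParseError",
    "StructureError",
    "LabelMismatchError",
    "GeneTree",
    "PhyloNetwork",
    "parse_gene_trees",
    "parse_network",
    "write_network",
]


class PhyloError(ValueError):
    """Base class for malformed phylogenies or inputs."""


class NewickParseError(PhyloError):
    """Raised when Newick / extended Newick text cannot be parsed."""


class StructureError(PhyloError):
    """Raised when a parsed graph violates the network degree conditions."""


class LabelMismatchError(PhyloError):
    """Raised when gene-tree and network leaf label sets differ."""


# ---------------------------------------------------------------------------
# Gene trees
# ---------------------------------------------------------------------------


class GeneTree:
    """A rooted binary leaf-labeled tree topology for one locus.

    Nodes are consecutive integers; ``children[v]`` is a tuple of the two
    child ids for internal nodes and empty for leaves; ``labels`` maps leaf
    ids to taxon names.
    """

    __slots__ = ("children", "labels", "root", "parent", "_canonical")

    def __init__(self, children: dict[int, tuple[int, ...]],
                 labels: dict[int, str], root: int):
        self.children = children
        self.labels = labels
        self.root = root
        self.parent: dict[int, int] = {}
        for v, kids in children.items():
            for c in kids:
                self.parent[c] = v
        self._canonical: str | None = None
        self._validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_nested(cls, nested) -> "GeneTree":
        """Build from nested tuples of labels, e.g. ``(("A", "B"), "C")``."""
        children: dict[int, tuple[int, ...]] = {}
        labels: dict[int, str] = {}
        counter = iter(range(10 ** 9))

        def build(x) -> int:
            v = next(counter)
            if isinstance(x, tuple):
                kids = tuple(build(c) for c in x)
                children[v] = kids
            else:
                children[v] = ()
                labels[v] = str(x)
            return v

        root = build(nested)
        return cls(children, labels, root)

    @classmethod
    def from_newick(cls, text: str) -> "GeneTree":
        """Parse one rooted Newick string; branch lengths are discarded."""
        try:
            dt = dendropy.Tree.get(
                data=text, schema="newick", preserve_underscores=True,
                suppress_internal_node_taxa=True)
        except Exception as exc:  # dendropy raises several error types
            raise NewickParseError(f"malformed Newick: {exc}") from exc
        children: dict[int, tuple[int, ...]] = {}
        labels: dict[int, str] = {}
        counter = iter(range(10 ** 9))

        def build(node) -> int:
            v = next(counter)
            kids = node.child_nodes()
            if kids:
                children[v] = tuple(build(k) for k in kids)
            else:
                children[v] = ()
                if node.taxon is None or node.taxon.label is None:
                    raise NewickParseError("leaf without a label")
                labels[v] = node.taxon.label
            return v

        root = build(dt.seed_node)
        return cls(children, labels, root)

    # -- queries -----------------------------------------------------------

    def _validate(self) -> None:
        for v, kids in self.children.items():
            if kids and len(kids) != 2:
                raise StructureError(
                    f"gene tree is not binary: node with {len(kids)} children")
        labs = list(self.labels.values())
        if len(set(labs)) != len(labs):
            raise StructureError("duplicate leaf labels in gene tree")
        if not labs:
            raise StructureError("empty gene tree")

    @property
    def leaves(self) -> list[int]:
        return sorted(self.labels)

    @property
    def leaf_labels(self) -> frozenset[str]:
        return frozenset(self.labels.values())

    @property
    def internal_nodes(self) -> list[int]:
        return [v for v, kids in self.children.items() if kids]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def postorder(self) -> Iterator[int]:
        stack = [(self.root, False)]
        while stack:
            v, done = stack.pop()
            if done or not self.children[v]:
                yield v
            else:
                stack.append((v, True))
                for c in self.children[v]:
                    stack.append((c, False))

    def internal_descendants(self, v: int) -> frozenset[int]:
        """Internal nodes weakly below ``v`` (including ``v`` if internal)."""
        out = []
        stack = [v]
        while stack:
            u = stack.pop()
            if self.children[u]:
                out.append(u)
                stack.extend(self.children[u])
        return frozenset(out)

    def canonical(self) -> str:
        """Canonical Newick string: children ordered lexicographically."""
        if self._canonical is None:
            def rec(v: int) -> str:
                kids = self.children[v]
                if not kids:
                    return self.labels[v]
                return "(" + ",".join(sorted(rec(c) for c in kids)) + ")"
            self._canonical = rec(self.root) + ";"
        return self._canonical

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"GeneTree({self.canonical()!r})"

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneTree) and self.canonical() == other.canonical()

    def __hash__(self) -> int:
        return hash(self.canonical())


def parse_gene_trees(text: str) -> list[GeneTree]:
    """Parse multi-line Newick text, one rooted binary gene tree per line."""
    trees = []
    for lineno, line in enumerate(io.StringIO(text), start=1):
        line = line.strip()
        if not line:
            continue
        try:
            trees.append(GeneTree.from_newick(line))
        except PhyloError as exc:
            raise type(exc)(f"line {lineno}: {exc}") from exc
    return trees


# ---------------------------------------------------------------------------
# Phylogenetic networks
# ---------------------------------------------------------------------------


class PhyloNetwork:
    """Rooted phylogenetic network (DAG) with optional branch lengths and
    inheritance probabilities.

    Attributes
    ----------
    children, parents : dict[int, list[int]]
        Adjacency, keyed by node id.  Child/parent order within a list is
        not meaningful; edge identity is the ``(parent, child)`` pair.
    labels : dict[int, str]
        Taxon names, keyed by leaf id.
    lengths : dict[tuple[int, int], float]
        Branch lengths in coalescent units, keyed by edge; optional.
    major_parent : dict[int, int]
        For each reticulation node, the parent on the designated major
        (gamma-carrying) edge ``b1``.
    gamma : dict[int, float]
        Inheritance probability on the major edge of each reticulation;
        optional (only needed for fixed-parameter likelihood and
        simulation, not for the integrated likelihood).
    """

    def __init__(self, children: dict[int, list[int]],
                 labels: dict[int, str],
                 lengths: dict[tuple[int, int], float] | None = None,
                 major_parent: dict[int, int] | None = None,
                 gamma: dict[int, float] | None = None):
        self.children = {v: list(kids) for v, kids in children.items()}
        self.parents: dict[int, list[int]] = {v: [] for v in children}
        for v, kids in self.children.items():
            for c in kids:
                self.parents[c].append(v)
        self.labels = dict(labels)
        self.lengths = dict(lengths or {})
        self.major_parent = dict(major_parent or {})
        self.gamma = dict(gamma or {})
        self._canonical: str | None = None
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def root(self) -> int:
        return self._root

    @property
    def leaves(self) -> list[int]:
        return sorted(self.labels)

    @property
    def leaf_labels(self) -> frozenset[str]:
        return frozenset(self.labels.values())

    @property
    def reticulations(self) -> list[int]:
        return sorted(v for v in self.children if len(self.parents[v]) == 2)

    @property
    def n_reticulations(self) -> int:
        return len(self.reticulations)

    @property
    def is_tree(self) -> bool:
        return self.n_reticulations == 0

    def edges(self) -> list[tuple[int, int]]:
        return [(p, c) for p in sorted(self.children)
                for c in self.children[p]]

    def b1_edge(self, r: int) -> tuple[int, int]:
        return (self.major_parent[r], r)

    def b2_edge(self, r: int) -> tuple[int, int]:
        other = [p for p in self.parents[r] if p != self.major_parent[r]]
        if not other:  # parallel parent edges share head and tail
            return (self.major_parent[r], r)
        return (other[0], r)

    def validate(self) -> None:
        roots = [v for v in self.children if not self.parents[v]]
        if len(roots) != 1:
            raise StructureError(f"expected exactly one root, found {len(roots)}")
        self._root = roots[0]
        for v in self.children:
            ind, outd = len(self.parents[v]), len(self.children[v])
            if v == self._root:
                if outd < 2 and self.labels.get(v) is None:
                    raise StructureError("root must have outdegree >= 2")
            elif outd == 0:
                if ind != 1:
                    raise StructureError("leaf with indegree != 1")
                if v not in self.labels:
                    raise StructureError("unlabeled leaf node")
            elif ind == 1:
                if outd < 2:
                    raise StructureError(
                        "internal tree node with outdegree < 2")
            elif ind == 2:
                if outd != 1:
                    raise StructureError(
                        "reticulation node with outdegree != 1")
            else:
                raise StructureError(f"node with indegree {ind}")
        labs = list(self.labels.values())
        if len(set(labs)) != len(labs):
            raise StructureError("duplicate leaf labels")
        # acyclicity + reachability via topological order
        order = self.topological_order()
        if len(order) != len(self.children):
            raise StructureError("graph is cyclic or has unreachable nodes")
        for r in self.reticulations:
            mp = self.major_parent.get(r)
            if mp is not None and mp not in self.parents[r]:
                raise StructureError("major parent is not a parent")
            if mp is None:
                # deterministic default designation
                self.major_parent[r] = min(self.parents[r])
            g = self.gamma.get(r)
            if g is not None and not 0.0 <= g <= 1.0:
                raise PhyloError(f"inheritance probability {g} outside [0,1]")

    def topological_order(self) -> list[int]:
        """Nodes ordered children-before-parents (leaves first, root last)."""
        indeg_out = {v: len(self.children[v]) for v in self.children}
        stack = [v for v in self.children if indeg_out[v] == 0]
        order = []
        while stack:
            v = stack.pop()
            order.append(v)
            for p in self.parents[v]:
                indeg_out[p] -= 1
                if indeg_out[p] == 0:
                    stack.append(p)
        return order

    def descendant_labels(self, v: int) -> frozenset[str]:
        """Leaf labels reachable from ``v`` (the hardwired cluster of the
        edge above ``v``)."""
        out = set()
        stack = [v]
        seen = set()
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            if u in self.labels:
                out.add(self.labels[u])
            stack.extend(self.children[u])
        return frozenset(out)

    def copy(self) -> "PhyloNetwork":
        return PhyloNetwork(self.children, self.labels, self.lengths,
                            self.major_parent, self.gamma)

    # -- parameters --------------------------------------------------------

    def with_lengths(self, lengths) -> "PhyloNetwork":
        """Return a copy with branch lengths set.  ``lengths`` is either a
        single float applied to every edge or a dict keyed by edge."""
        if isinstance(lengths, (int, float)):
            lengths = {e: float(lengths) for e in self.edges()}
        return PhyloNetwork(self.children, self.labels, lengths,
                            self.major_parent, self.gamma)

    def with_gammas(self, gammas) -> "PhyloNetwork":
        """Return a copy with inheritance probabilities set; ``gammas`` is a
        float applied to every reticulation or a dict keyed by node."""
        if isinstance(gammas, (int, float)):
            gammas = {r: float(gammas) for r in self.reticulations}
        return PhyloNetwork(self.children, self.labels, self.lengths,
                            self.major_parent, gammas)

    def edge_name(self, edge: tuple[int, int]) -> str:
        """Stable human-readable edge identifier based on clusters."""
        p, c = edge
        cl = "+".join(sorted(self.descendant_labels(c)))
        if c in self.parents and len(self.parents[c]) == 2:
            tag = "M" if self.major_parent.get(c) == p else "m"
            return f"{cl}#{tag}"
        return cl

    # -- serialization -----------------------------------------------------

    def _signatures(self) -> dict[int, str]:
        sig: dict[int, str] = {}
        for v in self.topological_order():
            kids = self.children[v]
            if not kids:
                sig[v] = self.labels[v]
            elif len(self.parents[v]) == 2:
                sig[v] = "#(" + sig[kids[0]] + ")"
            else:
                sig[v] = "(" + ",".join(sorted(sig[c] for c in kids)) + ")"
        return sig

    def to_newick(self, include_params: bool = True) -> str:
        """Extended Newick.  Canonical: children ordered by signature, so
        isomorphic networks serialize identically; reticulations numbered
        in order of first appearance."""
        sig = self._signatures()
        hnum: dict[int, int] = {}
        lengths = self.lengths if include_params else {}

        def fields(edge: tuple[int, int], is_ret: bool) -> str:
            lam = lengths.get(edge)
            gam = None
            if is_ret and include_params:
                r = edge[1]
                g = self.gamma.get(r)
                if g is not None:
                    gam = g if edge == self.b1_edge(r) else 1.0 - g
            if gam is not None:
                ls = "" if lam is None else f"{lam:g}"
                return f":{ls}::{gam:g}"
            if lam is not None:
                return f":{lam:g}"
            return ""

        def rec(v: int, parent: int | None) -> str:
            is_ret = len(self.parents[v]) == 2
            edge = (parent, v) if parent is not None else None
            suffix = fields(edge, is_ret) if edge is not None else ""
            if is_ret:
                if v in hnum:
                    return f"#H{hnum[v]}" + suffix
                hnum[v] = len(hnum) + 1
                inner = rec(self.children[v][0], v)
                return f"({inner})#H{hnum[v]}" + suffix
            if not self.children[v]:
                return self.labels[v] + suffix
            kids = sorted(self.children[v], key=lambda c: sig[c])
            return "(" + ",".join(rec(c, v) for c in kids) + ")" + suffix

        return rec(self.root, None) + ";"

    def canonical_topology(self) -> str:
        """Parameter-free canonical extended Newick, for dedup and caching."""
        if self._canonical is None:
            self._canonical = self.to_newick(include_params=False)
        return self._canonical

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PhyloNetwork({self.to_newick()!r})"


# ---------------------------------------------------------------------------
# Extended Newick parsing
# ---------------------------------------------------------------------------


def _tokenize(text: str) -> list[str]:
    tokens = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
        elif ch in "(),;:":
            tokens.append(ch)
            i += 1
        else:
            j = i
            while j < n and text[j] not in "(),;:" and not text[j].isspace():
                j += 1
            tokens.append(text[i:j])
            i = j
    return tokens


class _ENewickParser:
    """Recursive-descent parser for the extended Newick dialect."""

    def __init__(self, text: str):
        self.tokens = _tokenize(text)
        self.pos = 0
        self.counter = iter(range(10 ** 9))
        self.children: dict[int, list[int]] = {}
        self.labels: dict[int, str] = {}
        self.lengths: dict[tuple[int, int], float] = {}
        self.edge_gamma: dict[tuple[int, int], float] = {}
        self.hybrids: dict[str, int] = {}
        self.gamma_order: list[tuple[int, int]] = []

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        if self.pos >= len(self.tokens):
            raise NewickParseError("unexpected end of input")
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def expect(self, tok: str) -> None:
        got = self.take()
        if got != tok:
            raise NewickParseError(f"expected {tok!r}, got {got!r}")

    def parse(self) -> PhyloNetwork:
        root, _ = self.subtree()
        self.expect(";")
        if self.peek() is not None:
            raise NewickParseError("trailing content after ';'")
        major: dict[int, int] = {}
        gamma: dict[int, float] = {}
        for edge in self.gamma_order:
            p, r = edge
            g = self.edge_gamma[edge]
            if r in gamma:
                if abs(gamma[r] + g - 1.0) > 1e-6:
                    raise PhyloError(
                        "inheritance probabilities on a reticulation's two "
                        "parent edges must sum to 1")
            else:
                major[r] = p
                gamma[r] = g
        return PhyloNetwork(self.children, self.labels, self.lengths,
                            major, gamma)

    def subtree(self) -> tuple[int, list[float | None]]:
        """Parse one subtree; return (node id, colon-field values).  The
        caller owns the parent edge and attaches the fields to it."""
        if self.peek() == "(":
            self.take()
            kids = [self.subtree()]
            while self.peek() == ",":
                self.take()
                kids.append(self.subtree())
            self.expect(")")
            name = self._optional_name()
            node = self._node_for(name, has_children=True)
            for child, cvals in kids:
                self.children[node].append(child)
                self._attach(node, child, cvals)
        else:
            name = self.take()
            if name in "(),;:":
                raise NewickParseError(f"unexpected token {name!r}")
            node = self._node_for(name, has_children=False)
        return node, self._edge_fields()

    def _optional_name(self) -> str | None:
        tok = self.peek()
        if tok is not None and tok not in "(),;:":
            return self.take()
        return None

    def _node_for(self, name: str | None, has_children: bool) -> int:
        if name is not None and "#" in name:
            base, tag = name.split("#", 1)
            if tag in self.hybrids:
                node = self.hybrids[tag]
                if has_children and self.children[node]:
                    raise NewickParseError(
                        f"hybrid node #{tag} expanded more than once")
                return node
            node = next(self.counter)
            self.children[node] = []
            if base:
                self.labels[node] = base
            self.hybrids[tag] = node
            return node
        node = next(self.counter)
        self.children[node] = []
        if name:
            self.labels[node] = name
        return node

    def _edge_fields(self) -> list[float | None]:
        """Consume ``:length[:support[:gamma]]`` trailing fields."""
        vals: list[float | None] = []
        while self.peek() == ":":
            self.take()
            nxt = self.peek()
            if nxt == ":" or nxt in (",", ")", ";", None):
                vals.append(None)
                continue
            tok = self.take()
            try:
                vals.append(float(tok))
            except ValueError as exc:
                raise NewickParseError(f"bad numeric field {tok!r}") from exc
        return vals

    def _attach(self, parent: int, child: int,
                vals: list[float | None]) -> None:
        edge = (parent, child)
        if vals and vals[0] is not None:
            self.lengths[edge] = vals[0]
        if len(vals) >= 3 and vals[2] is not None:
            g = vals[2]
            if not 0.0 <= g <= 1.0:
                raise PhyloError(
                    f"inheritance probability {g} outside [0,1]")
            self.edge_gamma[edge] = g
            self.gamma_order.append(edge)


def parse_network(text: str) -> PhyloNetwork:
    """Parse an extended Newick string into a validated PhyloNetwork."""
    return _ENewickParser(text).parse()


def write_network(net: PhyloNetwork, include_params: bool = True) -> str:
    """Canonical extended Newick serialization of ``net``."""
    return net.to_newick(include_params=include_params)
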