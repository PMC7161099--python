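"""Topology-only inference of species trees and networks.

Because the integrated likelihood depends on the topology alone, inference
is a walk over topologies: exhaustive enumeration at small taxon counts
(3 rooted binary trees on 3 taxa, 15 on 4, 105 on 5, with optional
one-reticulation augmentation) or seeded hill climbing for anything
larger.  Both criteria are exposed: the integrated (NCM) log-likelihood,
maximized, and the MDC parsimony score, minimized.

Hill-climbing moves: rooted nearest-neighbor interchange on tree edges,
reticulation-edge addition, deletion, and relocation (delete + re-add).
Evaluated topologies are cached by canonical form, so no topology is
scored twice; ties break on the lexicographically smallest canonical
serialization.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .likelihood import LikelihoodConfig, gene_tree_log_prob_integrated
from .mdc import extra_lineages
from .phylo import GeneTree, PhyloError, PhyloNetwork

__all__ = ["SearchConfig", "enumerate_trees", "enumerate_topologies",
           "exhaustive_search", "hill_climb", "neighbors", "random_tree"]


@dataclass
class SearchConfig:
    """Settings for topology search."""

    max_reticulations: int = 0
    criterion: str = "ncm"          # "ncm" (integrated likelihood) or "mdc"
    mode: str = "exhaustive"        # "exhaustive" or "hill_climb"
    seed: int = 0
    max_iterations: int = 100
    num_restarts: int = 3
    tabu: bool = True

    def __post_init__(self):
        if self.criterion not in ("ncm", "mdc"):
            raise PhyloError(f"unknown criterion {self.criterion!r}")
        if self.mode not in ("exhaustive", "hill_climb"):
            raise PhyloError(f"unknown mode {self.mode!r}")
        if self.max_reticulations < 0:
            raise PhyloError("max_reticulations must be >= 0")


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------


def _nested_trees(labels: tuple[str, ...]):
    if len(labels) == 1:
        yield labels[0]
        return
    for t in _nested_trees(labels[:-1]):
        yield from _insert_leaf(t, labels[-1])


def _insert_leaf(t, x):
    yield (t, x)
    if isinstance(t, tuple):
        a, b = t
        for a2 in _insert_leaf(a, x):
            yield (a2, b)
        for b2 in _insert_leaf(b, x):
            yield (a, b2)


def _net_from_nested(nested) -> PhyloNetwork:
    children: dict[int, list[int]] = {}
    labels: dict[int, str] = {}
    counter = itertools.count()

    def build(x) -> int:
        v = next(counter)
        if isinstance(x, tuple):
            children[v] = [build(c) for c in x]
        else:
            children[v] = []
            labels[v] = str(x)
        return v

    build(nested)
    return PhyloNetwork(children, labels)


def enumerate_trees(taxa: Sequence[str]) -> Iterator[PhyloNetwork]:
    """All rooted binary species-tree topologies on ``taxa``
    ((2n-3)!! of them), each emitted once."""
    taxa = tuple(sorted(set(taxa)))
    if len(taxa) < 2:
        raise PhyloError("need at least two taxa")
    for nested in _nested_trees(taxa):
        yield _net_from_nested(nested)


def add_reticulation(net: PhyloNetwork, tail_edge: tuple[int, int],
                     head_edge: tuple[int, int]) -> PhyloNetwork | None:
    """Subdivide ``tail_edge`` and ``head_edge`` and add a directed
    reticulation edge between the new nodes; None if the result is not a
    valid network (e.g. cyclic)."""
    if tail_edge == head_edge:
        return None
    children = {v: list(ks) for v, ks in net.children.items()}
    nid = max(children) + 1
    s, hnode = nid, nid + 1
    (a, b), (c, d) = tail_edge, head_edge
    children[a].remove(b)
    children[a].append(s)
    children[s] = [b]
    children[c].remove(d)
    children[c].append(hnode)
    children[hnode] = [d]
    children[s].append(hnode)
    try:
        return PhyloNetwork(children, net.labels, major_parent={hnode: s})
    except PhyloError:
        return None


def enumerate_topologies(taxa: Sequence[str],
                         max_ret: int = 0) -> Iterator[PhyloNetwork]:
    """All topologies on ``taxa`` with up to ``max_ret`` reticulations
    (exhaustive use supports max_ret in {0, 1}), deduplicated by canonical
    form."""
    taxa = tuple(sorted(set(taxa)))
    if not 2 <= len(taxa) <= 6:
        raise PhyloError("exhaustive enumeration supports 2..6 taxa")
    if max_ret not in (0, 1):
        raise PhyloError("exhaustive enumeration supports max_ret in {0, 1}")
    seen: set[str] = set()
    for tree in enumerate_trees(taxa):
        key = tree.canonical_topology()
        if key not in seen:
            seen.add(key)
            yield tree
    if max_ret == 0:
        return
    for tree in enumerate_trees(taxa):
        edges = tree.edges()
        for tail_edge in edges:
            for head_edge in edges:
                net = add_reticulation(tree, tail_edge, head_edge)
                if net is None:
                    continue
                key = net.canonical_topology()
                if key not in seen:
                    seen.add(key)
                    yield net


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


class _Scorer:
    """Scores canonical topologies against a fixed multi-locus input;
    higher is better for both criteria (MDC is negated)."""

    def __init__(self, G: Sequence[GeneTree], criterion: str,
                 lik_cfg: LikelihoodConfig | None):
        self.counts: dict[str, int] = {}
        self.rep: dict[str, GeneTree] = {}
        for g in G:
            key = g.canonical()
            self.counts[key] = self.counts.get(key, 0) + 1
            self.rep.setdefault(key, g)
        self.criterion = criterion
        self.lik_cfg = lik_cfg or LikelihoodConfig()
        self.cache: dict[str, float] = {}
        self.trace: list[tuple[str, float]] = []
        self.accept_paths: list[list[tuple[str, float]]] = []

    def score(self, net: PhyloNetwork) -> float:
        key = net.canonical_topology()
        if key in self.cache:
            return self.cache[key]
        if self.criterion == "ncm":
            val = sum(n * gene_tree_log_prob_integrated(
                self.rep[k], net, self.lik_cfg)
                for k, n in self.counts.items())
        else:
            val = -float(sum(n * extra_lineages(self.rep[k], net)
                             for k, n in self.counts.items()))
        self.cache[key] = val
        self.trace.append((key, val))
        return val

    @property
    def n_evaluations(self) -> int:
        return len(self.trace)


# ---------------------------------------------------------------------------
# exhaustive search
# ---------------------------------------------------------------------------


def exhaustive_search(G: Sequence[GeneTree], cfg: SearchConfig,
                      lik_cfg: LikelihoodConfig | None = None):
    """Score every topology; return (best net, best score, scorer).

    Ties break on lexicographically smallest canonical serialization; the
    full co-optimal set is available from the scorer's cache.
    """
    taxa = sorted(G[0].leaf_labels) if G else None
    if not G:
        raise PhyloError("empty gene-tree input")
    scorer = _Scorer(G, cfg.criterion, lik_cfg)
    best_net, best = None, -np.inf
    for net in enumerate_topologies(taxa, cfg.max_reticulations):
        s = scorer.score(net)
        if s > best + 1e-12 or (abs(s - best) <= 1e-12 and best_net is not None
                                and net.canonical_topology()
                                < best_net.canonical_topology()):
            best_net, best = net, max(s, best)
    return best_net, best, scorer


def co_optima(scorer: _Scorer, best: float, tol: float = 1e-9) -> list[str]:
    """Canonical topologies whose score ties the optimum within ``tol``."""
    return sorted(k for k, v in scorer.cache.items() if abs(v - best) <= tol)


# ---------------------------------------------------------------------------
# hill climbing
# ---------------------------------------------------------------------------


def delete_reticulation(net: PhyloNetwork,
                        parent_edge: tuple[int, int]) -> PhyloNetwork | None:
    """Remove one parent edge of a reticulation and suppress the resulting
    degree-2 nodes; None if invalid."""
    p, r = parent_edge
    if len(net.parents[r]) != 2:
        return None
    children = {v: list(ks) for v, ks in net.children.items()}
    children[p].remove(r)
    # suppress chains: any node with exactly one parent and one child
    def parents_of(v):
        return [q for q, ks in children.items() if v in ks]

    changed = True
    while changed:
        changed = False
        for v in list(children):
            if v in net.labels:
                continue
            kids = children.get(v)
            if kids is None:
                continue
            pars = parents_of(v)
            if len(kids) == 0:
                for q in pars:
                    children[q].remove(v)
                del children[v]
                changed = True
            elif len(kids) == 1 and len(pars) == 1:
                q = pars[0]
                children[q].remove(v)
                children[q].append(kids[0])
                del children[v]
                changed = True
            elif len(kids) == 1 and len(pars) == 0 and len(children) > 2:
                # old root left with a single child: promote the child
                del children[v]
                changed = True
    try:
        return PhyloNetwork(children, net.labels)
    except PhyloError:
        return None


def _nni_moves(net: PhyloNetwork) -> Iterator[PhyloNetwork]:
    """Rooted NNI: for an edge (u, v) between tree nodes, swap a child of
    v with another child of u."""
    for u, v in net.edges():
        if len(net.parents[v]) != 1 or not net.children[v]:
            continue  # v must be an internal tree node
        for c in net.children[v]:
            for d in net.children[u]:
                if d == v:
                    continue
                children = {x: list(ks) for x, ks in net.children.items()}
                children[v].remove(c)
                children[u].append(c)
                children[u].remove(d)
                children[v].append(d)
                try:
                    yield PhyloNetwork(children, net.labels,
                                       major_parent=dict(net.major_parent))
                except PhyloError:
                    continue


def neighbors(net: PhyloNetwork, max_ret: int) -> Iterator[PhyloNetwork]:
    """One-move neighborhood: NNI, reticulation addition, deletion and
    relocation (deletion followed by re-addition)."""
    yield from _nni_moves(net)
    deletions = []
    for r in net.reticulations:
        for p in net.parents[r]:
            d = delete_reticulation(net, (p, r))
            if d is not None:
                deletions.append(d)
                yield d
    bases = [net] if net.n_reticulations < max_ret else []
    bases += deletions  # relocation: re-add after deletion
    for base in bases:
        edges = base.edges()
        for te in edges:
            for he in edges:
                cand = add_reticulation(base, te, he)
                if cand is not None:
                    yield cand


def random_tree(taxa: Sequence[str],
                rng: np.random.Generator) -> PhyloNetwork:
    """Random starting tree by random sequential joining."""
    items: list = list(sorted(taxa))
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        b = items.pop(j)
        a = items.pop(i)
        items.append((a, b))
    return _net_from_nested(items[0])


def hill_climb(G: Sequence[GeneTree], cfg: SearchConfig,
               lik_cfg: LikelihoodConfig | None = None):
    """Seeded steepest-ascent hill climbing with restarts.

    Returns (best net, best score, scorer); ``scorer.trace`` lists every
    (canonical topology, score) in evaluation order — with ``cfg.tabu``
    each canonical topology is scored at most once across the whole run.
    """
    if not G:
        raise PhyloError("empty gene-tree input")
    taxa = sorted(G[0].leaf_labels)
    rng = np.random.default_rng(cfg.seed)
    scorer = _Scorer(G, cfg.criterion, lik_cfg)
    scorer.accept_paths = []  # accepted (topology, score) per restart
    best_net, best = None, -np.inf
    for _restart in range(max(1, cfg.num_restarts)):
        cur = random_tree(taxa, rng)
        cur_score = scorer.score(cur)
        path = [(cur.canonical_topology(), cur_score)]
        scorer.accept_paths.append(path)
        for _it in range(cfg.max_iterations):
            cand_best, cand_score = None, cur_score
            seen_here = set()
            for nb in neighbors(cur, cfg.max_reticulations):
                key = nb.canonical_topology()
                if key in seen_here:
                    continue
                seen_here.add(key)
                if cfg.tabu and key in scorer.cache:
                    s = scorer.cache[key]
                else:
                    s = scorer.score(nb)
                if s > cand_score + 1e-12 or (
                        cand_best is not None
                        and abs(s - cand_score) <= 1e-12
                        and key < cand_best.canonical_topology()):
                    cand_best, cand_score = nb, max(s, cand_score)
            if cand_best is None:
                break
            cur, cur_score = cand_best, cand_score
            path.append((cur.canonical_topology(), cur_score))
        if cur_score > best + 1e-12 or (
                best_net is not None and abs(cur_score - best) <= 1e-12
                and cur.canonical_topology() < best_net.canonical_topology()):
            best_net, best = cur, max(cur_score, best)
    return best_net, best, scorer
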