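"""Multispecies (network) coalescent simulation of gene-tree topologies.

One lineage enters at each leaf; within an edge of length ``lambda``
(coalescent units) each pair of extant lineages coalesces at rate 1, i.e.
waiting times are exponential with rate k(k-1)/2; at a reticulation node
each lineage independently follows the major parent edge with probability
``gamma``; above the root coalescence continues until a single lineage
remains.  Only topologies are returned.

Two sampling regimes for multi-locus data sets:

* ``common``: one fixed setting of all branch lengths and inheritance
  probabilities shared by every locus (the common-mechanism data of the
  comparison experiments; reference settings use lengths 1 or 2 and
  gamma 0.5);
* ``ncm``: fresh per-locus draws — every branch length uniform on
  (0, upper) (upper 2 or 4) and every inheritance probability uniform on
  (0, 1) — so each locus evolves under its own mechanism.

A per-locus parameter log is returned so that no-common-mechanism data
sets are reproducible row by row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phylo import GeneTree, PhyloError, PhyloNetwork

__all__ = ["SimRegime", "simulate_gene_tree", "simulate_dataset"]


@dataclass
class SimRegime:
    """Sampling law for per-locus continuous parameters."""

    mode: str = "common"            # "common" or "ncm"
    branch_length_value: float = 1.0   # common mode: every edge length
    branch_length_upper: float = 2.0   # ncm mode: lengths ~ U(0, upper)
    gamma_value: float = 0.5           # common mode: every gamma
    n_loci: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("common", "ncm"):
            raise PhyloError(f"unknown regime mode {self.mode!r}")
        if self.branch_length_value <= 0 or self.branch_length_upper <= 0:
            raise PhyloError("branch lengths must be positive")
        if not 0.0 <= self.gamma_value <= 1.0:
            raise PhyloError("gamma_value must lie in [0, 1]")
        if self.n_loci < 1:
            raise PhyloError("n_loci must be >= 1")


def _coalesce_in_edge(lineages: list, lam: float,
                      rng: np.random.Generator) -> list:
    """Exact pure-death coalescent within one branch of length ``lam``."""
    t = 0.0
    while len(lineages) >= 2:
        k = len(lineages)
        t += rng.exponential(2.0 / (k * (k - 1)))
        if t > lam:
            break
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        b = lineages.pop(j)
        a = lineages.pop(i)
        lineages.append((a, b))
    return lineages


def simulate_gene_tree(net: PhyloNetwork,
                       rng: np.random.Generator) -> GeneTree:
    """Draw one gene-tree topology from the coalescent on ``net``.

    ``net`` must carry branch lengths on every edge that two or more
    lineages may traverse, and an inheritance probability on every
    reticulation.
    """
    exiting: dict[tuple[int, int], list] = {}
    for v in net.topological_order():
        kids = net.children[v]
        if not net.parents[v]:  # root: coalesce everything
            lineages = [x for c in kids for x in exiting[(v, c)]]
            lineages = _coalesce_in_edge(lineages, np.inf, rng)
            nested = lineages[0]
            return GeneTree.from_nested(
                nested if isinstance(nested, tuple) else (nested,))
        if len(net.parents[v]) == 2:  # reticulation: route lineages
            gam = net.gamma.get(v)
            if gam is None:
                raise PhyloError(
                    f"reticulation node {v} has no inheritance probability")
            src = exiting[(v, kids[0])]
            b1, b2 = net.b1_edge(v), net.b2_edge(v)
            s1, s2 = [], []
            for x in src:
                (s1 if rng.random() < gam else s2).append(x)
            for edge, s in ((b1, s1), (b2, s2)):
                lam = net.lengths.get(edge)
                if lam is None:
                    if len(s) >= 2:
                        raise PhyloError(
                            f"edge {net.edge_name(edge)} has no length")
                    lam = 0.0
                exiting[edge] = _coalesce_in_edge(s, lam, rng)
            continue
        if not kids:
            entering = [net.labels[v]]
        else:
            entering = [x for c in kids for x in exiting[(v, c)]]
        edge = (net.parents[v][0], v)
        lam = net.lengths.get(edge)
        if lam is None:
            if len(entering) >= 2:
                raise PhyloError(
                    f"edge {net.edge_name(edge)} has no branch length")
            lam = 0.0
        exiting[edge] = _coalesce_in_edge(entering, lam, rng)
    raise PhyloError("network has no root")  # pragma: no cover


def simulate_dataset(net: PhyloNetwork, regime: SimRegime
                     ) -> tuple[list[GeneTree], list[dict]]:
    """Simulate ``regime.n_loci`` gene trees from the topology of ``net``.

    Returns (gene trees, parameter log).  The log holds one row (dict of
    edge name -> length and ``gamma@<edge>`` -> inheritance probability)
    in common mode, and one row per locus in ncm mode.  Fully determined
    by ``regime.seed``.
    """
    rng = np.random.default_rng(regime.seed)
    edges = net.edges()
    rets = net.reticulations

    def param_row(lengths, gammas, locus):
        row = {"locus": locus}
        for e in edges:
            row[net.edge_name(e)] = lengths[e]
        for r in rets:
            row["gamma@" + net.edge_name(net.b1_edge(r))] = gammas[r]
        return row

    trees: list[GeneTree] = []
    log: list[dict] = []
    if regime.mode == "common":
        lengths = {e: regime.branch_length_value for e in edges}
        gammas = {r: regime.gamma_value for r in rets}
        param_net = net.with_lengths(lengths).with_gammas(gammas)
        log.append(param_row(lengths, gammas, "all"))
        for _ in range(regime.n_loci):
            trees.append(simulate_gene_tree(param_net, rng))
    else:
        for i in range(regime.n_loci):
            lengths = {e: float(rng.uniform(0.0, regime.branch_length_upper))
                       for e in edges}
            gammas = {r: float(rng.uniform(0.0, 1.0)) for r in rets}
            param_net = net.with_lengths(lengths).with_gammas(gammas)
            log.append(param_row(lengths, gammas, i))
            trees.append(simulate_gene_tree(param_net, rng))
    return trees, log
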