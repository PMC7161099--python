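"""Minimize-deep-coalescences (MDC) parsimony scoring.

The deep-coalescence cost of a gene tree on a species phylogeny is the
number of "extra lineages": summed over the network's edges, the number of
lineages exiting the edge beyond the first.  On a network the cost is
minimized jointly over coalescence placements and reticulation routings;
inheritance probabilities play no role.  With no reticulations this is the
classic species-tree MDC criterion.
"""

from __future__ import annotations

from typing import Sequence

from .histories import enumerate_histories
from .phylo import GeneTree, PhyloNetwork

__all__ = ["extra_lineages", "mdc_score"]


def extra_lineages(g: GeneTree, net: PhyloNetwork) -> int:
    """Fewest extra lineages over all coalescent histories of ``g``."""
    best = None
    for h in enumerate_histories(g, net):
        cost = sum(v - 1 for _e, _u, v, _m in h.edge_records)
        if best is None or cost < best:
            best = cost
            if best == 0:
                break
    return best


def mdc_score(G: Sequence[GeneTree], net: PhyloNetwork) -> int:
    """Total MDC cost of a multi-locus input, cached per topology."""
    cache: dict[str, int] = {}
    total = 0
    for g in G:
        key = g.canonical()
        if key not in cache:
            cache[key] = extra_lineages(g, net)
        total += cache[key]
    return total
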