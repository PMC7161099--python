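"""Gene-tree probabilities under the multispecies (network) coalescent,
with and without the continuous parameters integrated out.

Fixed-parameter pmf
-------------------
``P(g | Psi, Lambda, Gamma)`` sums over coalescent histories; each history
contributes the product over network edges of ``(w_b/d_b) * p_{u_b v_b}
(lambda_b)``, the root term ``w/d``, and for each reticulation
``gamma_i^{u_b1} (1-gamma_i)^{u_b2}``.

``p_uv(t)`` is the classic lineage-count transition probability of the
coalescent pure-death chain (Tavare's formula),

    p_uv(t) = sum_{j=v}^{u} e^{-j(j-1)t/2} f(u, v, j),
    f(u, v, j) = (2j-1)(-1)^{j-v} / (v! (j-v)! (v+j-1))
                 * prod_{y=0}^{j-1} (v+y)(u-y)/(u+y).

The coefficients ``f`` are computed in exact rational arithmetic; the
alternating sum is assembled in floating point.

Integrated (no-common-mechanism) likelihood
-------------------------------------------
Each branch length carries an independent Exponential(rate) prior
truncated to ``(0, tau]``; integrating term by term,

    p_uv^tau = 1/(1-e^{-rate*tau}) * sum_j f(u,v,j) * rate/(j(j-1)/2+rate)
               * (1 - e^{-(j(j-1)/2+rate) tau}),

with the untruncated limit (``tau = inf``, the library default)
``sum_j f(u,v,j) * rate/(j(j-1)/2 + rate)``, evaluated exactly in
rationals.  Each inheritance probability carries a conjugate Beta(a, b)
prior, giving per reticulation the factor
``B(u_b1 + a, u_b2 + b) / B(a, b)``; the default Beta(2, 2) reproduces
``6 * (u_b1+1)! (u_b2+1)! / (u_b1+u_b2+3)!``.

The per-history products are accumulated in log space and the per-locus
probabilities combined with logsumexp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from typing import Sequence

from scipy.special import betaln, logsumexp

from .histories import enumerate_histories, order_counts
from .phylo import GeneTree, LabelMismatchError, PhyloError, PhyloNetwork

__all__ = ["INFINITY", "LikelihoodConfig", "f_coeff", "p_uv",
           "p_uv_integrated", "history_log_prob", "history_prob",
           "gene_tree_prob", "history_log_prob_integrated",
           "history_prob_integrated", "gene_tree_log_prob_integrated",
           "gene_tree_prob_integrated", "multilocus_loglik"]

INFINITY = math.inf


@dataclass(frozen=True)
class LikelihoodConfig:
    """Prior settings for the integrated likelihood.

    tau : truncation bound of the exponential branch-length prior, in
        coalescent units; ``math.inf`` (default) selects the untruncated
        exponential.
    exp_rate : rate of the exponential prior (default 1).
    beta_a, beta_b : shapes of the Beta prior on inheritance
        probabilities (default 2, 2).
    """

    tau: float = INFINITY
    exp_rate: float = 1.0
    beta_a: float = 2.0
    beta_b: float = 2.0

    def __post_init__(self):
        if not self.tau > 0:
            raise PhyloError("tau must be positive (or math.inf)")
        if not self.exp_rate > 0:
            raise PhyloError("exp_rate must be positive")
        if not (self.beta_a > 0 and self.beta_b > 0):
            raise PhyloError("Beta shape parameters must be positive")


def _check_uv(u: int, v: int) -> None:
    if not 1 <= v <= u:
        raise PhyloError(f"require 1 <= v <= u, got u={u}, v={v}")


@lru_cache(maxsize=None)
def f_coeff(u: int, v: int, j: int) -> Fraction:
    """Exact rational coefficient f(u, v, j) of the transition density."""
    c = Fraction((2 * j - 1) * (-1) ** (j - v),
                 math.factorial(v) * math.factorial(j - v) * (v + j - 1))
    for y in range(j):
        c *= Fraction((v + y) * (u - y), u + y)
    return c


def p_uv(u: int, v: int, t: float) -> float:
    """Probability that ``u`` gene lineages coalesce into ``v`` within a
    branch of length ``t`` coalescent units."""
    _check_uv(u, v)
    if t < 0:
        raise PhyloError("t must be nonnegative")
    total = math.fsum(
        math.exp(-0.5 * j * (j - 1) * t) * float(f_coeff(u, v, j))
        for j in range(v, u + 1))
    # the alternating sum can round to a tiny negative number
    return min(max(total, 0.0), 1.0)


@lru_cache(maxsize=None)
def _p_uv_integrated_cached(u: int, v: int, tau: float,
                            rate: float) -> float:
    if math.isinf(tau):
        r = Fraction(rate)
        total = Fraction(0)
        for j in range(v, u + 1):
            q = Fraction(j * (j - 1), 2)
            total += f_coeff(u, v, j) * r / (q + r)
        return float(total)
    scale = 1.0 / -math.expm1(-rate * tau)
    total = math.fsum(
        float(f_coeff(u, v, j)) * rate / (0.5 * j * (j - 1) + rate)
        * -math.expm1(-(0.5 * j * (j - 1) + rate) * tau)
        for j in range(v, u + 1))
    return min(max(scale * total, 0.0), 1.0)


def p_uv_integrated(u: int, v: int,
                    cfg: LikelihoodConfig | None = None) -> float:
    """``p_uv`` with the branch length integrated against its truncated
    (or untruncated, ``tau = inf``) exponential prior."""
    cfg = cfg or LikelihoodConfig()
    _check_uv(u, v)
    return _p_uv_integrated_cached(u, v, cfg.tau, cfg.exp_rate)


# ---------------------------------------------------------------------------
# history-level probabilities
# ---------------------------------------------------------------------------


def _log(x: float) -> float:
    return math.log(x) if x > 0.0 else -math.inf


def _log_wd_terms(h, g: GeneTree) -> float:
    lp = 0.0
    u_root, merges_root = h.root_record
    w, d = order_counts(u_root, 1, merges_root, g)
    lp += math.log(w) - math.log(d)
    for _edge, u, v, merges in h.edge_records:
        w, d = order_counts(u, v, merges, g)
        lp += math.log(w) - math.log(d)
    return lp


def history_log_prob(h, g: GeneTree, net: PhyloNetwork) -> float:
    """log P(h | Psi, Lambda, Gamma) with fixed branch lengths and
    inheritance probabilities taken from ``net``."""
    lp = _log_wd_terms(h, g)
    for edge, u, v, _merges in h.edge_records:
        if u >= 2:
            lam = net.lengths.get(edge)
            if lam is None:
                raise PhyloError(
                    f"edge {net.edge_name(edge)} has no branch length")
            lp += _log(p_uv(u, v, lam))
    for r, s1, s2 in h.routing:
        gam = net.gamma.get(r)
        if gam is None:
            raise PhyloError(
                f"reticulation node {r} has no inheritance probability")
        u1, u2 = len(s1), len(s2)
        if u1:
            lp += u1 * _log(gam)
        if u2:
            lp += u2 * _log(1.0 - gam)
    return lp


def history_prob(h, g: GeneTree, net: PhyloNetwork) -> float:
    """P(h | Psi, Lambda, Gamma)."""
    return math.exp(history_log_prob(h, g, net))


def history_log_prob_integrated(h, g: GeneTree, net: PhyloNetwork,
                                cfg: LikelihoodConfig | None = None) -> float:
    """log P(h | Psi): branch lengths and inheritance probabilities
    analytically integrated out; only the topology of ``net`` is used."""
    cfg = cfg or LikelihoodConfig()
    lp = _log_wd_terms(h, g)
    for _edge, u, v, _merges in h.edge_records:
        if u >= 2:
            lp += _log(p_uv_integrated(u, v, cfg))
    lb0 = betaln(cfg.beta_a, cfg.beta_b)
    for _r, s1, s2 in h.routing:
        u1, u2 = len(s1), len(s2)
        lp += betaln(u1 + cfg.beta_a, u2 + cfg.beta_b) - lb0
    return lp


def history_prob_integrated(h, g: GeneTree, net: PhyloNetwork,
                            cfg: LikelihoodConfig | None = None) -> float:
    """P(h | Psi) under the NCM priors."""
    return math.exp(history_log_prob_integrated(h, g, net, cfg))


# ---------------------------------------------------------------------------
# gene-tree and multi-locus probabilities
# ---------------------------------------------------------------------------


def gene_tree_prob(g: GeneTree, net: PhyloNetwork) -> float:
    """P(g | Psi, Lambda, Gamma): fixed-parameter gene-tree pmf."""
    logs = [history_log_prob(h, g, net)
            for h in enumerate_histories(g, net)]
    return float(math.exp(logsumexp(logs)))


def gene_tree_log_prob_integrated(g: GeneTree, net: PhyloNetwork,
                                  cfg: LikelihoodConfig | None = None
                                  ) -> float:
    """log P(g | Psi): topology-only integrated gene-tree probability."""
    logs = [history_log_prob_integrated(h, g, net, cfg)
            for h in enumerate_histories(g, net)]
    return float(logsumexp(logs))


def gene_tree_prob_integrated(g: GeneTree, net: PhyloNetwork,
                              cfg: LikelihoodConfig | None = None) -> float:
    """P(g | Psi) under the NCM priors."""
    return math.exp(gene_tree_log_prob_integrated(g, net, cfg))


def multilocus_loglik(G: Sequence[GeneTree], net: PhyloNetwork,
                      cfg: LikelihoodConfig | None = None) -> float:
    """Integrated log-likelihood ``log f(Psi | G) = sum_i log P(g_i | Psi)``.

    Identical gene-tree topologies are computed once (cached on the
    canonical Newick string).
    """
    cache: dict[str, float] = {}
    total = 0.0
    for i, g in enumerate(G):
        if g.leaf_labels != net.leaf_labels:
            raise LabelMismatchError(
                f"locus {i}: gene tree labels do not match the network")
        key = g.canonical()
        if key not in cache:
            cache[key] = gene_tree_log_prob_integrated(g, net, cfg)
        total += cache[key]
    return total
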