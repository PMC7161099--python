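"""Model/Results interface for topology inference from gene trees.

``NCMTopologyModel`` wraps a multi-locus collection of rooted binary gene
trees; ``fit`` searches species-tree/network topology space under the
integrated no-common-mechanism likelihood (or the MDC parsimony score)
and returns an ``NCMTopologyResults`` with the chosen topology, its
score, the co-optimal set, and the evaluation trace.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

from .likelihood import LikelihoodConfig, multilocus_loglik
from .mdc import mdc_score
from .netprops import displayed_trees
from .phylo import GeneTree, PhyloError, PhyloNetwork, parse_gene_trees
from .search import SearchConfig, co_optima, exhaustive_search, hill_climb

__all__ = ["NCMTopologyModel", "NCMTopologyResults"]


class NCMTopologyModel:
    """Integrated-likelihood model of a species phylogeny topology.

    Parameters
    ----------
    gene_trees : sequence of GeneTree
        One rooted binary gene tree per locus, all on the same taxa.
    prior : LikelihoodConfig, optional
        Branch-length and inheritance-probability priors; defaults to the
        untruncated Exponential(1) and Beta(2, 2).
    """

    def __init__(self, gene_trees: Sequence[GeneTree],
                 prior: LikelihoodConfig | None = None):
        if not gene_trees:
            raise PhyloError("need at least one gene tree")
        taxa = gene_trees[0].leaf_labels
        for i, g in enumerate(gene_trees):
            if g.leaf_labels != taxa:
                raise PhyloError(f"locus {i}: leaf labels differ from locus 0")
        self.gene_trees = list(gene_trees)
        self.prior = prior or LikelihoodConfig()
        self.taxa = sorted(taxa)

    @classmethod
    def from_newick(cls, source: str | Path,
                    prior: LikelihoodConfig | None = None
                    ) -> "NCMTopologyModel":
        """Build from multi-line Newick text or a path to such a file."""
        if isinstance(source, Path) or ("\n" not in str(source)
                                        and Path(str(source)).is_file()):
            text = Path(source).read_text()
        else:
            text = str(source)
        return cls(parse_gene_trees(text), prior=prior)

    @property
    def n_loci(self) -> int:
        return len(self.gene_trees)

    def loglike(self, network: PhyloNetwork) -> float:
        """Integrated log-likelihood of a candidate topology."""
        return multilocus_loglik(self.gene_trees, network, self.prior)

    def mdc(self, network: PhyloNetwork) -> int:
        """Total deep-coalescence cost of a candidate topology."""
        return mdc_score(self.gene_trees, network)

    def fit(self, max_reticulations: int = 0, method: str = "exhaustive",
            criterion: str = "ncm", seed: int = 0,
            max_iterations: int = 100, num_restarts: int = 3
            ) -> "NCMTopologyResults":
        """Search topology space and return the optimum.

        ``method`` is "exhaustive" (all topologies, up to 6 taxa and one
        reticulation) or "hill_climb"; ``criterion`` is "ncm" (maximize
        the integrated likelihood) or "mdc" (minimize extra lineages).
        """
        cfg = SearchConfig(max_reticulations=max_reticulations,
                           criterion=criterion, mode=method, seed=seed,
                           max_iterations=max_iterations,
                           num_restarts=num_restarts)
        if method == "exhaustive":
            net, score, scorer = exhaustive_search(
                self.gene_trees, cfg, self.prior)
        else:
            net, score, scorer = hill_climb(self.gene_trees, cfg, self.prior)
        return NCMTopologyResults(self, cfg, net, score, scorer)


class NCMTopologyResults:
    """Inference results: optimal topology, score and diagnostics."""

    def __init__(self, model: NCMTopologyModel, config: SearchConfig,
                 network: PhyloNetwork, score: float, scorer):
        self.model = model
        self.config = config
        self.network = network
        self.score = score
        self._scorer = scorer
        self.trace = list(scorer.trace)
        self.n_evaluations = scorer.n_evaluations

    @property
    def loglik(self) -> float:
        """Integrated log-likelihood of the fitted topology (recomputed
        when the fit criterion was MDC)."""
        if self.config.criterion == "ncm":
            return self.score
        return self.model.loglike(self.network)

    @property
    def mdc(self) -> int:
        return self.model.mdc(self.network)

    def co_optimal(self, tol: float = 1e-9) -> list[str]:
        """Canonical topologies tying the optimum among those evaluated."""
        return co_optima(self._scorer, self.score, tol)

    def displayed(self) -> frozenset[str]:
        return displayed_trees(self.network)

    def summary(self) -> str:
        lines = [
            "NCM topology inference".center(58),
            "=" * 58,
            f"{'No. loci:':<28}{self.model.n_loci}",
            f"{'No. taxa:':<28}{len(self.model.taxa)}",
            f"{'Criterion:':<28}{self.config.criterion}",
            f"{'Search mode:':<28}{self.config.mode}",
            f"{'Max reticulations:':<28}{self.config.max_reticulations}",
            f"{'Prior tau:':<28}{self.model.prior.tau}",
            f"{'Prior Beta shapes:':<28}"
            f"({self.model.prior.beta_a:g}, {self.model.prior.beta_b:g})",
            f"{'Topologies evaluated:':<28}{self.n_evaluations}",
            "-" * 58,
            f"{'Best topology:':<28}{self.network.canonical_topology()}",
            f"{'Integrated log-likelihood:':<28}{self.loglik:.4f}",
            f"{'MDC extra lineages:':<28}{self.mdc}",
            f"{'Co-optimal topologies:':<28}{len(self.co_optimal())}",
            "=" * 58,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"<NCMTopologyResults {self.network.canonical_topology()} "
                f"score={self.score:.4f}>")
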