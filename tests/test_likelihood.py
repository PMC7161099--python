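"""Fixed-parameter and integrated gene-tree probabilities."""

import math

import numpy as np
import pytest
from scipy.integrate import quad, tplquad

from netcoal import (GeneTree, INFINITY, LikelihoodConfig, PhyloError,
                     enumerate_histories, gene_tree_prob,
                     gene_tree_prob_integrated, multilocus_loglik,
                     parse_network, p_uv, p_uv_integrated)
from netcoal.likelihood import history_log_prob, history_prob_integrated
from netcoal.phylo import LabelMismatchError
from netcoal.search import enumerate_trees

from .oracles import p_uv_expm, p_uv_quad


class TestTransitionProbability:
    def test_single_lineage_is_certain(self):
        for t in (0.0, 0.5, 50.0):
            assert p_uv(1, 1, t) == 1.0

    def test_two_lineage_closed_forms(self):
        assert p_uv(2, 2, 1.0) == pytest.approx(math.exp(-1), abs=1e-14)
        assert p_uv(2, 1, 1.0) == pytest.approx(1 - math.exp(-1), abs=1e-14)

    def test_identity_at_zero_time(self):
        for u in range(1, 9):
            assert p_uv(u, u, 0.0) == pytest.approx(1.0, abs=1e-12)

    def test_matches_matrix_exponential(self):
        """Agreement with the pure-death-chain oracle to 1e-10."""
        for u in range(1, 9):
            for v in range(1, u + 1):
                for t in (0.1, 1.0, 5.0):
                    assert p_uv(u, v, t) == pytest.approx(
                        p_uv_expm(u, v, t), abs=1e-10)

    def test_rows_sum_to_one(self):
        for u in range(1, 9):
            for t in (0.1, 1.0, 5.0):
                assert sum(p_uv(u, v, t) for v in range(1, u + 1)) \
                    == pytest.approx(1.0, abs=1e-10)

    def test_domain_errors(self):
        with pytest.raises(PhyloError):
            p_uv(2, 3, 1.0)
        with pytest.raises(PhyloError):
            p_uv(2, 0, 1.0)
        with pytest.raises(PhyloError):
            p_uv(2, 2, -0.1)


class TestIntegratedTransition:
    def test_trivial_single_lineage(self):
        for cfg in (LikelihoodConfig(), LikelihoodConfig(tau=1.0)):
            assert p_uv_integrated(1, 1, cfg) == 1.0

    def test_untruncated_two_lineages(self):
        # int_0^inf e^{-t} e^{-t} dt = 1/2
        assert p_uv_integrated(2, 2) == pytest.approx(0.5, abs=1e-14)

    def test_truncated_two_lineages(self):
        expect = (1 - math.exp(-2)) / (2 * (1 - math.exp(-1)))
        assert p_uv_integrated(2, 2, LikelihoodConfig(tau=1.0)) \
            == pytest.approx(expect, abs=1e-14)

    def test_matches_quadrature(self):
        """Agreement with numerical integration of p_uv x prior to 1e-8,
        truncated and untruncated, including a non-unit rate."""
        for u in range(1, 7):
            for v in range(1, u + 1):
                for tau in (0.5, 1.0, 2.0, INFINITY):
                    got = p_uv_integrated(u, v, LikelihoodConfig(tau=tau))
                    assert got == pytest.approx(
                        p_uv_quad(u, v, tau), abs=1e-8)
        assert p_uv_integrated(3, 1, LikelihoodConfig(exp_rate=2.0)) \
            == pytest.approx(p_uv_quad(3, 1, INFINITY, rate=2.0), abs=1e-8)

    def test_truncation_converges_to_untruncated(self):
        for u in range(1, 7):
            for v in range(1, u + 1):
                far = p_uv_integrated(u, v, LikelihoodConfig(tau=50.0))
                lim = p_uv_integrated(u, v, LikelihoodConfig())
                assert abs(far - lim) < 1e-12

    def test_rows_sum_to_one(self):
        for u in range(1, 7):
            for tau in (0.5, 2.0, INFINITY):
                cfg = LikelihoodConfig(tau=tau)
                assert sum(p_uv_integrated(u, v, cfg)
                           for v in range(1, u + 1)) \
                    == pytest.approx(1.0, abs=1e-10)


class TestFixedParameterPmf:
    def test_history_contributions_three_taxon(self, tree3):
        g = GeneTree.from_newick("((A,B),C);")
        hs = enumerate_histories(g, tree3)
        by_root_u = {h.root_record[0]: h for h in hs}
        # AB on the internal edge: (1 - e^{-1}) * 1
        assert math.exp(history_log_prob(by_root_u[2], g, tree3)) \
            == pytest.approx(1 - math.exp(-1), abs=1e-12)
        # everything at the root: e^{-1} / 3
        assert math.exp(history_log_prob(by_root_u[3], g, tree3)) \
            == pytest.approx(math.exp(-1) / 3, abs=1e-12)

    def test_classic_three_taxon_distribution(self, tree3, gene3):
        match, mis1, mis2 = gene3
        assert gene_tree_prob(match, tree3) == pytest.approx(
            1 - 2 / 3 * math.exp(-1), abs=1e-12)
        for g in (mis1, mis2):
            assert gene_tree_prob(g, tree3) == pytest.approx(
                math.exp(-1) / 3, abs=1e-12)
        assert sum(gene_tree_prob(g, tree3) for g in gene3) \
            == pytest.approx(1.0, abs=1e-12)

    def test_missing_length_raises(self, gene3):
        bare = parse_network("((A,B),C);")
        with pytest.raises(PhyloError):
            gene_tree_prob(gene3[0], bare)

    def test_gamma_one_collapses_to_displayed_tree(self, net1ret, gene3):
        """With gamma=1 the network behaves exactly like the displayed
        tree that keeps the major edge."""
        net = net1ret.with_lengths(0.8).with_gammas(1.0)
        r = net.reticulations[0]
        kept = net.b1_edge(r)
        # the kept route sends B toward the clade with A or C
        probs = {g.canonical(): gene_tree_prob(g, net) for g in gene3}
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-10)
        # one topology keeps the full tree-like probability > 1/3
        assert max(probs.values()) > 0.5

    def test_normalization_fixed_parameters(self, net1ret, all_trees4):
        """Sum over all gene-tree topologies equals 1, on 4-taxon trees
        and the 1-reticulation network."""
        nets = [t.with_lengths(0.7) for t in all_trees4[:4]]
        nets.append(net1ret.with_lengths(1.3).with_gammas(0.3))
        for net in nets:
            taxa = sorted(net.leaf_labels)
            total = sum(
                gene_tree_prob(
                    GeneTree.from_newick(t.canonical_topology()), net)
                for t in enumerate_trees(taxa))
            assert total == pytest.approx(1.0, abs=1e-8)


class TestIntegratedPmf:
    def test_reticulation_factor_values(self, net1ret):
        """Beta(2,2) reticulation factors: no crossing lineage -> 1;
        one crossing lineage -> 1/2 (= 6 * 2!1!/4!)."""
        g = GeneTree.from_newick("((A,B),C);")
        hs = enumerate_histories(g, net1ret)
        r = net1ret.reticulations[0]
        # every history routes the single B lineage one way: factor 1/2
        # relative to the same history without the reticulation term.
        for h in hs:
            u1, u2 = h.ret_counts(r)
            assert u1 + u2 == 1
        total = sum(history_prob_integrated(h, g, net1ret) for h in hs)
        assert 0 < total < 1

    def test_three_taxon_integrated_values(self, tree3, gene3):
        bare = parse_network("((A,B),C);")
        match, mis1, mis2 = gene3
        assert gene_tree_prob_integrated(match, bare) == pytest.approx(
            2 / 3, abs=1e-12)
        assert gene_tree_prob_integrated(mis1, bare) == pytest.approx(
            1 / 6, abs=1e-12)
        assert gene_tree_prob_integrated(mis1, bare) == pytest.approx(
            gene_tree_prob_integrated(mis2, bare), abs=1e-15)

    def test_matches_quadrature_species_tree(self, gene3):
        """Integrated pmf equals quadrature of the fixed-parameter pmf
        against the exponential prior (1-d: only the internal branch
        affects the topology distribution)."""
        for g in gene3:
            def integrand(t, g=g):
                net = parse_network("((A,B),C);").with_lengths(t)
                return gene_tree_prob(g, net) * math.exp(-t)
            expect, _ = quad(integrand, 0, np.inf, limit=200)
            got = gene_tree_prob_integrated(g, parse_network("((A,B),C);"))
            assert got == pytest.approx(expect, abs=1e-6)

    def test_matches_quadrature_network(self, net1ret, gene3):
        """Full (t1, t2, gamma) integration against both priors on the
        1-reticulation network reproduces the analytic integration."""
        # only the two root edges ever carry two lineages; all other
        # edges hold a single lineage and drop out of the integrand
        root = net1ret.root
        internal = [(root, c) for c in net1ret.children[root]]

        for g in gene3[:2]:
            hs = enumerate_histories(g, net1ret)  # topology-only, reusable

            def integrand(gamma, t2, t1, g=g, hs=hs):
                lengths = {e: 1.0 for e in net1ret.edges()}
                lengths[internal[0]] = t1
                lengths[internal[1]] = t2
                net = net1ret.with_lengths(lengths).with_gammas(gamma)
                pg = sum(math.exp(history_log_prob(h, g, net)) for h in hs)
                return (pg * math.exp(-t1) * math.exp(-t2)
                        * 6 * gamma * (1 - gamma))
            expect, _ = tplquad(integrand, 0, 25, 0, 25, 0, 1,
                                epsabs=1e-8, epsrel=1e-6)
            got = gene_tree_prob_integrated(g, net1ret)
            assert got == pytest.approx(expect, abs=1e-6)

    def test_normalization_integrated(self, net1ret, all_trees4):
        """Sum over all topologies is 1 for every <=4-taxon species tree
        and the 1-reticulation network, across tau settings."""
        nets = list(enumerate_trees("ABC")) + list(all_trees4) + [net1ret]
        for net in nets:
            taxa = sorted(net.leaf_labels)
            genes = [GeneTree.from_newick(t.canonical_topology())
                     for t in enumerate_trees(taxa)]
            for tau in (0.5, 1.0, 2.0, INFINITY):
                cfg = LikelihoodConfig(tau=tau)
                total = sum(gene_tree_prob_integrated(g, net, cfg)
                            for g in genes)
                assert total == pytest.approx(1.0, abs=1e-8), \
                    (net.canonical_topology(), tau)


class TestMultilocus:
    def test_two_identical_loci_double_the_loglik(self, gene3):
        net = parse_network("((A,B),C);")
        one = multilocus_loglik([gene3[0]], net)
        two = multilocus_loglik([gene3[0], gene3[0]], net)
        assert two == pytest.approx(2 * one, abs=1e-12)

    def test_three_topologies_once_each(self, gene3):
        net = parse_network("((A,B),C);")
        got = multilocus_loglik(gene3, net)
        assert got == pytest.approx(math.log(2 / 3 * 1 / 6 * 1 / 6),
                                    abs=1e-10)

    def test_empty_input_is_zero(self):
        net = parse_network("((A,B),C);")
        assert multilocus_loglik([], net) == 0.0

    def test_mismatch_names_locus(self, gene3):
        net = parse_network("((A,B),C);")
        bad = GeneTree.from_newick("((A,B),D);")
        with pytest.raises(LabelMismatchError, match="locus 1"):
            multilocus_loglik([gene3[0], bad], net)
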