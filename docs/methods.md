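# Methods

## The model

`netcoal` computes probabilities of rooted gene-tree *topologies* evolving
inside a species phylogeny under the multispecies coalescent (MSC) and its
network extension (MSNC), and uses an analytically *integrated* form of
that likelihood — branch lengths and inheritance probabilities
marginalized over priors — to infer the species phylogeny's topology
alone. Marginalizing every locus independently gives a "no common
mechanism" (NCM) model: all loci share the species phylogeny's topology,
but each locus effectively evolves under its own draw of branch lengths
and inheritance probabilities.

### Species phylogenies

A species network is a rooted DAG whose leaves are bijectively labeled by
taxa: the root has indegree 0; leaves have indegree 1 and outdegree 0;
internal tree nodes indegree 1 and outdegree ≥ 2; reticulation nodes
indegree 2 and outdegree 1. Each reticulation carries an inheritance
probability γ on a designated (major) parent edge and 1−γ on the other.
Branch lengths λ are in coalescent units (generations / effective
population size). A species tree is the reticulation-free special case.
One allele is sampled per species: gene-tree leaf labels must equal the
network's leaf labels.

### Coalescent histories

The gene-tree pmf is a sum over *coalescent histories*: assignments of
every gene-tree coalescence to a network edge (or to the root, treated as
a virtual edge of infinite duration), together with a routing of each
gene lineage at each reticulation node. Routing must be explicit — two
histories with identical coalescence placements but different routings
contribute different γ exponents — so the enumeration is generative: the
network is traversed children-first, tracking the set of gene lineages
entering each edge, branching over every feasible coalescence subset on
every edge and every lineage partition at every reticulation. A history
contributes

    w/d · ∏_b (w_b/d_b) · p_{u_b v_b}(λ_b) · ∏_i γ_i^{u_{b1_i}} (1-γ_i)^{u_{b2_i}}

where u_b and v_b are the lineage counts entering and exiting edge b,
d_b = ∏_{k=v_b+1}^{u_b} C(k,2) counts all sequences of the u_b − v_b
pairwise coalescent events, and w_b counts those sequences compatible
with the gene tree — the number of linear extensions of the ancestry
partial order among the events placed on b, computed with the
hook-length formula for forests, |T|! / ∏_t |T_t|. The unsubscripted w/d
is the same computation at the root with v = 1 and no p term.

### Transition probabilities and their integrals

p_uv(t) is the lineage-count transition probability of the coalescent
pure-death chain (rate k(k−1)/2 from k to k−1):

    p_uv(t) = Σ_{j=v}^{u} e^{-j(j-1)t/2} f(u,v,j),
    f(u,v,j) = (2j-1)(-1)^{j-v} / (v!(j-v)!(v+j-1)) ∏_{y=0}^{j-1} (v+y)(u-y)/(u+y).

The summation runs j = v..u and the inner product to y = j−1; these are
the index conventions forced by p_uu(0) = 1 and validated against a
matrix-exponential oracle (printed sources sometimes transpose them).

With an independent Exponential(rate) prior truncated to (0, τ] on every
branch length, each p factor integrates term by term to

    p_uv^τ = 1/(1-e^{-rate·τ}) Σ_j f(u,v,j) · rate/(j(j-1)/2+rate)
             · (1-e^{-(j(j-1)/2+rate)τ}),

and in the untruncated limit τ → ∞ (the library default, matching the
simulation studies) to Σ_j f(u,v,j)·rate/(j(j−1)/2+rate), which is a
rational number and is evaluated exactly. With a conjugate Beta(a, b)
prior on each γ, the reticulation factor integrates to
B(u_{b1}+a, u_{b2}+b)/B(a, b); the default Beta(2,2) gives
6·(u_{b1}+1)!(u_{b2}+1)!/(u_{b1}+u_{b2}+3)!. The multi-locus integrated
log-likelihood is the sum of per-locus log P(g|Ψ), cached per canonical
gene-tree topology.

### Numerical policy

The f(u,v,j) coefficients are exact `Fraction`s (the alternating sum is
ill-conditioned in floating point); per-history products are accumulated
in log space and per-locus sums combined with logsumexp. p values are
clamped to [0, 1] to absorb rounding at the 1e-13 level in extreme
(u, t) corners. Ties in search scores are broken by lexicographically
smallest canonical serialization, making every search deterministic
given its seed.

## Inference

Because the integrated likelihood depends only on the topology, the
search walks topology space. Exhaustive mode enumerates all rooted
binary trees (3 on 3 taxa, 15 on 4, 105 on 5), optionally augmented with
every one-reticulation network obtained by subdividing two tree edges
and adding a cross edge (the virtual root edge is not an attachment
point); it is guarded to ≤ 6 taxa and ≤ 1 reticulation. Hill climbing
uses rooted NNI plus reticulation addition, deletion and relocation,
steepest ascent, seeded random-joining restarts, and a cache keyed by
canonical topology so no topology is ever scored twice. The exact move
repertoire of earlier MDC software is not reproduced; this move set is a
documented substitute that connects the space at the scales used here.
MDC (minimize deep coalescences) is exposed as an alternative criterion:
the cost of a locus is the minimum over coalescent histories — routing
included — of Σ_b (v_b − 1), which reduces to the classic
cluster-counting extra-lineage score on species trees.

## Simulator

The generator draws gene-tree topologies by running the coalescent
bottom-up through the network: exponential waiting times at rate
k(k−1)/2 within each branch, uniformly chosen coalescing pairs,
independent Bernoulli(γ) routing at reticulations, and unbounded
coalescence above the root. Two regimes define multi-locus data sets:

* **common** — one parameter setting shared by all loci (branch lengths
  1.0 by default, with 1 and 2 as the reference settings; γ = 0.5);
* **ncm** — fresh per-locus draws, lengths ~ U(0, upper) with upper 2 or
  4 as the reference settings and γ ~ U(0, 1).

The per-locus parameter log (TSV via the CLI) makes NCM data sets
reproducible row by row. The simulator emulates the generative MSC/MSNC
process on topologies only: no sequences, no gene-tree estimation error,
no recombination or migration, and one allele per species. Tests that
pass against it therefore validate the coalescent machinery, not
robustness to gene-tree reconstruction noise in real data.

## Problem sizes and experiment design

Validation uses exhaustive cross-checks at small scale, where
independent oracles exist: brute-force history maps (≤ 4 taxa),
matrix-exponential transition probabilities (u ≤ 8), adaptive quadrature
of the integrated quantities, and full pmf normalization (Σ_g P(g|Ψ) = 1)
on all ≤ 4-taxon trees and a 1-reticulation network. The reproduction
experiments are deliberately scaled down versions of the published
design: simulator fidelity at 10⁵ loci on the 3-taxon tree with t = 1;
search convergence on a 4-taxon caterpillar (internal branches 1.0) with
10 common-mechanism replicates at 10/100/500 loci; and the
indistinguishability experiment on a constructed 4-taxon
one-reticulation pair displaying {((A,(B,C)),D), (A,((B,C),D))} with
opposite reticulation-edge directions — data simulated from one member
must be explained by a network with the truth's displayed-tree set,
since the two members cannot be told apart from topologies alone.

The MDC-vs-NCM contrast uses a constructed equal-frequency multiset of
three 4-taxon gene trees — (((A,B),C),D), (((A,D),C),B), ((A,C),(B,D)) —
found by exhaustive search over three-tree multisets: its MDC optimum is
the unique balanced tree ((A,C),(B,D)) while the NCM optimum is a
disjoint pair of caterpillar trees, so the two criteria provably differ
and the integrated-likelihood optimum need not be unique.

## Design choices and limitations

* Extended-Newick dialect: `#H`-tagged hybrid nodes, inheritance
  probability in the fourth colon field of the major parent edge
  (Rich-Newick style), matching the ecosystem this kind of analysis
  lives in. Serialization is canonical (children ordered by structural
  signature, hybrids numbered by first appearance), so isomorphic
  networks print identically and sets of topologies deduplicate by
  string.
* Branch lengths on input gene trees are read and discarded — the model
  is defined on topologies.
* Enumeration of histories is the definitional algorithm, guarded at 10
  gene-tree leaves and 3 reticulations by default; the
  dynamic-programming pmf over ancestral configurations is out of scope,
  so large networks are not desk-scale.
* `network_distance` is a hardwired-cluster symmetric-difference
  surrogate, not a reduction-based network metric; it is used only to
  decide "inferred equals truth" (distance 0), for which any sound
  metric agrees.
* The number of reticulations is an input (`max_reticulations`), never
  estimated: the unpenalized likelihood cannot select it.
* Model selection, multiple alleles per species, and branch-length
  estimation are out of scope.
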