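# netcoal

Integrated ("no common mechanism") coalescent likelihood for species
trees and phylogenetic networks, from multi-locus gene-tree topologies.

## What it does

Genome-scale data yield one gene tree per locus, and those trees
disagree — because of incomplete lineage sorting, modeled by the
multispecies coalescent (MSC), and because of hybridization, modeled by
the multispecies *network* coalescent (MSNC). Standard likelihood
inference of the species phylogeny Ψ must optimize or sample its branch
lengths Λ and inheritance probabilities Γ alongside the topology, which
is the expensive part of network inference.

`netcoal` instead works with the *integrated* likelihood

    f(Ψ | G) = ∏_{i=1}^{m} ∫∫ P(g_i | Ψ, Λ, Γ) p(Λ) p(Γ) dΓ dΛ
             = ∏_{i=1}^{m} P(g_i | Ψ),

in which every locus marginalizes the continuous parameters
independently — a no-common-mechanism (NCM) model. With an exponential
prior on each branch length (optionally truncated to (0, τ]) and a
conjugate Beta(2,2) prior on each inheritance probability, the integrals
are available in closed form per coalescent history, so P(g | Ψ) depends
on the *topology* of Ψ alone and search never touches a continuous
parameter. For users this buys: exhaustive topology search at small
taxon counts, cheap hill climbing at larger ones, and a principled
comparison against the minimize-deep-coalescences (MDC) parsimony
criterion, which the package also implements.

The package provides, as library modules and `netcoal` CLI subcommands:

* `phylo` — gene trees (Newick, via dendropy) and rooted networks
  (extended Newick with `#H` reticulations and γ annotations), with
  canonical serialization;
* `histories` — exhaustive coalescent-history enumeration with explicit
  reticulation routing and the w/d order-counting terms;
* `likelihood` — the fixed-parameter MSC/MSNC gene-tree pmf and its
  analytically integrated NCM counterpart (`score`);
* `mdc` — extra-lineage scoring (`mdc`);
* `search` — exhaustive and hill-climbing topology inference (`infer`,
  `enumerate`);
* `simulate` — a seedable MSC/MSNC gene-tree simulator with
  common-mechanism and per-locus ("ncm") regimes (`simulate`);
* `netprops` — displayed trees, indistinguishability checks and a
  cluster-based network dissimilarity (`display`, `netdist`);
* `model` — the `NCMTopologyModel` / `NCMTopologyResults` front end used
  below.

See `docs/methods.md` for the model, formulas, numerical policy and
limitations.

## Worked example

Simulate 200 loci from a 4-taxon one-reticulation network (all branch
lengths 1 coalescent unit, γ = 0.5) and re-infer the network from the
gene-tree topologies alone:

```python
from netcoal import (NCMTopologyModel, SimRegime, parse_network,
                     simulate_dataset)

truth = parse_network("((A,((B,C))#H1),(#H1,D));")
regime = SimRegime(mode="common", branch_length_value=1.0,
                   gamma_value=0.5, n_loci=200, seed=11)
trees, _log = simulate_dataset(truth.with_lengths(1.0).with_gammas(0.5),
                               regime)

model = NCMTopologyModel(trees)
result = model.fit(max_reticulations=1)   # exhaustive, 243 topologies
print(result.summary())
```

```
                  NCM topology inference
==========================================================
No. loci:                   200
No. taxa:                   4
Criterion:                  ncm
Search mode:                exhaustive
Max reticulations:          1
Prior tau:                  inf
Prior Beta shapes:          (2, 2)
Topologies evaluated:       243
----------------------------------------------------------
Best topology:              ((((B,C))#H1,A),(#H1,D));
Integrated log-likelihood:  -343.3842
MDC extra lineages:         76
Co-optimal topologies:      1
==========================================================
```

The best topology is exactly the generating network (its canonical
extended-Newick form). The log-likelihood is the sum over the 200 loci
of log P(g | Ψ); the MDC line is the same data scored under parsimony
(76 extra lineages: with ILS this heavy, many loci individually disagree
with the network's displayed trees). When inference errs on data like
these, it returns the other member of the truth's indistinguishability
class — a network displaying the same two trees
`(((B,C),A),D)` and `(((B,C),D),A)` with the reticulation edge
reversed — which `netcoal.same_displayed_set` detects:

```python
result.displayed()
# frozenset({'(((B,C),A),D);', '(((B,C),D),A);'})
```

Closed-form sanity check: on the 3-taxon species tree ((A,B),C) with the
untruncated prior, P = 2/3 for the concordant gene tree and 1/6 for each
discordant one.

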