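# dyhm — dynamic hierarchical block models for evolving networks

Biological interaction compendiums are static superpositions of
interactions that, in a living system, come and go as their protein
components are expressed and degraded.  Given a series of network
snapshots — time points, tissues, or any coupled states, e.g. subnetworks
of an interactome extracted from stage- and tissue-resolved expression
calls — `dyhm` infers which vertices form modules *in each snapshot* and
lets module membership drift smoothly across coupled snapshots, instead
of clustering every snapshot in isolation.  It is a library for
computational biologists and network scientists working on
protein-complex and module detection in spatiotemporally resolved
interaction data.

## The model

Vertices are assigned to the `G = 2^D` leaves of a fixed-depth binary
tree.  Every tree node `r` carries a Bernoulli edge probability `θ_r`
with a Beta(`a₀`, `b₀`) prior: an internal node governs edges between its
left and right descendant leaf sets, a leaf governs its within-leaf
edges, so each vertex pair is one Bernoulli observation at the lowest
common ancestor of its two leaves.  With edge/non-edge counts `e_r`,
`n_r`, the collapsed likelihood of an assignment is

    log L = Σ_r [ log B(e_r + a₀, n_r + b₀) − log B(a₀, b₀) ].

Across a snapshot series the tree and its `θ` are shared (group–group
interaction patterns are constant over space and time) while each
vertex's leaf membership `τ_i(t)` is per-snapshot.  Inference is
variational mean field; smoothness across coupled snapshots `(t, s)` is
enforced by a λ-weighted KL penalty, giving the coupled update

    τ_iu(t) ∝ exp( [field_iu(t) + λ Σ_s log τ_iu(s)] / (1 + λK) ),

which interpolates between independent snapshot fits (λ = 0) and a
single superposed fit (λ → ∞).  λ itself is chosen by a penalized
likelihood — the fit's collapsed likelihood minus `log C(G(G−1), m)`,
where `m` is the number of distinct directed leaf transitions observed —
so the pipeline has no tuning parameters beyond tree depth.  A collapsed
Metropolis–Hastings sampler provides the exact-posterior oracle on small
instances, and a shared-neighbor hypergeometric baseline the comparator.
See `docs/methods.md` for the full account.

## Worked example

`examples/dynamic_smoothing.py` generates a 15-snapshot series of
30 vertices in 5 groups (within-group edge probability 0.5, between
0.05) where each vertex switches groups with probability 0.05 per step,
then selects λ by penalized likelihood and scores the fits against the
planted truth:

```
series: 15 snapshots, 30 vertices, 5 drifting groups

lambda  loglik(MAP)   m   penalty   score     mean F1 vs truth
0.0        -2093.8   56      0.0    -2093.8   0.733
0.1        -1885.4   34     35.3    -1920.7   0.936
0.25       -1914.4   24     36.0    -1950.4   0.978
0.5        -1928.3   23     35.7    -1964.0   0.990
1.0        -1961.6   20     34.3    -1995.9   0.988
2.0        -2147.7   19     33.7    -2181.4   0.716
4.0        -2481.4    0      0.0    -2481.4   0.717
8.0        -2481.4    0      0.0    -2481.4   0.719

selected lambda = 0.1
selected fit: mean per-snapshot max-F1 0.936; 34 of 56 possible directed leaf transitions observed
```

Reading this: at λ = 0 each sparse snapshot is fit independently, its
own tree parameters overfit the realized edges, and all 56 possible
directed transitions are invoked (F1 0.73).  Any moderate smoothing
pools evidence across snapshots under one shared set of tree parameters;
the penalized likelihood — computed without any access to the truth —
lands in that plateau, and the selected fit tracks the drifting groups
at F1 0.94.  Too much smoothing (λ ≥ 2) freezes memberships and the
score drops accordingly.

Other examples, one capability each: `static_clustering.py` (single
network, tree enrichment), `mcmc_oracle.py` (variational fit vs sampler),
`baseline_comparison.py` (model vs hypergeometric ranking),
`expression_series.py` (activity-matrix series construction with degree
pruning and grid couplings).

## Acceptance benchmark

`scripts/acceptance.py` recomputes the headline number from scratch: it
generates 20 seeded replicates of the dynamic benchmark above, runs the
full pipeline (λ grid search with 7 restarts per fit) on each, and writes
the mean per-snapshot max-F1 of the selected fits (as a percentage) to a
JSON file:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

It takes roughly 15 minutes on one CPU; all randomness derives from
`--seed`.
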