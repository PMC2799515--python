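# Methods

## The model

`dyhm` clusters the vertices of an undirected network into the leaves of a
perfect binary tree of fixed depth `D` (`G = 2^D` leaves).  Every node `r`
of the tree — internal nodes and leaves alike — carries a Bernoulli edge
probability `θ_r` with a Beta(`a0`, `b0`) prior (flat, `a0 = b0 = 1`, by
default).  A pair of vertices assigned to leaves `u` and `v` contributes
one Bernoulli observation to exactly one node: the lowest common ancestor
of `u` and `v` when `u ≠ v`, the leaf itself when `u = v`.  Writing
`e_r`/`n_r` for the edge/non-edge counts at node `r`, the marginal
likelihood of a hard assignment, with every `θ_r` integrated out by
Beta–binomial conjugacy, is

    log L = Σ_r [ log B(e_r + a0, n_r + b0) − log B(a0, b0) ].

The hierarchy expresses heterogeneous between-group densities at every
scale, which flat block models miss; fixing the topology to a perfect
tree (rather than sampling dendrograms) is what makes deterministic
variational inference possible.  Leaves may hold many vertices, and
unoccupied leaves are legitimate: observing spare leaves is the working
diagnostic that the chosen depth is large enough.

For a *series* of snapshots — time points, tissues, or any states with a
declared undirected coupling graph — the tree and its parameters are
shared: group–group interaction patterns are constant over space and
time, and the series likelihood is the product of per-snapshot block
likelihoods, so the Beta posteriors pool expected counts over all
snapshots.  What evolves is membership: each vertex has one assignment
distribution per snapshot in which it is active.

## Variational inference

The surrogate factorizes completely: a categorical row `τ_i` over leaves
per active vertex and a Beta factor per tree node.  Coordinate ascent
alternates two exact updates:

* tree parameters: `a_r = a0 + e_r`, `b_r = b0 + n_r` with mean-field
  expected counts, whence `E[log θ_r] = ψ(a_r) − ψ(a_r + b_r)`;
* memberships: `τ_iu ∝ exp(field_iu)` where the field accumulates, over
  the leaf's ancestors and the leaf itself,
  `d·E[log θ] + (m − d)·E[log(1−θ)]` with `d` the expected edges from
  vertex `i` into the governed leaf set and `m` that set's expected
  occupancy excluding `i`.

Both are exact conditional maximizers, so the evidence lower bound is
non-decreasing sweep to sweep (asserted in the tests at relative
tolerance 1e-6).  The field is computed as two `G × G` matrix products
against per-leaf edge and occupancy vectors, using the LCA matrix of the
tree, so a sweep costs `O(N·(N + G)·G)` per snapshot.

For coupled snapshots, smoothness is enforced by penalizing the KL
divergence between a vertex's membership at coupled snapshots with weight
`λ ≥ 0`.  Stationarity of the penalized objective gives the coupled
update

    τ_iu(t) ∝ exp( [field_iu(t) + λ Σ_{s∈N_i(t)} log τ_iu(s)] / (1 + λK) ),

with `K` the number of coupled snapshots where the vertex is also active.
`λ = 0` recovers independent static fits (the implementation literally
dispatches to the static engine, so the equivalence is bit-exact under
matched seeds); `λ → ∞` recovers the normalized geometric mean of the
neighbors, i.e. time-constant membership — the superposed fit.  Newly
appearing vertices receive no smoothing from snapshots where they are
absent.  Neighbor values are read asynchronously (most recent τ), one
global sweep passing snapshots in index order.

## Optimization: what the bound landscape forced

Three algorithmic choices deviate from the most naive scheme, each forced
by a measured failure mode; they are the package's own design, and all
acceptance checks exercise them.

**Hard spectral initialization.**  Near-uniform membership is an *exactly
stable* fixed point of the mean-field iteration: flat memberships give
every node the same expected density, which makes the assignment field
constant across leaves, which regenerates flat memberships.  Dirichlet(1)
rows start close enough to uniform that fits collapse.  Restarts
therefore initialize from hard partitions obtained by hierarchical
spectral bisection — recursive Fiedler splits mirroring the binary tree —
of the snapshot adjacency (static fit) or of the pooled summed adjacency
(coupled fit), perturbed 15% after the first restart for diversity.

**Leaf-split refinement.**  Two planted groups merged into one leaf are a
local optimum that no single-vertex move escapes.  After convergence,
each multiply-occupied leaf is tentatively bisected along the Fiedler
vector of its (pooled) induced subgraph into an unoccupied leaf and the
fit re-ascended; splits are kept only when the objective improves, so the
recorded trace stays monotone.  In the coupled fit, refinement polishes
only the two best restarts, candidate re-descents are capped at 40
sweeps, and each round tries the three largest leaves — the refinement is
a local polish, and evaluating every candidate to full convergence on
every restart would dominate the runtime without changing the winner.

**MAP-based model scores.**  On weak-contrast data the soft bound itself
can prefer the degenerate solution: the surrogate entropy refunds the
`n log G` assignment prior in full at uniform membership, and when the
per-snapshot likelihood gap between structure and uniformity is smaller
than that refund (≈42 vs ≈62 nats per snapshot at the default dynamic
benchmark), the bound ranks the uninformative state on top.  Restarts and
smoothness weights are therefore compared by the collapsed marginal
likelihood of the hard-projected (argmax) assignments — a quantity with
no entropy refund that is observed to track pair-recovery F1
monotonically.  The soft bound is still computed, exposed
(`VBState.elbo`, `DynamicState.elbo_sum`), and used for the monotonicity
guarantees; co-membership scores are always taken from the soft τ.

## Choosing the smoothness weight

`select_lambda` fits the series over a grid (default
{0, 0.1, 0.25, 0.5, 1, 2, 4, 8}) and maximizes a penalized likelihood:
the fit's collapsed MAP likelihood minus `log C(G(G−1), m)`, where `m`
counts the distinct directed leaf transitions (argmax labels, vertices
active on both sides of a coupling).  The penalty follows from placing a
Bernoulli probability on each possible directed transition and
integrating it out: every model with exactly `m` observed transitions
gets equal weight, so models invoking more distinct transitions pay more.
Ties break toward larger `λ`.  No ground truth enters the selection.

## The synthetic world

* **Static generator** — group count uniform on 5–10, group sizes uniform
  on 5–10, `(Pwithin, Pbetween)` uniform on configurable ranges with
  draws rejected unless `Pwithin > Pbetween`.  The preset
  `marginal` keeps nearly overlapping ranges (0.05–0.1 vs 0.05–0.08),
  giving intentionally marginal recovery; the preset
  `contrast` (0.5 vs 0.05) is the separable regime used for benchmarks.
* **Dynamic generator** — 30 vertices in 5 groups, balanced round-robin
  start; each snapshot draws fresh Bernoulli edges from the current
  labels, then every vertex switches with probability `Pswitch` to a
  group uniform among the other four.  Group sizes drift; all vertices
  stay active; couplings are consecutive pairs.  `T = 15` snapshots by
  default, matching the size of a 5-tissue × 3-stage expression grid,
  the kind of layout the package targets.

What a green benchmark establishes: on Bernoulli planted partitions with
the stated sizes and rates, the full pipeline (fit, selection, scoring)
recovers drifting groups at roughly 90% precision/recall.  What it does
not establish: robustness to degree heterogeneity, weighted or missing
edges, activity-driven vertex churn, or the fidelity of expression
presence calls — real interaction data have all of these.

## Numerical choices

* τ entries floored at 1e-12 before any logarithm.
* Convergence: relative objective change < 1e-6, at most 500 static
  sweeps / 200 global sweeps (non-convergence is flagged, not raised).
* Degenerate (unoccupied) leaves keep their prior Beta parameters.
* Enrichment log2-ratios are clipped at ±10; zero-pair nodes report NaN.
* MCMC: single-vertex reassignment proposals uniform over all leaves
  (self-proposals keep the chain aperiodic on flat posteriors); a
  "sweep" is one proposal; burn-in defaults to 20% of sweeps, thinning
  to 10; incremental count updates are verifiable against recomputation
  (`debug_check_every`).
* Ordered-pair KL (both directions of each coupling) is the monitored
  dynamic objective.  The closed-form coupled update minimizes only its
  forward-KL part, so each proposal is kept only if it does not increase
  the vertex's exact objective contribution; with that guard every global
  sweep is non-increasing exactly, and both λ limits are untouched (the
  guard never rejects at λ = 0, and at λ → ∞ the geometric mean is also
  the symmetric minimizer).

## Known limitations

* On a small tree (`G = 8`, `M = G(G−1) = 56`) the transition penalty is
  bounded by `log C(56, 28) ≈ 37` nats and is non-monotone above
  `m = M/2`, so the penalized likelihood tends to select the smallest
  positive grid λ: the likelihood gain of a less-constrained fit outruns
  the penalty.  The selected fit still clearly beats independent
  snapshots, but sits a few F1 points below the best grid λ on the
  dynamic benchmark (≈0.88 vs ≈0.92 mean max-F1).  With many groups
  (`M` in the thousands, `m ≪ M`) the penalty behaves as intended.

* Group–group parameters are constant across snapshots by construction;
  regime changes in interaction density are absorbed into membership
  drift instead.
* The entropy-refund degeneracy means soft-bound comparisons across
  models of very different sharpness are unreliable on weak-contrast
  data; all model selection here goes through the MAP projection.
* The spectral initialization pools couplings-connected snapshots
  indiscriminately; series whose structure changes wholesale midway
  would deserve windowed anchors.
* MCMC is static-only and serves as a small-instance oracle, not a
  production sampler.
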