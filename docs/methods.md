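# Methods

## Model

We consider a multiplex network of k layers, each an edge-weighted, possibly
directed graph over the same p nodes, given as dense p×p adjacency matrices
A₁ … A_k with a(l,m) the weight of the edge *from* node l *to* node m.
Node identity across layers is positional; labels are metadata.

Standard eigenvector centrality defines a node's importance as proportional
to the weighted sum of the importance of its adjacent nodes: A x = λ x,
solved by the principal eigenvector. For an irreducible nonnegative A the
Perron–Frobenius theorem guarantees a unique dominant eigenvalue with a
strictly positive eigenvector. The package computes right centrality as
written; left centrality is the same procedure on transposed layers
(`transpose=True`).

The multilayer generalization separates *adjacency* from *adjacent-node
importance*. A k×k dependency matrix Ã with unit row sums assigns each layer
i a mixture c(i, Ã) = Σ_j ã_ij x_j of the layer centrality vectors, and the
joint solution is defined by

    A_i c(i, Ã) = λ_i x_i,   ‖x_i‖₂ = 1,   i = 1 … k.

Row i's self-weight classifies layer i:

- **case A** (ã_ii = 1): independent eigenvalue problem (row sums force all
  other entries to 0);
- **case B** (ã_ii = 0): x_i is a pure linear function of other layers;
- **case C** (fractional): a mixed pseudo-eigenvalue problem.

Negative dependency weights are allowed as long as rows sum to 1. They model
inverse dependencies, can produce negative centrality entries, and may slow
convergence; validation flags them and the solvers warn.

## Solvers

`solve` dispatches on structure:

1. **independent** — Ã = I: per-layer power iteration.
2. **direct-acyclic** — all layers case A/B and the off-diagonal dependency
   digraph (edge i→j when ã_ij ≠ 0, i ≠ j) is acyclic: case-A layers are
   solved by power iteration, then case-B layers in topological order as
   x_i = A_i c(i, Ã)/λ_i with λ_i = ‖A_i c(i, Ã)‖₂. Self-loops are excluded
   from the cycle test; a case-C self-weight independently forces iteration.
3. **interleaved** — anything else: per sweep and layer,
   y_i = A_i c(i, Ã), λ_i = ‖y_i‖₂, x_i = y_i/λ_i, with the relative
   sequential delta δ_i = |λ_i^{(t−1)} − λ_i^{(t)}|/λ_i^{(t)} tested against
   the tolerance — by default the mean over layers; optionally
   (`per_layer_convergence`) every layer individually, which guards against
   terminating while a few layers are still far from their fixed point.

### Numerical choices

- **Initialization**: deterministic uniform vector (every entry 1/√p) by
  default; optional seeded random start. Determinism aids testing, and on
  the worked examples both starts reach the same fixed point.
- **Update schedule**: by default each sweep computes every mixture c(i, Ã)
  from the previous sweep's vectors (Jacobi-style, layer-order invariant).
  An in-sweep (Gauss–Seidel) mode reuses already-updated vectors; both reach
  the same fixed point on all worked examples but in-sweep needs fewer
  sweeps.
- **Sign convention**: after normalization each vector is flipped so its
  entry sum is nonnegative. With nonnegative inputs this yields the positive
  Perron vector; with negative dependency weights individual entries may
  still be negative.
- **Degenerate inputs**: an update that collapses below 1e-12 in norm (zero
  matrix, nullspace start) raises a degenerate-layer error; a λ below 1e-12
  makes the relative delta +∞ rather than dividing by ~0. Non-convergence at
  `max_iter` (default 10 000; default tol 1e-6) returns `converged=False`
  with a warning.
- **Convergence resolution**: the stopping rule tests λ changes, and on
  symmetric layers λ converges quadratically in the eigenvector error, so a
  delta tolerance of `tol` resolves the *vectors* only to roughly √tol.
  Tests that assert 1e-6 element agreement therefore run at tol 1e-12–1e-14.
  `SolveResult.residuals` reports ‖A_i c(i, Ã) − λ_i x_i‖₂ per layer as a
  direct quality check.
- **Uniqueness**: for nonnegative inputs the worked examples and
  cross-solver checks all reach a unique fixed point; for negative weights
  no uniqueness argument is known, and the solver simply reports what the
  iteration converged to.

## Inter-layer-edge comparison method

The conventional alternative couples layers with edges instead of mixtures:
every nonzero off-diagonal ã_ij adds directed edges of weight ω·ã_ij from
each node in layer i to the same node in layer j (the dependency diagonal
has no edge counterpart and is ignored; ω defaults to 1). The merged
kp×kp matrix in block form is

    C(ω) = blockdiag(A₁ … A_k) + ω (Ã_offdiag ⊗ I)

(`build_supercentrality`, block (i,j) = ω·ã_ij·I). `solve_interlayer_edge`
computes the principal eigenvector of the merged network in the convention
that importance flows along each directed edge into its target — i.e. power
iteration on blockdiag(A₁…A_k) + ω(Ã_offdiagᵀ ⊗ I) — then splits it into k
blocks of p and rescales each block to unit length. This orientation is the
package's deliberate choice: it matches igraph-style directed eigenvector
centrality (verified against an independent dense eigendecomposition and
against R igraph's `eigen_centrality` on the merged graph), it is the only
orientation under which a layer that nothing depends on keeps its
independent centrality, and it agrees with the dependency semantics (layer i
drawing importance from layer j). With the opposite orientation every
layer that nothing points into decays to a zero block of the exact
eigenvector, making per-layer normalization ill-defined in the limit.

Blocks of the exact joint eigenvector can still be zero when coupling is
absent and one layer's spectral radius strictly dominates; the solver raises
a degenerate-block error if a block's magnitude falls below 1e-12.

## Synthetic data

`sample_islands` draws one layer as an *islands* graph: `n_islands`
Erdős–Rényi blocks of `island_size` nodes with within-block edge probability
`p_in`, plus `n_inter` uniformly placed, non-duplicating bridge edges per
island pair (defaults 5 / 20 / 0.2 / 1 — the community-structured regime the
simulation study states). `random_dependency` draws each row of Ã i.i.d.
uniform(0,1) and normalizes it to sum 1, which generically makes every layer
case C. These generators emulate modular connectivity with sparse
cross-module links and dense positive inter-layer dependence; they do **not**
produce directed layers, weighted edges, negative dependencies or
disconnected layers, so green simulation tests say nothing about those
regimes (the worked-example tests cover negative weights and cycles).

`run_simulation` compares the interleaved solver (per-layer convergence)
against the inter-layer-edge method over three schemes — (1) 20 nodes per
layer (5 islands of 4), layer count varied; (2) 5 layers, island size varied
(20–110 nodes per layer); (3) as (1) with independent layers, the comparison
arm solving each layer separately — recording sweeps to convergence, the
wall-clock runtime ratio (hardware-dependent; reported, never asserted) and
the Euclidean norm of the stacked centrality difference. The scaled
difference divides the raw norm by √k, the norm of either stacked set of
unit-length layer vectors, so it reads as the *fraction* of the centrality
norm on which the methods disagree. "20 nodes per layer" is read as total
p = 20, consistent with scheme 2's range (p = 5 × island size); the
alternative reading (island size 20, p = 100) remains available via
`nodes_per_layer_total`.

At the tiny scheme-1 scale, size-4 islands at p_in = 0.2 yield
near-degenerate spectra; the two arms' convergence tests can stop on
different sweeps around a spectral plateau, so independent-layer runs agree
only to a few percent per replicate (mean well under 5%). At 100 nodes per
layer the per-replicate agreement is better than 2%.

## Known limitations

- Dense matrices throughout; no sparse storage (deliberate — the method is
  defined and benchmarked dense).
- No convergence proof for the interleaved iteration; for negative
  dependency weights the limit's dependence on initialization is unknown.
- No accelerated/stochastic power-iteration variants and no conditioning
  checks beyond the degenerate-zero guards.
- The inter-layer-edge method inherits the usual supracentrality caveats:
  results depend on the coupling strength ω, and per-layer normalized blocks
  are only defined when no block of the joint eigenvector vanishes.
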