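# Methods

This note records the model implemented by `gpdag`, the design choices made
where the design was genuinely open, the numerical conventions, and what the
synthetic-data experiments do and do not demonstrate.

## Model and assumptions

The package computes a *composite* likelihood for a DNA alignment, per site
marginalized over the rooted bifurcating topologies encoded by a subsplit DAG
and over ancestral states, then multiplied across sites:

    L(θ) = ∏_m Σ_{τ ∈ D} P(Y^m | τ, θ) P(τ).

This is *not* the Bayesian marginal likelihood (which would sum over
topologies a product across sites); the site-wise marginalization is what
makes the dynamic program possible. Branch lengths are parameterized as one
scalar per DAG edge — a deliberate simplification relative to per-tree branch
lengths or branch-length distributions; marginalizing a distribution over
branch lengths would require an integral inside the DAG recursion and is out
of scope.

Substitution follows Jukes–Cantor, normalized so that one branch-length unit
is one expected substitution per site. The engine itself is written against
arbitrary row-stochastic 4×4 transition matrices with explicit transposes in
the rootward-to-leafward direction, so non-symmetric (non-reversible) models
can be substituted without touching traversal code; only
`substitution.py` is JC-specific. Sites are independent given the tree;
identical alignment columns are compressed to weighted patterns (exact under
site independence).

The prior over topologies factorizes over DAG edges. Two initializers exist:

- **uniform** (default): conditionals `n(s) / n((t,Z))` from exact topology
  counts (arbitrary-precision integers), giving every topology in the DAG
  prior `1/n_total`;
- **flat**: equal probability per sibling edge, which is simpler but does not
  correspond to a standard prior on topologies.

Conditionals are stored per subsplit-clade and never merged across the two
clades of a parent: `P(s|t)` summed over *all* children of `t` is 2, not 1,
because each clade is resolved independently.

## Conventions forced by boundary cases

- **Left/right clades.** Clades are compared as big-integer bitmasks (taxon 0
  = lowest bit); the smaller clade of a subsplit is "left". For degenerate
  subsplits (leaf subsplits `({x}, ∅)` and the DAG root `ρ = (X, ∅)`) the
  non-empty clade is stored first; `ρ`'s edges to rootsplits leave from its
  non-empty clade and its empty clade has no edges.
- **Taxon order.** Taken from the explicit taxon list when provided,
  otherwise sorted by label string. This fixes every "lexicographic"
  comparison and makes DAG serialization byte-stable.
- **`r` at the root boundary.** The rootward-marginal vectors are defined in
  the interior of the DAG by the two-term parent sum; at a rootsplit `t` the
  incoming quantity is pinned to `π · P(t)` (root distribution times the
  prior mass of `t`). This makes the per-edge marginal at a
  rootsplit-to-child edge agree exactly with the site marginal restricted to
  trees through `t`, which the enumeration tests verify.
- **Root edges.** Branch lengths on `ρ`-outgoing edges are carried but never
  enter any likelihood; editing them invalidates nothing and the optimizer
  skips them.
- **Missing data.** IUPAC ambiguity codes become multi-hot leaf indicators;
  `-`, `N`, `?`, `.` are all-ones. A fully missing column therefore has site
  marginal exactly 1.

## Numerics

- **Underflow protection.** Every stored partial likelihood vector carries a
  per-pattern log-scaler; scalers add through elementwise and matrix products
  and sums over siblings are shifted to the largest sibling scaler before
  accumulation. With scaling off, the same code paths run with scalers pinned
  to zero (tested equal to 1e-8 on small instances); scaling is required
  beyond roughly 50 taxa and is on by default.
- **All public likelihood values are log-space**, matching how the per-edge
  objective is optimized.
- **Transition matrices are cached per edge** and recomputed only when that
  edge's branch length changes, since the scalar optimizer evaluates the same
  edge repeatedly.
- **Optimizer defaults** (`OptimizerConfig`): search bounds
  `[1e-6, 3.0]` expected substitutions per site, Brent absolute tolerance
  `1e-6`, convergence when the total composite log likelihood changes by less
  than `1e-4` between sweeps, at most 50 sweeps, initial branch length 0.1
  everywhere (a moderate value away from both the zero boundary and the flat
  stationary regime). All configurable. The `gradient` method finds a sign
  change of the analytic derivative and solves it by bisection-safeguarded
  root finding; it agrees with Brent to optimizer tolerance in tests.
- **Schedule details.** Depth-first from the rootsplits, left clade before
  right, children in clade order — all deterministic, so fixed inputs give
  byte-identical fits. Each edge update can only improve its own per-edge
  objective (worse candidates are rejected); the *total* composite likelihood
  is not guaranteed monotone, because improving one edge can worsen another
  (the loopy-belief-propagation caveat), and no such guarantee is asserted.
  After a branch edit, all strict ancestors of the edge's child node are
  marked dirty; dirty vectors are recomputed on read without re-optimizing,
  so cleanup cannot recurse into optimization. Rootward-side (`r`) vectors
  are refreshed unconditionally at node visit rather than tracked by a
  dirtiness mechanism of their own.
- **Stopping rule.** "Run until convergence" is made concrete as the
  composite log-likelihood delta rule above; non-convergence returns
  best-so-far with a flag rather than raising.

## Synthetic data

`simulate_alignment` draws the root state from the stationary distribution
and evolves it down the tree with exact JC transition matrices —
i.i.d. sites, no rate heterogeneity, no indels, no model misspecification.
`generate_tree_set` produces a true topology plus distinct random rooted-NNI
perturbations, standing in for bootstrap or MCMC tree samples. Passing tests
on these inputs demonstrates algorithmic correctness (the DP equals its
definition; the optimizer maximizes its objective; estimates are consistent
under the generating model). It does not demonstrate robustness to real-data
features such as among-site rate variation, alignment error, or
model-misspecified substitution processes.

## Recovery experiment design

The branch-length recovery check fits a 10-taxon single-tree DAG on a
50,000-site simulated alignment with true branch lengths spread evenly over
[0.02, 0.5]. Two statistical facts shape the assertions:

1. Under a reversible model with stationary root distribution, the two
   branches incident to the root are not separately identifiable — the
   likelihood depends only on their sum (`πᵀ (P(a)p₁ ∘ P(b)p₂) =
   ¼ p₁ᵀ P(a+b) p₂` under JC). The root-adjacent pair is therefore assessed
   by its sum.
2. The maximum-likelihood estimator's relative standard error scales like
   `c/√(θM)` with `c ≈ 1` for pendant branches and 2–3× larger for internal
   ones. The smallest true values are placed on pendant edges so that the 10%
   relative-error criterion sits at ≥ 3.5 standard errors for every edge —
   i.e. the experiment is powered to detect method error rather than sampling
   noise. In runs, the fitted values attain a higher single-tree likelihood
   than the truth, confirming the optimizer reaches the ML optimum and the
   residual error is sampling variation.

## Problem sizes

The randomized equivalence suites use 4–6 taxa, 2–8 input trees (DAGs capped
at 200 encoded topologies so brute-force enumeration stays exact), and 1–50
alignment columns; the single-tree reduction is checked up to 50 taxa and
numerical stability up to 100; recovery uses 10 taxa × 50,000 sites. These
sizes make every oracle exact while keeping the full suite under a minute.

## Known limitations

- Jukes–Cantor only out of the box (no GTR/HKY, no Γ rate heterogeneity).
- One scalar branch length per DAG edge; no branch-length distributions.
- The DAG structure is an input: no NNI search over the DAG itself.
- Sequential per-edge optimization carries no global-optimality guarantee
  for the composite objective.
- Rooted topologies only; unrooted inputs must be rooted explicitly
  (`--root-at`).
- Topology enumeration (oracles, `gpdag enumerate`) is capped (default
  10,000) and intended for validation, not production-scale DAGs.
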