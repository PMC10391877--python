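# gpdag — generalized phylogenetic pruning on a subsplit DAG

`gpdag` implements a *generalized pruning* algorithm for Bayesian
phylogenetics: a dynamic program over a **subsplit DAG** that marginalizes the
phylogenetic likelihood over both ancestral states *and* tree topologies, and
uses the result to fit one branch length per DAG edge — in seconds, where an
MCMC treatment of the same quantities takes hours.

It is aimed at phylogenetics researchers who have a collection of plausible
rooted topologies (bootstrap replicates, a short MCMC sample) and want fast,
accurate point estimates of branch lengths on the *union* structure of those
trees, for example to initialize variational Bayesian phylogenetic inference.

## The model

A rooted bifurcating topology on a taxon set `X` decomposes into *subsplits*:
unordered pairs `{V, Z}` of disjoint clades. The **subsplit DAG** `D` collects
the subsplits of a set of topologies as nodes (plus a universal-ancestor root
`ρ` and one leaf subsplit per taxon) and connects a *subsplit-clade* `(t, Z)`
to every subsplit `s` with `U(s) = Z`. Choosing one outgoing edge for every
clade of every reachable subsplit reads out a topology, so the DAG encodes a
(typically much larger) superset of the input trees.

Attaching normalized conditionals `P(s | (t, Z))` to the edges yields a prior
over the encoded topologies, `P(τ) = ∏_{t→s ∈ τ} P(s|t)`; by default the
conditionals are derived from exact topology counts `n(·)` so that every
topology in the DAG has prior `1/n_total`. Sequence evolution is Jukes–Cantor
with one branch length `θ(t→s)` per DAG edge.

The engine computes, per alignment column `Y^m`, the topology-marginal
likelihood and the **per-edge marginal likelihood**

    ℓ^m(θ)      = Σ_{τ ∈ D} P(Y^m | τ, θ) P(τ)
    ℓ^m(t→s; θ) = Σ_{τ ∋ t→s} P(Y^m | τ, θ) P(τ | t→s)

with two passes over the DAG — a rootward pass filling `p`-vectors
(marginalized over sub-topologies below a node) and a leafward pass filling
`r`-vectors (marginalized over partially-specified topologies above it) — so
that `ℓ^m(t→s; θ) = r(t)ᵀ P(θ) p(s) / P(t)` is constant-time per edge. On a
single-tree DAG everything reduces exactly to classic two-pass Felsenstein
pruning. Branch lengths are then fitted by maximizing each edge's composite
objective `Σ_m log ℓ^m(t→s; θ)` in turn (Brent or gradient-based), in
depth-first sweeps with dirty-node cache maintenance.

## Worked example

Three trees on four taxa (the smallest DAG with real topology sharing):

```sh
$ printf '((0,1),(2,3));\n(0,((1,2),3));\n(0,(1,(2,3)));\n' > example.nwk
$ gpdag build-dag example.nwk
input trees (unique): 3
DAG nodes: 12  edges: 17
topology count: 3
```

The DAG has two rootsplits, `{0 | 123}` (in two of the three trees) and
`{01 | 23}`, and encodes exactly the three input topologies. Simulating 2000
sites on the third tree (all true branch lengths 0.15) and fitting:

```python
import numpy as np
from gpdag import GPEngine, OptimizerConfig, build_dag, run_schedule
from gpdag.io import read_newick_trees
from gpdag.oracle import branch_map_from_dag
from gpdag.simulate import simulate_patterns

topologies, taxa, _ = read_newick_trees("example.nwk")
dag = build_dag(topologies, taxa)
patterns = simulate_patterns(
    topologies[2], branch_map_from_dag(dag, np.full(dag.n_edges, 0.15)),
    2000, seed=1,
)
engine = GPEngine(dag, patterns)   # uniform-over-topologies prior
theta, trace = run_schedule(engine, OptimizerConfig())
print(f"converged after {trace.n_sweeps} sweeps: "
      f"log-likelihood {trace.log_likelihoods[-1]:.3f}")
```

prints

```
converged after 6 sweeps: log-likelihood -8227.658
```

The fitted `theta` holds one branch length per DAG edge — including edges
belonging only to topologies the data were *not* simulated under, each
estimated against the topologies in the DAG that contain it. The prior masses
are available as `engine.marginals.node_probs` (here 2/3 and 1/3 for the two
rootsplits), and per-edge fits can be exported with
`gpdag.io.write_branch_lengths_csv`.

The same pipeline is scriptable from the shell: `gpdag simulate`, `gpdag
fit`, `gpdag loglik`, and `gpdag enumerate` (see `gpdag --help`).

## Layout

- `src/gpdag/taxa.py`, `dag.py` — clades, subsplits, topologies, the DAG
  (construction, containment, exact counting, enumeration, traversals, JSON).
- `src/gpdag/substitution.py` — Jukes–Cantor transition matrices and
  derivatives.
- `src/gpdag/prior.py` — edge conditionals, topology priors, subsplit/edge
  marginals.
- `src/gpdag/engine.py` — the two-pass generalized pruning engine.
- `src/gpdag/optimize.py` — per-edge branch length optimization schedule.
- `src/gpdag/oracle.py` — independent brute-force reference implementations
  used by the tests.
- `src/gpdag/simulate.py`, `io.py`, `cli.py` — synthetic data, file formats,
  command line.

See `docs/methods.md` for the modeling assumptions, numerical choices, and
known limitations.
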