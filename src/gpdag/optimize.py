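"""Per-edge branch length optimization on the subsplit DAG.

Each DAG edge carries one branch length, optimized against its per-edge
composite likelihood (the pattern-weighted product over sites of the data
likelihood averaged over topologies containing the edge).  Because each
per-edge objective is maximized in turn while the others are held fixed, the
total composite likelihood is not guaranteed to increase monotonically --
improving one edge can worsen another, as in loopy belief propagation -- but
each edge's own objective never decreases within its update.

The sweep is a depth-first traversal from the rootsplits: at each node the
rootward PLVs are refreshed from the node's parents, the traversal descends
left clade then right clade, each child edge is optimized on return from its
subtree, and the node's leafward PLVs are re-accumulated with the fresh
branch lengths.  Branch length edits flag stale ancestors "dirty"; stale
vectors are recomputed on read without re-optimizing, so cleanup cannot loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .engine import GPEngine
from .taxa import LEFT, RIGHT

__all__ = [
    "OptimizerConfig",
    "OptimizerTrace",
    "optimize_edge_branch",
    "invalidate_and_clean",
    "run_schedule",
]


@dataclass
class OptimizerConfig:
    """Tunable settings for the optimization schedule.

    Branch lengths are searched in [min_branch, max_branch] (expected
    substitutions per site); ``brent_tol`` is the absolute tolerance of the
    scalar search, ``convergence_tol`` the stopping threshold on the change
    in total composite log likelihood between sweeps.
    """

    min_branch: float = 1e-6
    max_branch: float = 3.0
    brent_tol: float = 1e-6
    convergence_tol: float = 1e-4
    max_sweeps: int = 50
    method: str = "brent"  # or "gradient"
    init_branch: float = 0.1
    seed: int | None = None

    def __post_init__(self):
        if not 0 < self.min_branch < self.max_branch:
            raise ValueError("need 0 < min_branch < max_branch")
        if self.brent_tol <= 0 or self.convergence_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.method not in ("brent", "gradient"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass
class OptimizerTrace:
    """Per-sweep record of the schedule's progress."""

    log_likelihoods: list[float] = field(default_factory=list)
    max_edge_deltas: list[float] = field(default_factory=list)
    cleanup_counts: list[int] = field(default_factory=list)
    converged: bool = False

    @property
    def n_sweeps(self) -> int:
        return len(self.log_likelihoods)


def optimize_edge_branch(
    engine: GPEngine, edge_id: int, config: OptimizerConfig
) -> float:
    """Maximize one edge's per-edge composite log likelihood over its branch
    length, holding all PLVs fixed; returns the new branch length.

    Never returns a value whose objective is below the incoming one.  The
    "brent" method is a bounded scalar search; "gradient" locates a sign
    change of the analytic derivative and solves for its root.
    """
    i, _side, _j = engine.dag.edges[edge_id]
    if i == engine.dag.root_node:
        return float(engine.theta[edge_id])  # meaningless parameter, leave as is
    current = float(engine.theta[edge_id])
    f_current = engine.edge_objective(edge_id, current)
    if not np.isfinite(f_current):
        raise FloatingPointError(
            "non-finite per-edge objective: partial likelihood vectors corrupt"
        )
    lo, hi = config.min_branch, config.max_branch

    if config.method == "gradient":
        candidate = _gradient_argmax(engine, edge_id, lo, hi, config.brent_tol)
    else:
        res = minimize_scalar(
            lambda th: -engine.edge_objective(edge_id, th),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": config.brent_tol},
        )
        candidate = float(res.x)
    if engine.edge_objective(edge_id, candidate) >= f_current:
        return candidate
    return current


def _gradient_argmax(
    engine: GPEngine, edge_id: int, lo: float, hi: float, tol: float
) -> float:
    """Root of the per-edge objective derivative, or the better boundary."""

    def grad(th: float) -> float:
        return engine.edge_objective_gradient(edge_id, th)

    g_lo, g_hi = grad(lo), grad(hi)
    if g_lo <= 0:
        return lo
    if g_hi >= 0:
        return hi
    return float(brentq(grad, lo, hi, xtol=tol))


def invalidate_and_clean(engine: GPEngine, edge_id: int, value: float) -> int:
    """Set a branch length, flag stale ancestors, and refresh them at once.

    Returns the number of nodes recomputed.  Provided for callers that want
    eager cleanup; the engine itself cleans lazily on read.
    """
    engine.set_branch_length(edge_id, value)
    n = 0
    for t in engine.dag.rootsplits():
        n += engine.ensure_clean(t)
    return n


def run_schedule(
    engine: GPEngine, config: OptimizerConfig | None = None
) -> tuple[np.ndarray, OptimizerTrace]:
    """Run depth-first branch length optimization sweeps to convergence.

    Returns the fitted per-edge branch lengths and a trace.  On reaching
    ``max_sweeps`` without meeting ``convergence_tol`` the best-so-far values
    are returned with ``trace.converged`` False; no exception is raised.
    """
    if config is None:
        config = OptimizerConfig()
    dag = engine.dag
    engine.full_passes()
    trace = OptimizerTrace()
    previous = engine.composite_log_likelihood()
    cleanups = 0

    def visit(node: int, visited: set[int]) -> None:
        nonlocal cleanups
        if node in visited or dag.nodes[node].is_leaf:
            return
        visited.add(node)
        cleanups += engine.ensure_clean(node)
        engine.refresh_rbreve(node)
        for side in (LEFT, RIGHT):  # left first, consistently
            engine.set_r(node, side)
            for k in dag.children[node][side]:
                child = dag.edges[k][2]
                visit(child, visited)
                cleanups += engine.ensure_clean(child)
                new_theta = optimize_edge_branch(engine, k, config)
                engine.set_branch_length(k, new_theta)
            engine._accumulate_pbreve(node, side)
        engine.p[node] = engine.pbreve[node, LEFT] * engine.pbreve[node, RIGHT]
        engine.p_scale[node] = (
            engine.pbreve_scale[node, LEFT] + engine.pbreve_scale[node, RIGHT]
        )
        engine._rescale(engine.p[node], engine.p_scale[node])
        engine.dirty[node] = False

    for _sweep in range(config.max_sweeps):
        theta_before = engine.theta.copy()
        cleanups = 0
        visited: set[int] = set()
        for t in dag.rootsplits():
            engine.ensure_clean(t)
            visit(t, visited)
        total = engine.composite_log_likelihood()
        trace.log_likelihoods.append(total)
        trace.max_edge_deltas.append(float(np.abs(engine.theta - theta_before).max()))
        trace.cleanup_counts.append(cleanups)
        if abs(total - previous) < config.convergence_tol:
            trace.converged = True
            break
        previous = total
        engine.leafward_pass()
    return engine.theta.copy(), trace
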