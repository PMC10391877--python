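"""The generalized pruning engine: topology-marginal likelihood on a subsplit DAG.

This is the core dynamic program.  It maintains, per DAG node ``s`` and per
alignment pattern, the partial likelihood vectors

* ``p(s)``: likelihood of the data below ``s``, marginalized over all DAG
  sub-topologies rooted at ``s`` (weighted by their conditional prior);
* ``pbreve(s, side)``: the per-clade accumulation whose elementwise product
  over the two sides gives ``p(s)``;
* ``rbreve(s)`` and ``r(s, side)``: the rootward analogues, marginalized over
  all partially-specified topologies above ``s`` weighted by their
  unconditional prior mass.

A rootward pass (children before parents) fills the ``p`` family; a leafward
pass fills the ``r`` family.  Given both, every per-edge marginal likelihood
is a constant-time vector product, which is what makes per-edge branch length
optimization cheap.

Underflow protection: each stored vector carries a per-pattern log-scaler, so
the true PLV is ``stored * exp(scaler)``.  Scalers add through elementwise
and matrix products and are folded into all log-space outputs; with scaling
disabled the same code paths run with all scalers pinned at zero.

Branch-length edits mark the ancestors of the edited edge "dirty" (their
``p``/``pbreve`` stale); any read of a dirty node triggers a downward
recomputation, never an optimization, so cleaning cannot loop.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

from .alignment import SitePatterns
from .dag import SubsplitDAG
from .prior import (
    SubsplitConditionals,
    SubsplitMarginals,
    subsplit_and_edge_marginals,
    uniform_prior_conditionals,
)
from .substitution import (
    jc_transition_derivative,
    jc_transition_matrix,
    stationary_distribution,
)
from .taxa import LEFT, RIGHT

__all__ = ["GPEngine"]


def _logsumexp(a: np.ndarray, axis: int = 0) -> np.ndarray:
    m = np.max(a, axis=axis)
    safe_m = np.where(np.isfinite(m), m, 0.0)
    out = safe_m + np.log(np.sum(np.exp(a - np.expand_dims(safe_m, axis)), axis=axis))
    return np.where(np.isfinite(m), out, m)


class GPEngine:
    """Generalized pruning over a subsplit DAG for one alignment.

    Parameters
    ----------
    dag : SubsplitDAG
    patterns : SitePatterns
        Compressed alignment columns for the DAG's taxa.
    conditionals : SubsplitConditionals, optional
        Prior edge conditionals; defaults to the uniform-over-topologies prior.
    branch_lengths : array or float, optional
        Initial branch length per DAG edge (default 0.1 everywhere).  Values
        on rho-outgoing edges are carried but never enter any likelihood.
    scaling : bool
        Enable per-vector log-scalers (needed beyond ~50 taxa).
    """

    def __init__(
        self,
        dag: SubsplitDAG,
        patterns: SitePatterns,
        conditionals: SubsplitConditionals | None = None,
        branch_lengths: np.ndarray | float = 0.1,
        scaling: bool = True,
        transition_fn: Callable[[float], np.ndarray] = jc_transition_matrix,
        transition_derivative_fn: Callable[[float], np.ndarray] = jc_transition_derivative,
        root_distribution: np.ndarray | None = None,
    ):
        if patterns.taxa != dag.taxa:
            raise ValueError("patterns and DAG are on different taxon sets")
        self.dag = dag
        self.patterns = patterns
        if conditionals is None:
            conditionals = uniform_prior_conditionals(dag)
        conditionals.validate()
        self.conditionals = conditionals
        self.marginals: SubsplitMarginals = subsplit_and_edge_marginals(
            dag, conditionals
        )
        self.scaling = bool(scaling)
        self._transition = transition_fn
        self._transition_derivative = transition_derivative_fn
        self.pi = (
            stationary_distribution()
            if root_distribution is None
            else np.asarray(root_distribution, dtype=float)
        )

        theta = np.broadcast_to(
            np.asarray(branch_lengths, dtype=float), (dag.n_edges,)
        ).copy()
        if np.any(theta < 0) or not np.all(np.isfinite(theta)):
            raise ValueError("branch lengths must be finite and >= 0")
        self.theta = theta
        self._pmat_cache: dict[int, tuple[float, np.ndarray]] = {}

        n, P = dag.n_nodes, patterns.n_patterns
        self.p = np.zeros((n, P, 4))
        self.p_scale = np.zeros((n, P))
        self.pbreve = np.zeros((n, 2, P, 4))
        self.pbreve_scale = np.zeros((n, 2, P))
        self.rbreve = np.zeros((n, P, 4))
        self.rbreve_scale = np.zeros((n, P))
        self.r = np.zeros((n, 2, P, 4))
        self.r_scale = np.zeros((n, 2, P))
        self.dirty = np.ones(n, dtype=bool)

        self._leaf_plvs = patterns.leaf_likelihoods()
        self._rootsplit_set = set(dag.rootsplits())

    # -- transition matrices ----------------------------------------------

    def transition_matrix(self, edge_id: int) -> np.ndarray:
        theta = self.theta[edge_id]
        cached = self._pmat_cache.get(edge_id)
        if cached is not None and cached[0] == theta:
            return cached[1]
        pmat = self._transition(theta)
        self._pmat_cache[edge_id] = (theta, pmat)
        return pmat

    # -- branch length edits and dirty-node maintenance --------------------

    def set_branch_length(self, edge_id: int, value: float) -> None:
        """Set one branch length and flag every affected ancestor dirty."""
        value = float(value)
        if not np.isfinite(value) or value < 0:
            raise ValueError("branch length must be finite and >= 0")
        if self.theta[edge_id] == value:
            return
        self.theta[edge_id] = value
        # Strict ancestors of the child node; empty for rho-outgoing edges,
        # whose branch lengths never enter the likelihood.
        for node in self._strict_ancestors(self.dag.edges[edge_id][2]):
            self.dirty[node] = True

    def _strict_ancestors(self, node: int) -> Iterable[int]:
        seen: set[int] = set()
        stack = [node]
        while stack:
            v = stack.pop()
            for k in self.dag.parents[v]:
                u = self.dag.edges[k][0]
                if u != self.dag.root_node and u not in seen:
                    seen.add(u)
                    stack.append(u)
        return seen

    def ensure_clean(self, node: int) -> int:
        """Recompute stale p-side PLVs below ``node``; returns #nodes refreshed.

        Cleaning performs plain downward updates and never optimizes branch
        lengths, so it cannot recurse into optimization.
        """
        if not self.dirty[node]:
            return 0
        # Dirty nodes reachable leafward from `node` must be refreshed first.
        need = set()
        stack = [node]
        while stack:
            v = stack.pop()
            if v in need or not self.dirty[v]:
                continue
            need.add(v)
            for side in (LEFT, RIGHT):
                for k in self.dag.children[v][side]:
                    stack.append(self.dag.edges[k][2])
        for v in self.dag.rootward_order():
            if v in need:
                self._compute_p(v)
                self.dirty[v] = False
        return len(need)

    # -- rootward pass ------------------------------------------------------

    def _rescale(self, vec: np.ndarray, scale: np.ndarray) -> None:
        if not self.scaling:
            return
        m = vec.max(axis=-1)
        nz = m > 0
        vec[nz] /= m[nz, None]
        scale[nz] += np.log(m[nz])

    def _accumulate_pbreve(self, node: int, side: int) -> None:
        ks = self.dag.children[node][side]
        kids = [self.dag.edges[k][2] for k in ks]
        if self.scaling:
            ref = np.max(self.p_scale[kids], axis=0)
        else:
            ref = 0.0
        acc = np.zeros_like(self.pbreve[node, side])
        for k, child in zip(ks, kids):
            pmat = self.transition_matrix(k)
            term = self.p[child] @ pmat.T  # P(theta) p(child), batched over patterns
            w = self.conditionals.values[k]
            if self.scaling:
                term = term * np.exp(self.p_scale[child] - ref)[:, None]
            acc += w * term
        self.pbreve[node, side] = acc
        self.pbreve_scale[node, side] = ref

    def _compute_p(self, node: int) -> None:
        s = self.dag.nodes[node]
        if node == self.dag.root_node:
            return
        if s.is_leaf:
            taxon = s.left.bit_length() - 1
            self.p[node] = self._leaf_plvs[taxon]
            self.p_scale[node] = 0.0
            return
        for side in (LEFT, RIGHT):
            self._accumulate_pbreve(node, side)
        self.p[node] = self.pbreve[node, LEFT] * self.pbreve[node, RIGHT]
        self.p_scale[node] = (
            self.pbreve_scale[node, LEFT] + self.pbreve_scale[node, RIGHT]
        )
        self._rescale(self.p[node], self.p_scale[node])

    def rootward_pass(self) -> None:
        """Populate p and pbreve at every node, children before parents."""
        for node in self.dag.rootward_order():
            self._compute_p(node)
        self.dirty[:] = False

    # -- leafward pass ------------------------------------------------------

    def refresh_rbreve(self, node: int) -> None:
        """Recompute rbreve(node) from the r-PLVs of its parents.

        At a rootsplit t this is the boundary convention: rbreve(t) is the
        root distribution weighted by the prior mass P(t), which makes the
        per-edge marginal at rootsplit-to-child edges consistent with the
        site marginal restricted to trees through t.
        """
        if node in self._rootsplit_set:
            prob = self.marginals.node_probs[node]
            if self.scaling:
                self.rbreve[node] = self.pi
                self.rbreve_scale[node] = np.log(prob) if prob > 0 else -np.inf
            else:
                self.rbreve[node] = self.pi * prob
                self.rbreve_scale[node] = 0.0
            return
        ks = self.dag.parents[node]
        pars = [(k,) + self.dag.edges[k][:2] for k in ks]
        if self.scaling:
            ref = np.max([self.r_scale[i, side] for (_, i, side) in pars], axis=0)
        else:
            ref = 0.0
        acc = np.zeros_like(self.rbreve[node])
        for k, i, side in pars:
            pmat = self.transition_matrix(k)
            # P(theta)^T r, batched: (r @ P)_j = sum_i r_i P_ij
            term = self.r[i, side] @ pmat
            if self.scaling:
                term = term * np.exp(self.r_scale[i, side] - ref)[:, None]
            acc += self.conditionals.values[k] * term
        self.rbreve[node] = acc
        self.rbreve_scale[node] = ref

    def set_r(self, node: int, side: int) -> None:
        """r(node, side) = pbreve(node, other side) o rbreve(node)."""
        other = RIGHT if side == LEFT else LEFT
        self.r[node, side] = self.pbreve[node, other] * self.rbreve[node]
        self.r_scale[node, side] = (
            self.pbreve_scale[node, other] + self.rbreve_scale[node]
        )
        self._rescale(self.r[node, side], self.r_scale[node, side])

    def leafward_pass(self) -> None:
        """Populate rbreve and r at every non-leaf node, parents first.

        Requires the rootward pass; stale p-PLVs are refreshed on the way.
        """
        for node in self.dag.leafward_order():
            if node == self.dag.root_node or self.dag.nodes[node].is_leaf:
                continue
            self.ensure_clean(node)
            self.refresh_rbreve(node)
            self.set_r(node, LEFT)
            self.set_r(node, RIGHT)

    def full_passes(self) -> None:
        self.rootward_pass()
        self.leafward_pass()

    # -- likelihood values --------------------------------------------------

    def site_log_marginals(self) -> np.ndarray:
        """Per-pattern log of the topology-marginal likelihood
        sum_t P(t) pi^T p(t) over rootsplits t."""
        terms = []
        for t in self.dag.rootsplits():
            self.ensure_clean(t)
            prob = self.marginals.node_probs[t]
            with np.errstate(divide="ignore"):
                lg = np.log(self.p[t] @ self.pi) + self.p_scale[t]
                terms.append(lg + (np.log(prob) if prob > 0 else -np.inf))
        return _logsumexp(np.stack(terms), axis=0)

    def site_log_marginal(self, m: int) -> float:
        return float(self.site_log_marginals()[m])

    def composite_log_likelihood(self) -> float:
        """Pattern-weighted sum of per-site log marginal likelihoods."""
        return float(self.patterns.weights @ self.site_log_marginals())

    def per_edge_log_marginals(self, edge_id: int) -> np.ndarray:
        """Per-pattern log of the per-edge marginal likelihood: the data
        likelihood averaged over DAG topologies containing the edge, under
        the prior renormalized to those topologies."""
        i, side, j = self.dag.edges[edge_id]
        self.ensure_clean(j)
        if i == self.dag.root_node:
            # Trees through rootsplit j: the P(t) weights cancel exactly.
            with np.errstate(divide="ignore"):
                return np.log(self.p[j] @ self.pi) + self.p_scale[j]
        prob = self.marginals.node_probs[i]
        if prob <= 0:
            raise ValueError("edge is unreachable under the prior (P(t) = 0)")
        pmat = self.transition_matrix(edge_id)
        dot = np.einsum("pi,ij,pj->p", self.r[i, side], pmat, self.p[j])
        with np.errstate(divide="ignore"):
            return (
                np.log(dot)
                + self.r_scale[i, side]
                + self.p_scale[j]
                - np.log(prob)
            )

    def per_edge_log_marginal(self, edge_id: int, m: int) -> float:
        return float(self.per_edge_log_marginals(edge_id)[m])

    def per_edge_composite_log_likelihood(self, edge_id: int) -> float:
        return float(self.patterns.weights @ self.per_edge_log_marginals(edge_id))

    def edge_objective(self, edge_id: int, theta: float) -> float:
        """Per-edge composite log likelihood as a function of this edge's
        branch length, holding every PLV fixed.  Constant-time per pattern."""
        i, side, j = self.dag.edges[edge_id]
        if i == self.dag.root_node:
            return self.per_edge_composite_log_likelihood(edge_id)
        pmat = self._transition(theta)
        dot = np.einsum("pi,ij,pj->p", self.r[i, side], pmat, self.p[j])
        prob = self.marginals.node_probs[i]
        with np.errstate(divide="ignore"):
            logs = (
                np.log(dot)
                + self.r_scale[i, side]
                + self.p_scale[j]
                - np.log(prob)
            )
        return float(self.patterns.weights @ logs)

    # -- gradients ----------------------------------------------------------

    def edge_objective_gradient(self, edge_id: int, theta: float) -> float:
        """d/dtheta of the per-edge composite log likelihood at ``theta``,
        holding every PLV fixed (the P(t) normalizer drops out)."""
        i, side, j = self.dag.edges[edge_id]
        if i == self.dag.root_node:
            return 0.0
        pmat = self._transition(theta)
        dmat = self._transition_derivative(theta)
        r, p = self.r[i, side], self.p[j]
        dot_p = np.einsum("pi,ij,pj->p", r, pmat, p)
        dot_d = np.einsum("pi,ij,pj->p", r, dmat, p)
        return float(self.patterns.weights @ (dot_d / dot_p))

    def branch_log_gradient(self, edge_id: int) -> tuple[float, float]:
        """d/dtheta of (a) the per-edge composite log likelihood and (b) the
        full composite log likelihood, for this edge's branch length."""
        i, side, j = self.dag.edges[edge_id]
        if i == self.dag.root_node:
            return 0.0, 0.0
        self.ensure_clean(j)
        pmat = self.transition_matrix(edge_id)
        dmat = self._transition_derivative(self.theta[edge_id])
        r, p = self.r[i, side], self.p[j]
        dot_p = np.einsum("pi,ij,pj->p", r, pmat, p)
        dot_d = np.einsum("pi,ij,pj->p", r, dmat, p)
        w = self.patterns.weights
        per_edge = float(w @ (dot_d / dot_p))
        slm = self.site_log_marginals()
        scale = self.r_scale[i, side] + self.p_scale[j]
        ratio = dot_d * np.exp(scale - slm)
        full = float(
            self.marginals.edge_probs[edge_id]
            / self.marginals.node_probs[i]
            * (w @ ratio)
        )
        return per_edge, full
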