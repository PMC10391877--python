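"""Brute-force ground-truth engines: classic single-tree pruning and
enumeration-based versions of every topology-marginal quantity.

These are deliberately independent of the DAG engine's PLV code paths (a
shared bug would silently pass equivalence tests) and make no attempt at
efficiency: the enumeration oracles are O(n_topologies * N * M).
"""

from __future__ import annotations

from itertools import product as _iterproduct
from typing import Callable, Mapping

import numpy as np

from .alignment import SitePatterns
from .dag import SubsplitDAG
from .prior import SubsplitConditionals, topology_prior
from .substitution import jc_transition_matrix, stationary_distribution
from .taxa import LEFT, RIGHT, Subsplit, SubsplitClade, Topology, popcount

__all__ = [
    "BranchMap",
    "branch_map_from_dag",
    "felsenstein_log_likelihood",
    "felsenstein_edge_decomposition",
    "exhaustive_state_sum_log_likelihood",
    "enumeration_site_log_marginal",
    "enumeration_per_edge_log_marginal",
    "enumeration_all_marginals",
    "enumeration_node_and_edge_probs",
]

# A branch length lookup keyed by topology subsplit edges.
BranchMap = Callable[[SubsplitClade, Subsplit], float]


def branch_map_from_dag(dag: SubsplitDAG, theta: np.ndarray) -> BranchMap:
    """Adapt a per-DAG-edge branch length vector into a topology edge lookup."""

    def lookup(parent_sc: SubsplitClade, child: Subsplit) -> float:
        return float(theta[dag.edge_id(parent_sc.subsplit, parent_sc.side, child)])

    return lookup


def _leaf_vectors(patterns: SitePatterns) -> np.ndarray:
    return patterns.leaf_likelihoods()  # (n_taxa, P, 4)


def _lower_partials(
    tau: Topology, branches: BranchMap, patterns: SitePatterns
) -> dict[int, np.ndarray]:
    """Classic upward pruning: lower partial vectors keyed by clade mask."""
    leaves = _leaf_vectors(patterns)
    partials: dict[int, np.ndarray] = {}

    def rec(clade: int) -> np.ndarray:
        if clade in partials:
            return partials[clade]
        if popcount(clade) == 1:
            vec = leaves[clade.bit_length() - 1]
        else:
            s = tau.subsplit_below(clade)
            vec = np.ones_like(leaves[0])
            for side in (LEFT, RIGHT):
                child_clade = s.clade(side)
                child = tau.subsplit_below(child_clade)
                th = branches(SubsplitClade(s, side), child)
                vec = vec * (rec(child_clade) @ jc_transition_matrix(th).T)
        partials[clade] = vec
        return vec

    rec(tau.taxa.full_mask)
    return partials


def felsenstein_log_likelihood(
    tau: Topology, branches: BranchMap, patterns: SitePatterns
) -> np.ndarray:
    """Per-pattern log likelihood of the alignment on a single rooted tree."""
    partials = _lower_partials(tau, branches, patterns)
    pi = stationary_distribution()
    return np.log(partials[tau.taxa.full_mask] @ pi)


def felsenstein_edge_decomposition(
    tau: Topology, branches: BranchMap, patterns: SitePatterns
) -> dict[tuple[int, int], np.ndarray]:
    """Per-pattern likelihood evaluated as r^T P(theta) p at every tree edge.

    Keys are (parent clade mask, child clade mask).  Every entry must equal
    the root evaluation -- the defining invariance of the two-pass scheme.
    The upper partials are computed by the downward recursion from the root
    distribution.
    """
    partials = _lower_partials(tau, branches, patterns)
    pi = stationary_distribution()
    uppers: dict[int, np.ndarray] = {tau.taxa.full_mask: np.broadcast_to(
        pi, partials[tau.taxa.full_mask].shape
    ).copy()}
    # r at child v of parent u: (P(theta_sibling) p(sibling)) o (P(theta_up)^T r(u));
    # at the root, r is the root distribution itself.
    order = sorted(
        (s for s in tau.subsplits), key=lambda s: -popcount(s.union)
    )
    out: dict[tuple[int, int], np.ndarray] = {}
    for s in order:
        parent_clade = s.union
        r_parent = uppers[parent_clade]
        sub = {LEFT: s.left, RIGHT: s.right}
        vecs = {}
        for side in (LEFT, RIGHT):
            child_clade = sub[side]
            child = tau.subsplit_below(child_clade)
            th = branches(SubsplitClade(s, side), child)
            vecs[side] = (partials[child_clade] @ jc_transition_matrix(th).T, th)
        for side in (LEFT, RIGHT):
            other = RIGHT if side == LEFT else LEFT
            child_clade = sub[side]
            th = vecs[side][1]
            r_child = vecs[other][0] * r_parent
            uppers[child_clade] = r_child @ jc_transition_matrix(th)
            # r^T P p across this edge
            out[(parent_clade, child_clade)] = np.einsum(
                "pi,ij,pj->p",
                r_child,
                jc_transition_matrix(th),
                partials[child_clade],
            )
    return out


def exhaustive_state_sum_log_likelihood(
    tau: Topology, branches: BranchMap, patterns: SitePatterns
) -> np.ndarray:
    """Likelihood by explicit summation over all ancestral-state assignments.

    Exponential in the number of internal nodes; only for tiny trees.
    """
    pi = stationary_distribution()
    leaves = _leaf_vectors(patterns)
    internal = sorted(tau.subsplits, key=lambda s: (s.left, s.right))
    P = patterns.n_patterns
    total = np.zeros(P)
    pmat = {}

    def trans(parent_sc: SubsplitClade, child: Subsplit) -> np.ndarray:
        key = (parent_sc, child)
        if key not in pmat:
            pmat[key] = jc_transition_matrix(branches(parent_sc, child))
        return pmat[key]

    for states in _iterproduct(range(4), repeat=len(internal)):
        assign = {s.union: st for s, st in zip(internal, states)}
        like = np.full(P, pi[assign[tau.taxa.full_mask]])
        for s in internal:
            st_parent = assign[s.union]
            for side in (LEFT, RIGHT):
                clade = s.clade(side)
                child = tau.subsplit_below(clade)
                mat = trans(SubsplitClade(s, side), child)
                if popcount(clade) == 1:
                    taxon = clade.bit_length() - 1
                    like = like * (mat[st_parent] @ leaves[taxon].T)
                else:
                    like = like * mat[st_parent, assign[clade]]
        total += like
    return np.log(total)


def enumeration_site_log_marginal(
    dag: SubsplitDAG,
    theta: np.ndarray,
    conditionals: SubsplitConditionals,
    patterns: SitePatterns,
    cap: int = 10_000,
) -> np.ndarray:
    """Per-pattern log of sum_tau P(Y | tau, theta) P(tau) over the DAG."""
    branches = branch_map_from_dag(dag, theta)
    total = np.zeros(patterns.n_patterns)
    for tau in dag.enumerate_topologies(cap=cap):
        pr = topology_prior(dag, conditionals, tau)
        total += pr * np.exp(felsenstein_log_likelihood(tau, branches, patterns))
    return np.log(total)


def enumeration_per_edge_log_marginal(
    dag: SubsplitDAG,
    theta: np.ndarray,
    conditionals: SubsplitConditionals,
    edge_id: int,
    patterns: SitePatterns,
    cap: int = 10_000,
) -> np.ndarray:
    """Per-pattern log of the likelihood averaged over the topologies
    containing a DAG edge, weighting by the prior renormalized to them."""
    branches = branch_map_from_dag(dag, theta)
    i, side, j = dag.edges[edge_id]
    parent_sc = SubsplitClade(dag.nodes[i], side)
    child = dag.nodes[j]
    total = np.zeros(patterns.n_patterns)
    mass = 0.0
    for tau in dag.enumerate_topologies(cap=cap):
        if (parent_sc, child) not in tau.edges():
            continue
        pr = topology_prior(dag, conditionals, tau)
        mass += pr
        total += pr * np.exp(felsenstein_log_likelihood(tau, branches, patterns))
    if mass == 0.0:
        raise ValueError("no topology in the DAG contains this edge")
    return np.log(total / mass)


def enumeration_all_marginals(
    dag: SubsplitDAG,
    theta: np.ndarray,
    conditionals: SubsplitConditionals,
    patterns: SitePatterns,
    cap: int = 10_000,
) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Site marginal and every per-edge marginal from one enumeration.

    Evaluates the single-tree likelihood once per enumerated topology and
    reuses the table for all edges; returns (per-pattern site log marginal,
    {edge_id: per-pattern per-edge log marginal}) for edges with positive
    prior mass.
    """
    branches = branch_map_from_dag(dag, theta)
    taus = dag.enumerate_topologies(cap=cap)
    priors = np.array([topology_prior(dag, conditionals, t) for t in taus])
    likes = np.stack(
        [np.exp(felsenstein_log_likelihood(t, branches, patterns)) for t in taus]
    )  # (n_trees, n_patterns)
    site = np.log(priors @ likes)
    membership = np.zeros((len(taus), dag.n_edges), dtype=bool)
    for ti, tau in enumerate(taus):
        membership[ti, dag.topology_edge_ids(tau)] = True
    per_edge: dict[int, np.ndarray] = {}
    for k in range(dag.n_edges):
        sel = membership[:, k]
        mass = priors[sel].sum()
        if mass > 0:
            per_edge[k] = np.log(priors[sel] @ likes[sel] / mass)
    return site, per_edge


def enumeration_node_and_edge_probs(
    dag: SubsplitDAG,
    conditionals: SubsplitConditionals,
    cap: int = 10_000,
) -> tuple[Mapping[int, float], Mapping[int, float]]:
    """P(t) and P(t -> s) by brute-force summation over enumerated trees."""
    node_probs = {i: 0.0 for i in range(dag.n_nodes)}
    edge_probs = {k: 0.0 for k in range(dag.n_edges)}
    for tau in dag.enumerate_topologies(cap=cap):
        pr = topology_prior(dag, conditionals, tau)
        for s in tau.subsplits:
            node_probs[dag.node_index[s]] += pr
        for k in dag.topology_edge_ids(tau):
            edge_probs[k] += pr
    node_probs[dag.root_node] = 1.0
    for i in dag.leaf_nodes:
        node_probs[i] = 1.0
    return node_probs, edge_probs
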