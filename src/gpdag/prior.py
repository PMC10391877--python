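"""Subsplit-Bayes-net prior on the topologies encoded by a subsplit DAG.

The prior attaches a conditional probability P(s | (t, Z)) to every DAG edge,
normalized within each subsplit-clade; the probability of a topology is the
product of its edge conditionals (including the rho -> rootsplit edge).  Two
initializers are provided: the default induces the uniform distribution over
the topologies in the DAG via exact topology counts, and a "flat" alternative
sets every conditional to 1 / (number of sibling edges).
"""

from __future__ import annotations

import csv
import io as _io
import warnings
from dataclasses import dataclass

import numpy as np

from .dag import SubsplitDAG
from .taxa import LEFT, RIGHT, Topology

__all__ = [
    "SubsplitConditionals",
    "SubsplitMarginals",
    "uniform_prior_conditionals",
    "flat_prior_conditionals",
    "topology_prior",
    "subsplit_and_edge_marginals",
]


@dataclass
class SubsplitConditionals:
    """Per-edge conditionals P(s | (t, Z)), indexed by DAG edge id."""

    dag: SubsplitDAG
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.dag.n_edges,):
            raise ValueError("need one conditional per DAG edge")

    def validate(self, atol: float = 1e-12) -> None:
        if np.any(self.values < 0):
            raise ValueError("conditionals must be nonnegative")
        for i in range(self.dag.n_nodes):
            for side in (LEFT, RIGHT):
                ks = self.dag.children[i][side]
                if ks and abs(self.values[ks].sum() - 1.0) > atol:
                    raise ValueError(
                        "conditionals of a subsplit-clade must sum to 1"
                    )

    def to_csv(self) -> str:
        n = len(self.dag.taxa)
        buf = _io.StringIO()
        w = csv.writer(buf, lineterminator="\n")
        w.writerow(["parent", "side", "child", "probability"])
        for k, (i, side, j) in enumerate(self.dag.edges):
            w.writerow(
                [
                    self.dag.nodes[i].bitstring(n),
                    "left" if side == LEFT else "right",
                    self.dag.nodes[j].bitstring(n),
                    repr(float(self.values[k])),
                ]
            )
        return buf.getvalue()


@dataclass
class SubsplitMarginals:
    """Unconditional node probabilities P(t) and edge probabilities P(t -> s).

    P(t) is the probability that a topology drawn from the prior contains the
    subsplit t; the probability of containing either subsplit-clade of t is
    the same number, since a tree containing t contains both its clades.
    """

    dag: SubsplitDAG
    node_probs: np.ndarray
    edge_probs: np.ndarray

    def to_csv(self) -> str:
        n = len(self.dag.taxa)
        buf = _io.StringIO()
        w = csv.writer(buf, lineterminator="\n")
        w.writerow(["parent", "side", "child", "probability"])
        for k, (i, side, j) in enumerate(self.dag.edges):
            w.writerow(
                [
                    self.dag.nodes[i].bitstring(n),
                    "left" if side == LEFT else "right",
                    self.dag.nodes[j].bitstring(n),
                    repr(float(self.edge_probs[k])),
                ]
            )
        return buf.getvalue()


def uniform_prior_conditionals(dag: SubsplitDAG) -> SubsplitConditionals:
    """Conditionals inducing the uniform distribution over DAG topologies.

    With n(s) the number of sub-topologies below subsplit s and n((t, Z)) the
    sum over the clade's child edges, the edge conditional is
    n(s) / n((t, Z)); for rootsplit edges this equals n(left) n(right) /
    n_total.  Every topology in the DAG then has prior 1 / n_total.
    """
    node_counts, clade_counts, _total = dag.count_topologies()
    values = np.empty(dag.n_edges)
    for k, (i, side, j) in enumerate(dag.edges):
        values[k] = node_counts[j] / clade_counts[i][side]
    return SubsplitConditionals(dag, values)


def flat_prior_conditionals(dag: SubsplitDAG) -> SubsplitConditionals:
    """The simplest choice: equal probability to each edge of a subsplit-clade.

    Does not correspond to a standard prior on topologies; provided as an
    alternative initializer only.
    """
    values = np.empty(dag.n_edges)
    for i in range(dag.n_nodes):
        for side in (LEFT, RIGHT):
            ks = dag.children[i][side]
            for k in ks:
                values[k] = 1.0 / len(ks)
    return SubsplitConditionals(dag, values)


def topology_prior(
    dag: SubsplitDAG, conditionals: SubsplitConditionals, tau: Topology
) -> float:
    """Prior probability of a topology: the product of its edge conditionals.

    A topology not contained in the DAG has probability 0; a warning is
    issued rather than an exception.
    """
    try:
        edge_ids = dag.topology_edge_ids(tau)
    except KeyError:
        warnings.warn("topology is not contained in the DAG; prior is 0")
        return 0.0
    return float(np.prod(conditionals.values[edge_ids]))


def subsplit_and_edge_marginals(
    dag: SubsplitDAG, conditionals: SubsplitConditionals
) -> SubsplitMarginals:
    """P(t) and P(t -> s) for every node and edge, by one leafward sweep.

    P(rho) = 1; P(t -> s) = P(t) P(s | t); and P(s) accumulates the edge
    probabilities over s's parent edges.
    """
    node_probs = np.zeros(dag.n_nodes)
    edge_probs = np.zeros(dag.n_edges)
    node_probs[dag.root_node] = 1.0
    for i in dag.leafward_order():
        p = node_probs[i]
        for side in (LEFT, RIGHT):
            for k in dag.children[i][side]:
                contrib = p * conditionals.values[k]
                edge_probs[k] += contrib
                node_probs[dag.edges[k][2]] += contrib
    return SubsplitMarginals(dag, node_probs, edge_probs)
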