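"""The subsplit DAG: a compact encoding of a collection of rooted topologies.

Nodes are subsplits (plus the universal-ancestor root ``rho`` and one leaf
subsplit per taxon).  A directed edge runs from a subsplit-clade ``(t, Z)`` to
a subsplit ``s`` whenever ``U(s) = Z``, i.e. ``s`` resolves clade ``Z`` of
``t``.  A topology is contained in the DAG when all of its subsplit edges are
DAG edges; the DAG built from a set of trees contains every input tree, and
typically more trees arising from recombining compatible substructures.
"""

from __future__ import annotations

import json
from typing import Iterable, Sequence

from .taxa import (
    LEFT,
    RIGHT,
    Subsplit,
    SubsplitClade,
    TaxonSet,
    Topology,
    popcount,
)

__all__ = ["SubsplitDAG", "build_dag"]

DEFAULT_ENUMERATION_CAP = 10_000


class SubsplitDAG:
    """Subsplit DAG over a fixed taxon set.

    Nodes and edges are indexed densely; ``nodes[i]`` is the subsplit of node
    ``i`` and ``edges[e] = (parent_node, side, child_node)``.  Both lists are
    deterministically ordered so that serialization is byte-stable.
    """

    def __init__(self, taxa: TaxonSet, subsplits: Iterable[Subsplit]):
        self.taxa = taxa
        n = len(taxa)
        node_set = {s for s in subsplits}
        node_set.add(Subsplit.root(taxa))
        for i in range(n):
            node_set.add(Subsplit.leaf(i))
        for s in node_set:
            if s.union & ~taxa.full_mask:
                raise ValueError("subsplit refers to taxa outside the taxon set")
        # Deterministic node order: by clade-union size, then by clade masks.
        self.nodes: list[Subsplit] = sorted(
            node_set, key=lambda s: (popcount(s.union), s.left, s.right)
        )
        self.node_index = {s: i for i, s in enumerate(self.nodes)}
        self.root_node = self.node_index[Subsplit.root(taxa)]
        self.leaf_nodes = [self.node_index[Subsplit.leaf(i)] for i in range(n)]

        by_union: dict[int, list[int]] = {}
        for i, s in enumerate(self.nodes):
            by_union.setdefault(s.union, []).append(i)

        edges: list[tuple[int, int, int]] = []
        for i, t in enumerate(self.nodes):
            if t.is_leaf:
                continue
            for side in (LEFT, RIGHT):
                clade = t.clade(side)
                if clade == 0:
                    continue
                for j in by_union.get(clade, []):
                    if j != i:
                        edges.append((i, side, j))
        edges.sort()
        self.edges = edges
        self.edge_index = {e: k for k, e in enumerate(edges)}

        # Adjacency: children[node][side] and parents[node] as edge-id lists.
        self.children: list[tuple[list[int], list[int]]] = [
            ([], []) for _ in self.nodes
        ]
        self.parents: list[list[int]] = [[] for _ in self.nodes]
        for k, (i, side, j) in enumerate(edges):
            self.children[i][side].append(k)
            self.parents[j].append(k)

        self._validate()
        self._rootward_order: list[int] | None = None

    # -- structure ---------------------------------------------------------

    def _validate(self) -> None:
        for i, s in enumerate(self.nodes):
            if s.is_leaf or i == self.root_node:
                continue
            for side in (LEFT, RIGHT):
                if not self.children[i][side]:
                    raise ValueError(
                        f"subsplit {s.bitstring(len(self.taxa))} has no child edge "
                        f"on side {side}"
                    )
            if not self.parents[i]:
                raise ValueError(
                    f"subsplit {s.bitstring(len(self.taxa))} has no parent edge"
                )

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def rootsplits(self) -> list[int]:
        """Node ids of the rootsplits, i.e. children of rho."""
        return [self.edges[k][2] for k in self.children[self.root_node][LEFT]]

    def edge_id(self, parent: Subsplit, side: int, child: Subsplit) -> int:
        return self.edge_index[
            (self.node_index[parent], side, self.node_index[child])
        ]

    def edge_tuple(self, edge_id: int) -> tuple[SubsplitClade, Subsplit]:
        i, side, j = self.edges[edge_id]
        return SubsplitClade(self.nodes[i], side), self.nodes[j]

    def topology_edge_ids(self, tau: Topology) -> list[int]:
        """DAG edge ids of a contained topology's subsplit edges.

        Raises ``KeyError`` via lookup if the topology is not contained.
        """
        ids = []
        for (parent_sc, child) in tau.edges():
            ids.append(self.edge_id(parent_sc.subsplit, parent_sc.side, child))
        return ids

    def contains_topology(self, tau: Topology) -> bool:
        if tau.taxa != self.taxa:
            raise ValueError("topology is on a different taxon set")
        for (parent_sc, child) in tau.edges():
            i = self.node_index.get(parent_sc.subsplit)
            j = self.node_index.get(child)
            if i is None or j is None:
                return False
            if (i, parent_sc.side, j) not in self.edge_index:
                return False
        return True

    # -- counting and enumeration -----------------------------------------

    def count_topologies(self) -> tuple[list[int], list[list[int]], int]:
        """Exact topology counts below every node and subsplit-clade.

        Returns ``(node_counts, clade_counts, total)`` where
        ``node_counts[i]`` is the number of sub-topologies descending from
        node ``i`` (1 for leaves), ``clade_counts[i][side]`` sums the node
        counts over the child edges of that subsplit-clade, and ``total`` is
        the number of topologies encoded by the DAG.  Python integers keep
        the counts exact at any scale.
        """
        node_counts = [0] * self.n_nodes
        clade_counts: list[list[int]] = [[1, 1] for _ in self.nodes]
        for i in self.rootward_order():
            s = self.nodes[i]
            if s.is_leaf:
                node_counts[i] = 1
                continue
            for side in (LEFT, RIGHT):
                if s.clade(side) == 0:
                    clade_counts[i][side] = 1
                    continue
                clade_counts[i][side] = sum(
                    node_counts[self.edges[k][2]] for k in self.children[i][side]
                )
            node_counts[i] = clade_counts[i][LEFT] * clade_counts[i][RIGHT]
        total = node_counts[self.root_node]
        return node_counts, clade_counts, total

    def n_topologies(self) -> int:
        return self.count_topologies()[2]

    def enumerate_topologies(
        self, cap: int = DEFAULT_ENUMERATION_CAP
    ) -> list[Topology]:
        """Every distinct topology contained in the DAG, exactly once.

        Intended for oracles and small problems; refuses to expand more than
        ``cap`` topologies.
        """
        total = self.n_topologies()
        if total > cap:
            raise ValueError(
                f"DAG encodes {total} topologies, above the enumeration cap {cap}"
            )
        memo: dict[int, list[frozenset[Subsplit]]] = {}

        def below(i: int) -> list[frozenset[Subsplit]]:
            if i in memo:
                return memo[i]
            s = self.nodes[i]
            if s.is_leaf:
                memo[i] = [frozenset()]
                return memo[i]
            side_opts: list[list[frozenset[Subsplit]]] = []
            for side in (LEFT, RIGHT):
                opts: list[frozenset[Subsplit]] = []
                for k in self.children[i][side]:
                    child = self.edges[k][2]
                    opts.extend(below(child))
                side_opts.append(opts)
            out = [
                frozenset({s}) | l | r
                for l in side_opts[LEFT]
                for r in side_opts[RIGHT]
            ]
            memo[i] = out
            return out

        result = []
        for t in self.rootsplits():
            for ss in below(t):
                result.append(Topology(self.taxa, ss))
        return result

    # -- traversal ---------------------------------------------------------

    def rootward_order(self) -> list[int]:
        """Node order visiting every node after all of its DAG descendants
        (a postorder linearization); deterministic."""
        if self._rootward_order is not None:
            return self._rootward_order
        state = [0] * self.n_nodes  # 0 unvisited, 1 on stack, 2 done
        order: list[int] = []
        # Iterative DFS from rho for stack safety on large DAGs.
        stack: list[tuple[int, int]] = [(self.root_node, 0)]
        child_lists = [
            self.children[i][LEFT] + self.children[i][RIGHT]
            for i in range(self.n_nodes)
        ]
        while stack:
            node, ci = stack.pop()
            if ci == 0:
                if state[node] == 2:
                    continue
                if state[node] == 1:
                    raise ValueError("subsplit DAG contains a cycle")
                state[node] = 1
            kids = child_lists[node]
            if ci < len(kids):
                stack.append((node, ci + 1))
                stack.append((self.edges[kids[ci]][2], 0))
            else:
                state[node] = 2
                order.append(node)
        if len(order) != self.n_nodes:
            raise ValueError("subsplit DAG has nodes unreachable from the root")
        self._rootward_order = order
        return order

    def leafward_order(self) -> list[int]:
        return list(reversed(self.rootward_order()))

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        n = len(self.taxa)
        doc = {
            "taxa": list(self.taxa.labels),
            "nodes": [s.bitstring(n) for s in self.nodes],
            "edges": [
                [
                    self.nodes[i].bitstring(n),
                    "left" if side == LEFT else "right",
                    self.nodes[j].bitstring(n),
                ]
                for (i, side, j) in self.edges
            ],
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SubsplitDAG":
        doc = json.loads(text)
        taxa = TaxonSet(doc["taxa"])
        subsplits = [Subsplit.from_bitstring(s) for s in doc["nodes"]]
        dag = cls(taxa, subsplits)
        declared = {
            (
                dag.node_index[Subsplit.from_bitstring(p)],
                LEFT if side == "left" else RIGHT,
                dag.node_index[Subsplit.from_bitstring(c)],
            )
            for p, side, c in doc["edges"]
        }
        if declared != set(dag.edge_index):
            raise ValueError("DAG JSON edge set is inconsistent with its node set")
        return dag

    def __repr__(self) -> str:
        return (
            f"SubsplitDAG(n_taxa={len(self.taxa)}, nodes={self.n_nodes}, "
            f"edges={self.n_edges})"
        )


def build_dag(topologies: Sequence[Topology], taxa: TaxonSet | None = None) -> SubsplitDAG:
    """Build the subsplit DAG from a collection of rooted topologies.

    The node set is the union of the subsplits of all (deduplicated) input
    topologies plus rho and the leaf subsplits; edges connect every
    subsplit-clade to every node resolving it.
    """
    if not topologies:
        raise ValueError("cannot build a DAG from an empty topology list")
    if taxa is None:
        taxa = topologies[0].taxa
    unique = {t for t in topologies}
    subsplits: set[Subsplit] = set()
    for t in unique:
        if t.taxa != taxa:
            raise ValueError("all topologies must share the DAG's taxon set")
        subsplits |= t.subsplits
    return SubsplitDAG(taxa, subsplits)
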