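"""File formats: rooted Newick tree sets, FASTA alignments, CSV/JSON outputs.

Input trees must be rooted and bifurcating; branch lengths in the Newick are
ignored for DAG construction (optionally averaged per DAG edge to initialize
the branch length vector).  Unrooted inputs can be rooted explicitly on the
pendant edge of a named outgroup taxon.
"""

from __future__ import annotations

import csv
import io as _io
import warnings
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
from Bio import SeqIO

from .alignment import SitePatterns
from .dag import SubsplitDAG
from .taxa import Subsplit, TaxonSet, Topology, popcount

__all__ = [
    "read_newick_trees",
    "read_fasta_alignment",
    "topology_from_dendropy",
    "write_fasta",
    "write_branch_lengths_csv",
    "read_branch_lengths_csv",
    "average_branch_lengths",
]


def topology_from_dendropy(
    tree: dendropy.Tree, taxa: TaxonSet, line: int | None = None
) -> tuple[Topology, dict]:
    """Convert a dendropy tree to a Topology; also collect per-edge branch
    lengths keyed by (parent subsplit, side, child subsplit union)."""
    where = f" (tree {line})" if line is not None else ""
    subsplits: list[Subsplit] = []
    lengths: dict[tuple[Subsplit, int], float] = {}

    def rec(node) -> int:
        children = node.child_nodes()
        if not children:
            if node.taxon is None:
                raise ValueError(f"unlabeled leaf{where}")
            label = node.taxon.label
            try:
                return 1 << taxa.index(label)
            except KeyError:
                raise ValueError(f"unknown taxon {label!r}{where}")
        if len(children) != 2:
            kind = "unrooted (top-level trifurcation)" if node.parent_node is None else "multifurcating"
            raise ValueError(f"{kind} tree{where}: every node needs exactly 2 children")
        masks = [rec(c) for c in children]
        s = Subsplit.make(masks[0], masks[1])
        subsplits.append(s)
        for c, m in zip(children, masks):
            side = 0 if s.left == m else 1
            if c.edge.length is not None:
                lengths[(s, side)] = float(c.edge.length)
        return masks[0] | masks[1]

    root_mask = rec(tree.seed_node)
    if root_mask != taxa.full_mask:
        raise ValueError(f"tree{where} does not cover the full taxon set")
    return Topology(taxa, subsplits), lengths


def read_newick_trees(
    path: str | Path,
    taxa: TaxonSet | None = None,
    root_at: str | None = None,
) -> tuple[list[Topology], TaxonSet, list[dict]]:
    """Parse a file of rooted bifurcating Newick trees on one taxon set.

    Returns (unique topologies, taxon set, per-topology branch length maps).
    Duplicated topologies are reported via a warning and removed.  If
    ``taxa`` is not given, the taxon set is the sorted union of leaf labels.
    ``root_at`` roots each tree on the pendant edge of the named outgroup
    taxon (for inputs written unrooted).
    """
    trees = dendropy.TreeList.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    if len(trees) == 0:
        raise ValueError(f"no trees found in {path}")
    labels = sorted({t.label for t in trees.taxon_namespace})
    if taxa is None:
        taxa = TaxonSet(labels)
    if root_at is not None:
        if root_at not in list(taxa):
            raise ValueError(f"outgroup taxon {root_at!r} not in the taxon set")
        for tree in trees:
            leaf = next(
                nd for nd in tree.leaf_node_iter() if nd.taxon.label == root_at
            )
            tree.reroot_at_edge(leaf.edge, update_bipartitions=False)
    topologies: list[Topology] = []
    length_maps: list[dict] = []
    seen = set()
    n_dup = 0
    for line, tree in enumerate(trees, start=1):
        topo, lengths = topology_from_dendropy(tree, taxa, line=line)
        if topo.subsplits in seen:
            n_dup += 1
            continue
        seen.add(topo.subsplits)
        topologies.append(topo)
        length_maps.append(lengths)
    if n_dup:
        warnings.warn(f"removed {n_dup} duplicate topologies from {path}")
    return topologies, taxa, length_maps


def average_branch_lengths(
    dag: SubsplitDAG,
    length_maps: Sequence[dict],
    default: float = 0.1,
) -> np.ndarray:
    """Per-DAG-edge average of the branch lengths observed across input trees.

    Edges never observed with a length (including all rho-outgoing edges)
    get ``default``.
    """
    sums = np.zeros(dag.n_edges)
    counts = np.zeros(dag.n_edges)
    # Within a topology the child resolving a clade is unique, so each
    # (parent, side) length can be credited to the DAG edge actually present.
    for lengths in length_maps:
        by_union = {}
        for (s, side) in lengths:
            by_union[s.union] = s
        for (s, side), theta in lengths.items():
            clade = s.clade(side)
            if popcount(clade) == 1:
                child = Subsplit(clade, 0)
            else:
                child = by_union.get(clade)
                if child is None:
                    continue
            key = (dag.node_index[s], side, dag.node_index[child])
            k = dag.edge_index.get(key)
            if k is not None:
                sums[k] += theta
                counts[k] += 1
    out = np.full(dag.n_edges, float(default))
    has = counts > 0
    out[has] = sums[has] / counts[has]
    return out


def read_fasta_alignment(path: str | Path, taxa: TaxonSet) -> SitePatterns:
    """Read a FASTA DNA alignment (IUPAC codes allowed) for the DAG's taxa."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq)
    return SitePatterns.from_sequences(taxa, seqs)


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_branch_lengths_csv(dag: SubsplitDAG, theta: np.ndarray) -> str:
    n = len(dag.taxa)
    buf = _io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["parent", "side", "child", "branch_length"])
    for k, (i, side, j) in enumerate(dag.edges):
        w.writerow(
            [
                dag.nodes[i].bitstring(n),
                "left" if side == 0 else "right",
                dag.nodes[j].bitstring(n),
                repr(float(theta[k])),
            ]
        )
    return buf.getvalue()


def read_branch_lengths_csv(dag: SubsplitDAG, text: str) -> np.ndarray:
    theta = np.full(dag.n_edges, np.nan)
    reader = csv.DictReader(_io.StringIO(text))
    for row in reader:
        key = (
            dag.node_index[Subsplit.from_bitstring(row["parent"])],
            0 if row["side"] == "left" else 1,
            dag.node_index[Subsplit.from_bitstring(row["child"])],
        )
        theta[dag.edge_index[key]] = float(row["branch_length"])
    if np.isnan(theta).any():
        raise ValueError("branch length CSV does not cover every DAG edge")
    return theta
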