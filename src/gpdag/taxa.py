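"""Taxon sets, clades, subsplits, and rooted topologies.

Clades are represented as integer bit masks over the positions of a
:class:`TaxonSet`: taxon ``i`` corresponds to bit ``1 << i``.  The total order
on clades used throughout (for deciding which clade of a subsplit is "left")
is the big-integer order on these masks, so taxon 0 is the lowest bit.

A *subsplit* is an unordered pair of disjoint clades; it is the bipartition of
the taxa below an internal node of a rooted tree.  Two degenerate families are
allowed: leaf subsplits ``({x}, {})`` and the universal-ancestor subsplit
``rho = (X, {})`` that roots the subsplit DAG.
"""

from __future__ import annotations

from typing import Iterable, Iterator, NamedTuple

__all__ = [
    "TaxonSet",
    "Subsplit",
    "SubsplitClade",
    "Topology",
    "LEFT",
    "RIGHT",
    "popcount",
    "clade_bitstring",
    "clade_from_bitstring",
]

LEFT = 0
RIGHT = 1


def popcount(mask: int) -> int:
    return mask.bit_count()


def clade_bitstring(mask: int, n_taxa: int) -> str:
    """Render a clade mask as a bit string with taxon 0 first."""
    return "".join("1" if mask >> i & 1 else "0" for i in range(n_taxa))


def clade_from_bitstring(bits: str) -> int:
    mask = 0
    for i, b in enumerate(bits):
        if b == "1":
            mask |= 1 << i
        elif b != "0":
            raise ValueError(f"invalid clade bit string {bits!r}")
    return mask


class TaxonSet:
    """An ordered collection of distinct taxon labels.

    The label order is fixed for the life of any structure built on top of it
    and induces the clade order used for left/right subsplit normalization.
    """

    __slots__ = ("labels", "_index")

    def __init__(self, labels: Iterable[str]):
        labels = tuple(str(x) for x in labels)
        if len(labels) < 2:
            raise ValueError("a taxon set needs at least 2 taxa")
        if len(set(labels)) != len(labels):
            raise ValueError("taxon labels must be unique")
        self.labels = labels
        self._index = {lab: i for i, lab in enumerate(labels)}

    @classmethod
    def from_labels_sorted(cls, labels: Iterable[str]) -> "TaxonSet":
        return cls(sorted(set(str(x) for x in labels)))

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self) -> Iterator[str]:
        return iter(self.labels)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TaxonSet) and self.labels == other.labels

    def __hash__(self) -> int:
        return hash(self.labels)

    def __repr__(self) -> str:
        return f"TaxonSet({list(self.labels)!r})"

    def index(self, label: str) -> int:
        return self._index[label]

    def mask(self, labels: Iterable[str]) -> int:
        m = 0
        for lab in labels:
            m |= 1 << self._index[lab]
        return m

    @property
    def full_mask(self) -> int:
        return (1 << len(self.labels)) - 1

    def clade_labels(self, mask: int) -> tuple[str, ...]:
        return tuple(lab for i, lab in enumerate(self.labels) if mask >> i & 1)


class Subsplit(NamedTuple):
    """An unordered pair of disjoint clades, stored normalized.

    ``left`` is the smaller clade under the big-integer order, except that for
    degenerate subsplits (one empty clade) the non-empty clade is stored on
    the left, matching the conventional written forms ``({x}, {})`` and
    ``rho = (X, {})``.
    """

    left: int
    right: int

    @classmethod
    def make(cls, a: int, b: int) -> "Subsplit":
        if a & b:
            raise ValueError("subsplit clades must be disjoint")
        if a == 0 or b == 0:
            nonempty = a | b
            if nonempty == 0:
                raise ValueError("subsplit cannot have two empty clades")
            return cls(nonempty, 0)
        if a > b:
            a, b = b, a
        return cls(a, b)

    @classmethod
    def leaf(cls, taxon_index: int) -> "Subsplit":
        return cls(1 << taxon_index, 0)

    @classmethod
    def root(cls, taxa: TaxonSet) -> "Subsplit":
        """The universal-ancestor subsplit rho = (X, {})."""
        return cls(taxa.full_mask, 0)

    @property
    def union(self) -> int:
        """U(s): the set of taxa in the subsplit."""
        return self.left | self.right

    @property
    def is_leaf(self) -> bool:
        return self.right == 0 and popcount(self.left) == 1

    def is_root(self, taxa: TaxonSet) -> bool:
        return self.right == 0 and self.left == taxa.full_mask

    @property
    def is_degenerate(self) -> bool:
        return self.right == 0

    def clade(self, side: int) -> int:
        return self.left if side == LEFT else self.right

    def key(self) -> tuple[int, int]:
        return (self.left, self.right)

    def bitstring(self, n_taxa: int) -> str:
        return (
            clade_bitstring(self.left, n_taxa)
            + "|"
            + clade_bitstring(self.right, n_taxa)
        )

    @classmethod
    def from_bitstring(cls, s: str) -> "Subsplit":
        l, r = s.split("|")
        return cls.make(clade_from_bitstring(l), clade_from_bitstring(r))


class SubsplitClade(NamedTuple):
    """A subsplit focusing attention on one of its clades."""

    subsplit: Subsplit
    side: int

    @property
    def clade(self) -> int:
        return self.subsplit.clade(self.side)


class Topology:
    """A rooted bifurcating leaf-labeled tree on the full taxon set.

    Represented by its set of non-leaf subsplits (the rootsplit plus one
    subsplit per internal node); this set determines the tree completely and
    makes containment and equality checks order-insensitive.
    """

    __slots__ = ("taxa", "subsplits", "_by_union")

    def __init__(self, taxa: TaxonSet, subsplits: Iterable[Subsplit]):
        self.taxa = taxa
        ss = frozenset(s for s in subsplits if not s.is_leaf)
        n = len(taxa)
        if len(ss) != n - 1:
            raise ValueError(
                f"a topology on {n} taxa has {n - 1} non-leaf subsplits, got {len(ss)}"
            )
        by_union: dict[int, Subsplit] = {}
        covered = 0
        for s in ss:
            if s.is_degenerate:
                raise ValueError("topology subsplits must have two non-empty clades")
            if s.union in by_union:
                raise ValueError("duplicate clade in topology subsplit set")
            by_union[s.union] = s
            covered |= s.union
        if covered != taxa.full_mask or taxa.full_mask not in by_union:
            raise ValueError("topology subsplits do not resolve the full taxon set")
        for s in ss:
            for side in (LEFT, RIGHT):
                w = s.clade(side)
                if popcount(w) > 1 and w not in by_union:
                    raise ValueError("topology subsplit set is not closed under clades")
        self.subsplits = ss
        self._by_union = by_union

    @classmethod
    def from_nested(cls, taxa: TaxonSet, nested) -> "Topology":
        """Build from a nested pair structure of taxon labels, e.g. ((a,b),(c,d))."""
        subsplits: list[Subsplit] = []

        def rec(node) -> int:
            if isinstance(node, (tuple, list)):
                if len(node) != 2:
                    raise ValueError("topology must be bifurcating")
                a, b = rec(node[0]), rec(node[1])
                subsplits.append(Subsplit.make(a, b))
                return a | b
            return 1 << taxa.index(str(node))

        rec(nested)
        return cls(taxa, subsplits)

    @property
    def rootsplit(self) -> Subsplit:
        return self._by_union[self.taxa.full_mask]

    def subsplit_below(self, clade: int) -> Subsplit:
        """The subsplit resolving ``clade``; a leaf subsplit for singletons."""
        if popcount(clade) == 1:
            return Subsplit(clade, 0)
        return self._by_union[clade]

    def edges(self) -> list[tuple[SubsplitClade, Subsplit]]:
        """All parent-child subsplit edges, including rho -> rootsplit and
        edges to leaf subsplits."""
        out = [(SubsplitClade(Subsplit.root(self.taxa), LEFT), self.rootsplit)]
        for s in self.subsplits:
            for side in (LEFT, RIGHT):
                out.append((SubsplitClade(s, side), self.subsplit_below(s.clade(side))))
        return out

    def contains_subsplit(self, s: Subsplit) -> bool:
        if s.is_leaf or s.is_root(self.taxa):
            return True
        return s in self.subsplits

    def to_nested(self):
        """The nested-pair representation with taxon labels, left clade first."""

        def rec(clade: int):
            if popcount(clade) == 1:
                return self.taxa.labels[clade.bit_length() - 1]
            s = self._by_union[clade]
            return (rec(s.left), rec(s.right))

        return rec(self.taxa.full_mask)

    def to_newick(self) -> str:
        def rec(clade: int) -> str:
            if popcount(clade) == 1:
                return self.taxa.labels[clade.bit_length() - 1]
            s = self._by_union[clade]
            return f"({rec(s.left)},{rec(s.right)})"

        return rec(self.taxa.full_mask) + ";"

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Topology)
            and self.taxa == other.taxa
            and self.subsplits == other.subsplits
        )

    def __hash__(self) -> int:
        return hash((self.taxa, self.subsplits))

    def __repr__(self) -> str:
        return f"Topology({self.to_newick()!r})"
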