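"""Synthetic data generation: JC sequence simulation and NNI tree sets.

These emulate the two inputs of the method: a DNA alignment evolved along a
known tree under the Jukes-Cantor model, and a collection of rooted
topologies (a "true" tree plus nearest-neighbor-interchange perturbations,
standing in for a bootstrap or MCMC tree sample) from which a non-trivial
subsplit DAG can be built.
"""

from __future__ import annotations

import numpy as np

from .alignment import SitePatterns
from .oracle import BranchMap
from .substitution import ALPHABET, jc_transition_matrix, stationary_distribution
from .taxa import LEFT, RIGHT, Subsplit, SubsplitClade, TaxonSet, Topology, popcount

__all__ = [
    "simulate_alignment",
    "simulate_patterns",
    "generate_tree_set",
    "nni_neighbors",
    "random_topology",
]


def random_topology(taxa: TaxonSet, seed: int | np.random.Generator) -> Topology:
    """A uniformly random rooted bifurcating topology by random sequential
    joins of subtrees."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    items: list = list(taxa.labels)
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        b = items.pop(int(j))
        a = items.pop(int(i))
        items.append((a, b))
    return Topology.from_nested(taxa, items[0])


def simulate_alignment(
    tau: Topology,
    branches: BranchMap,
    n_sites: int,
    seed: int | np.random.Generator,
) -> dict[str, str]:
    """Evolve ``n_sites`` DNA sites down a rooted tree under Jukes-Cantor.

    The root state is drawn from the stationary distribution and each branch
    applies its transition matrix.  Deterministic given the seed; returns a
    taxon -> sequence mapping.
    """
    if n_sites < 1:
        raise ValueError("need at least one site")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    taxa = tau.taxa
    pi = stationary_distribution()
    root_states = rng.choice(4, size=n_sites, p=pi)
    seqs: dict[str, str] = {}

    def descend(clade: int, states: np.ndarray) -> None:
        if popcount(clade) == 1:
            taxon = taxa.labels[clade.bit_length() - 1]
            seqs[taxon] = "".join(ALPHABET[s] for s in states)
            return
        s = tau.subsplit_below(clade)
        for side in (LEFT, RIGHT):
            child_clade = s.clade(side)
            child = tau.subsplit_below(child_clade)
            pmat = jc_transition_matrix(branches(SubsplitClade(s, side), child))
            cum = np.cumsum(pmat, axis=1)
            u = rng.random(n_sites)
            child_states = (u[:, None] > cum[states]).sum(axis=1)
            descend(child_clade, child_states)

    descend(taxa.full_mask, root_states)
    return seqs


def simulate_patterns(
    tau: Topology,
    branches: BranchMap,
    n_sites: int,
    seed: int | np.random.Generator,
) -> SitePatterns:
    seqs = simulate_alignment(tau, branches, n_sites, seed)
    return SitePatterns.from_sequences(tau.taxa, seqs)


def nni_neighbors(tau: Topology) -> list[Topology]:
    """All rooted nearest-neighbor-interchange neighbors of a topology.

    For every internal edge (parent v with sibling clade w and children
    c1, c2) the two swaps (w, c1) and (w, c2) each yield a neighbor.
    Deterministic order; duplicates removed.
    """
    taxa = tau.taxa
    out: list[Topology] = []
    seen: set[frozenset[Subsplit]] = {tau.subsplits}
    for parent in sorted(tau.subsplits, key=lambda s: (s.left, s.right)):
        for side in (LEFT, RIGHT):
            v_clade = parent.clade(side)
            if popcount(v_clade) < 2:
                continue  # v must be internal to have two children to swap
            w_clade = parent.clade(RIGHT if side == LEFT else LEFT)
            v = tau.subsplit_below(v_clade)
            for keep_side in (LEFT, RIGHT):
                kept = v.clade(keep_side)
                moved = v.clade(RIGHT if keep_side == LEFT else LEFT)
                # Swap w with `moved`: new internal node joins kept and w.
                new_inner = Subsplit.make(kept, w_clade)
                new_parent = Subsplit.make(kept | w_clade, moved)
                ss = set(tau.subsplits)
                ss.discard(parent)
                ss.discard(v)
                ss.add(new_inner)
                ss.add(new_parent)
                key = frozenset(ss)
                if key not in seen:
                    seen.add(key)
                    out.append(Topology(taxa, key))
    return out


def generate_tree_set(
    tau_true: Topology, k_neighbors: int, seed: int | np.random.Generator
) -> list[Topology]:
    """The true topology plus ``k_neighbors`` distinct NNI-perturbed ones.

    Perturbations are drawn by repeatedly applying a random NNI to a random
    member of the growing set, so for larger ``k`` the set spreads beyond the
    immediate neighborhood of the true tree.  Raises if the requested count
    exceeds what is reachable (tiny taxon sets).
    """
    if k_neighbors < 0:
        raise ValueError("k_neighbors must be >= 0")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    found = [tau_true]
    found_keys = {tau_true.subsplits}
    stale = 0
    while len(found) < k_neighbors + 1:
        base = found[rng.integers(len(found))]
        nbrs = nni_neighbors(base)
        nbrs = [t for t in nbrs if t.subsplits not in found_keys]
        if not nbrs:
            stale += 1
            if stale > 50 * (k_neighbors + 1):
                raise ValueError(
                    f"cannot find {k_neighbors} distinct NNI perturbations "
                    f"on {len(tau_true.taxa)} taxa"
                )
            continue
        pick = nbrs[rng.integers(len(nbrs))]
        found.append(pick)
        found_keys.add(pick.subsplits)
        stale = 0
    return found
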