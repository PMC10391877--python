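import numpy as np
import pytest

from gpdag import TaxonSet, Topology, build_dag
from gpdag.alignment import SitePatterns
from gpdag.simulate import random_topology

BASES = "ACGT"


@pytest.fixture
def four_taxa():
    return TaxonSet(["0", "1", "2", "3"])


@pytest.fixture
def three_tree_set(four_taxa):
    """The canonical worked example: three trees on four taxa whose DAG has
    two rootsplits and exactly three topologies."""
    return [
        Topology.from_nested(four_taxa, (("0", "1"), ("2", "3"))),
        Topology.from_nested(four_taxa, ("0", (("1", "2"), "3"))),
        Topology.from_nested(four_taxa, ("0", ("1", ("2", "3")))),
    ]


@pytest.fixture
def three_tree_dag(three_tree_set):
    return build_dag(three_tree_set)


def random_patterns(taxa: TaxonSet, n_sites: int, rng: np.random.Generator) -> SitePatterns:
    """Alignment with i.i.d. uniform random bases (not tree-generated)."""
    seqs = {
        lab: "".join(rng.choice(list(BASES), size=n_sites)) for lab in taxa
    }
    return SitePatterns.from_sequences(taxa, seqs)


def random_dag_instance(
    rng: np.random.Generator,
    n_taxa_choices=(4, 5, 6),
    n_trees_range=(2, 8),
    max_topologies=200,
):
    """A random multi-tree DAG with n_total under an enumeration budget."""
    while True:
        n_taxa = int(rng.choice(n_taxa_choices))
        taxa = TaxonSet([f"t{i}" for i in range(n_taxa)])
        n_trees = int(rng.integers(n_trees_range[0], n_trees_range[1] + 1))
        trees = [random_topology(taxa, rng) for _ in range(n_trees)]
        dag = build_dag(list({t for t in trees}))
        if dag.n_topologies() <= max_topologies:
            return dag
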