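import numpy as np
import pytest

from gpdag import (
    GPEngine,
    Subsplit,
    TaxonSet,
    Topology,
    build_dag,
    flat_prior_conditionals,
    uniform_prior_conditionals,
)
from gpdag.alignment import SitePatterns
from gpdag.oracle import (
    branch_map_from_dag,
    enumeration_all_marginals,
    felsenstein_edge_decomposition,
    felsenstein_log_likelihood,
)
from gpdag.simulate import random_topology, simulate_patterns
from gpdag.taxa import LEFT, RIGHT

from conftest import random_dag_instance, random_patterns


def make_engine(dag, patterns, rng, scaling=True, prior=uniform_prior_conditionals):
    theta = rng.uniform(0.01, 1.0, dag.n_edges)
    eng = GPEngine(
        dag, patterns, conditionals=prior(dag), branch_lengths=theta, scaling=scaling
    )
    eng.full_passes()
    return eng, theta


class TestSingleTreeReduction:
    """On a single-tree DAG the engine must reproduce classic two-pass
    Felsenstein pruning at every node, edge, and site."""

    @pytest.mark.parametrize("n_taxa", [3, 6, 12])
    def test_per_node_p_equals_lower_partials(self, n_taxa):
        rng = np.random.default_rng(n_taxa)
        taxa = TaxonSet([f"t{i}" for i in range(n_taxa)])
        tau = random_topology(taxa, rng)
        dag = build_dag([tau])
        pats = random_patterns(taxa, 9, rng)
        eng, theta = make_engine(dag, pats, rng)
        from gpdag.oracle import _lower_partials

        partials = _lower_partials(tau, branch_map_from_dag(dag, theta), pats)
        for i, s in enumerate(dag.nodes):
            if s.is_leaf or i == dag.root_node:
                continue
            got = eng.p[i] * np.exp(eng.p_scale[i])[:, None]
            np.testing.assert_allclose(got, partials[s.union], atol=1e-12)

    def test_per_edge_equals_tree_likelihood_at_every_edge(self):
        rng = np.random.default_rng(71)
        taxa = TaxonSet([f"t{i}" for i in range(8)])
        tau = random_topology(taxa, rng)
        dag = build_dag([tau])
        pats = random_patterns(taxa, 13, rng)
        eng, theta = make_engine(dag, pats, rng)
        fels = felsenstein_log_likelihood(tau, branch_map_from_dag(dag, theta), pats)
        np.testing.assert_allclose(eng.site_log_marginals(), fels, atol=1e-10)
        for k in range(dag.n_edges):
            np.testing.assert_allclose(
                eng.per_edge_log_marginals(k), fels, atol=1e-10
            )

    def test_r_vectors_match_classic_upper_partials(self):
        """r at a subsplit-clade times the edge transition equals the classic
        r^T P p edge decomposition (prior mass is 1 on a single tree)."""
        rng = np.random.default_rng(73)
        taxa = TaxonSet([f"t{i}" for i in range(6)])
        tau = random_topology(taxa, rng)
        dag = build_dag([tau])
        pats = random_patterns(taxa, 5, rng)
        eng, theta = make_engine(dag, pats, rng)
        decomp = felsenstein_edge_decomposition(
            tau, branch_map_from_dag(dag, theta), pats
        )
        for k, (i, side, j) in enumerate(dag.edges):
            if i == dag.root_node:
                continue
            parent, child = dag.nodes[i], dag.nodes[j]
            vals = np.exp(eng.per_edge_log_marginals(k))
            np.testing.assert_allclose(
                vals, decomp[(parent.union, child.union)], atol=1e-10
            )


class TestTrivialCases:
    def test_zero_branches_same_base_gives_quarter(self, three_tree_dag):
        taxa = three_tree_dag.taxa
        pats = SitePatterns.from_sequences(taxa, {lab: "A" for lab in taxa})
        eng = GPEngine(three_tree_dag, pats, branch_lengths=0.0)
        eng.rootward_pass()
        # every tree gives likelihood 1/4; the prior sums to 1
        assert eng.site_log_marginal(0) == pytest.approx(np.log(0.25), abs=1e-12)
        # p at each rootsplit is the indicator of base A
        for t in three_tree_dag.rootsplits():
            vec = eng.p[t][0] * np.exp(eng.p_scale[t][0])
            np.testing.assert_allclose(vec, [1.0, 0.0, 0.0, 0.0], atol=1e-15)

    def test_fully_missing_column_marginalizes_to_one(self, three_tree_dag):
        taxa = three_tree_dag.taxa
        pats = SitePatterns.from_sequences(taxa, {lab: "-" for lab in taxa})
        eng = GPEngine(three_tree_dag, pats, branch_lengths=0.3)
        eng.rootward_pass()
        assert eng.site_log_marginal(0) == pytest.approx(0.0, abs=1e-12)

    def test_pattern_weights_match_repeated_columns(self, three_tree_dag):
        taxa = three_tree_dag.taxa
        seqs = {"0": "AAC", "1": "AAG", "2": "CCT", "3": "CCT"}
        compressed = SitePatterns.from_sequences(taxa, seqs)
        raw = SitePatterns.from_sequences(taxa, seqs, compress=False)
        assert compressed.n_patterns == 2 and raw.n_patterns == 3
        e1 = GPEngine(three_tree_dag, compressed, branch_lengths=0.2)
        e2 = GPEngine(three_tree_dag, raw, branch_lengths=0.2)
        e1.rootward_pass(), e2.rootward_pass()
        assert e1.composite_log_likelihood() == pytest.approx(
            e2.composite_log_likelihood(), abs=1e-12
        )


class TestEnumerationEquivalence:
    @pytest.mark.parametrize("prior", [uniform_prior_conditionals, flat_prior_conditionals])
    def test_site_and_edge_marginals_match_enumeration(self, prior):
        rng = np.random.default_rng(79)
        for _ in range(6):
            dag = random_dag_instance(rng)
            pats = random_patterns(dag.taxa, int(rng.integers(1, 20)), rng)
            eng, theta = make_engine(dag, pats, rng, prior=prior)
            site_o, edge_o = enumeration_all_marginals(
                dag, theta, eng.conditionals, pats
            )
            np.testing.assert_allclose(eng.site_log_marginals(), site_o, atol=1e-8)
            for k, vals in edge_o.items():
                np.testing.assert_allclose(
                    eng.per_edge_log_marginals(k), vals, atol=1e-8
                )


class TestScaling:
    def test_scaled_and_unscaled_agree_on_small_instance(self):
        rng = np.random.default_rng(83)
        dag = random_dag_instance(rng)
        pats = random_patterns(dag.taxa, 8, rng)
        theta = rng.uniform(0.01, 1.0, dag.n_edges)
        engines = []
        for scaling in (True, False):
            e = GPEngine(dag, pats, branch_lengths=theta, scaling=scaling)
            e.full_passes()
            engines.append(e)
        np.testing.assert_allclose(
            engines[0].site_log_marginals(), engines[1].site_log_marginals(),
            atol=1e-8,
        )
        for k in range(dag.n_edges):
            np.testing.assert_allclose(
                engines[0].per_edge_log_marginals(k),
                engines[1].per_edge_log_marginals(k),
                atol=1e-8,
            )

    def test_hundred_taxon_tree_stays_finite_with_scaling(self):
        rng = np.random.default_rng(89)
        taxa = TaxonSet([f"t{i:03d}" for i in range(100)])
        tau = random_topology(taxa, rng)
        dag = build_dag([tau])
        pats = random_patterns(taxa, 4, rng)
        eng = GPEngine(dag, pats, branch_lengths=0.08, scaling=True)
        eng.full_passes()
        slm = eng.site_log_marginals()
        assert np.all(np.isfinite(slm)) and np.all(slm < 0)
        for k in range(0, dag.n_edges, 17):
            assert np.all(np.isfinite(eng.per_edge_log_marginals(k)))


class TestRootEdges:
    def test_root_outgoing_branch_lengths_are_inert(self, three_tree_dag):
        rng = np.random.default_rng(97)
        pats = random_patterns(three_tree_dag.taxa, 6, rng)
        eng, _ = make_engine(three_tree_dag, pats, rng)
        before = eng.composite_log_likelihood()
        for k, (i, _s, _j) in enumerate(three_tree_dag.edges):
            if i == three_tree_dag.root_node:
                eng.set_branch_length(k, 2.5)
                assert not eng.dirty.any()
        eng.full_passes()
        assert eng.composite_log_likelihood() == pytest.approx(before, abs=1e-12)


class TestGradients:
    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(101)
        dag = random_dag_instance(rng)
        pats = random_patterns(dag.taxa, 10, rng)
        eng, _ = make_engine(dag, pats, rng)
        h = 1e-6
        for k in range(dag.n_edges):
            if dag.edges[k][0] == dag.root_node:
                continue
            g_edge, g_full = eng.branch_log_gradient(k)
            th0 = eng.theta[k]

            def pe(t):
                eng.set_branch_length(k, t)
                return eng.per_edge_composite_log_likelihood(k)

            def full(t):
                eng.set_branch_length(k, t)
                return eng.composite_log_likelihood()

            fd_edge = (pe(th0 + h) - pe(th0 - h)) / (2 * h)
            eng.set_branch_length(k, th0)
            fd_full = (full(th0 + h) - full(th0 - h)) / (2 * h)
            eng.set_branch_length(k, th0)
            assert g_edge == pytest.approx(fd_edge, abs=1e-5)
            assert g_full == pytest.approx(fd_full, abs=1e-5)
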