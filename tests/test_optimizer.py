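import numpy as np
import pytest

from gpdag import (
    GPEngine,
    OptimizerConfig,
    TaxonSet,
    Topology,
    build_dag,
    invalidate_and_clean,
    optimize_edge_branch,
    run_schedule,
)
from gpdag.oracle import branch_map_from_dag
from gpdag.simulate import generate_tree_set, random_topology, simulate_patterns

from conftest import random_dag_instance, random_patterns


def effective_log_p(engine):
    """Stored p-PLVs with their scalers folded in (log space, masked zeros)."""
    with np.errstate(divide="ignore"):
        return np.where(
            engine.p > 0, np.log(engine.p) + engine.p_scale[..., None], -np.inf
        )


class TestOptimizeEdgeBranch:
    def test_two_taxon_ml_matches_grid_scan(self):
        rng = np.random.default_rng(7)
        taxa = TaxonSet(["a", "b"])
        tau = Topology.from_nested(taxa, ("a", "b"))
        dag = build_dag([tau])
        theta_true = np.full(dag.n_edges, 0.12)
        pats = simulate_patterns(tau, branch_map_from_dag(dag, theta_true), 10_000, rng)
        # hold the sibling branch at its true value; optimize one pendant edge
        eng = GPEngine(dag, pats, branch_lengths=theta_true)
        eng.full_passes()
        cfg = OptimizerConfig()
        k = next(
            k for k, (i, _s, _j) in enumerate(dag.edges) if i != dag.root_node
        )
        fitted = optimize_edge_branch(eng, k, cfg)
        # independent 1-D scan of the same likelihood on a fine grid
        grid = np.linspace(1e-4, 1.0, 8001)
        vals = [eng.edge_objective(k, th) for th in grid]
        scan_opt = grid[int(np.argmax(vals))]
        assert fitted == pytest.approx(scan_opt, abs=5e-4)
        # curvature-based standard error of the 1-D ML estimate
        h = 1e-3
        curv = (
            eng.edge_objective(k, fitted + h)
            - 2 * eng.edge_objective(k, fitted)
            + eng.edge_objective(k, fitted - h)
        ) / h**2
        se = 1.0 / np.sqrt(-curv)
        assert abs(fitted - 0.12) < 3 * se

    def test_objective_never_decreases(self):
        rng = np.random.default_rng(13)
        dag = random_dag_instance(rng)
        pats = random_patterns(dag.taxa, 15, rng)
        eng = GPEngine(dag, pats, branch_lengths=rng.uniform(0.01, 1.5, dag.n_edges))
        eng.full_passes()
        cfg = OptimizerConfig()
        for k in range(dag.n_edges):
            if dag.edges[k][0] == dag.root_node:
                continue
            before = eng.per_edge_composite_log_likelihood(k)
            new = optimize_edge_branch(eng, k, cfg)
            assert eng.edge_objective(k, new) >= before - 1e-12

    def test_brent_and_gradient_methods_agree(self):
        rng = np.random.default_rng(17)
        dag = random_dag_instance(rng)
        pats = random_patterns(dag.taxa, 12, rng)
        theta0 = rng.uniform(0.02, 1.0, dag.n_edges)
        eng = GPEngine(dag, pats, branch_lengths=theta0)
        eng.full_passes()
        for k in range(dag.n_edges):
            if dag.edges[k][0] == dag.root_node:
                continue
            b = optimize_edge_branch(eng, k, OptimizerConfig(method="brent"))
            g = optimize_edge_branch(eng, k, OptimizerConfig(method="gradient"))
            assert b == pytest.approx(g, abs=1e-5)


class TestSchedule:
    def test_multi_tree_smoke_convergence(self):
        rng = np.random.default_rng(19)
        taxa = TaxonSet([f"t{i}" for i in range(6)])
        true_tau = random_topology(taxa, rng)
        dag = build_dag(generate_tree_set(true_tau, 4, rng))
        pats = simulate_patterns(true_tau, lambda *_: 0.1, 1000, rng)
        eng = GPEngine(dag, pats)
        _theta, trace = run_schedule(eng, OptimizerConfig(max_sweeps=30))
        assert trace.converged
        assert abs(trace.log_likelihoods[-1] - trace.log_likelihoods[-2]) < 1e-4

    def test_fixed_point_at_converged_values(self):
        rng = np.random.default_rng(23)
        taxa = TaxonSet([f"t{i}" for i in range(5)])
        tau = random_topology(taxa, rng)
        dag = build_dag([tau])
        pats = simulate_patterns(tau, lambda *_: 0.15, 800, rng)
        eng = GPEngine(dag, pats)
        theta1, _ = run_schedule(eng, OptimizerConfig(convergence_tol=1e-9))
        eng2 = GPEngine(dag, pats, branch_lengths=theta1)
        theta2, trace2 = run_schedule(eng2, OptimizerConfig(max_sweeps=1))
        # restarting at the optimum changes nothing beyond the scalar tolerance
        assert np.abs(theta2 - theta1).max() < 10 * OptimizerConfig().brent_tol
        assert trace2.log_likelihoods[0] == pytest.approx(
            eng2.composite_log_likelihood(), abs=1e-9
        )

    def test_determinism_under_fixed_inputs(self):
        rng = np.random.default_rng(29)
        dag = random_dag_instance(rng)
        pats = random_patterns(dag.taxa, 25, rng)
        results = []
        for _ in range(2):
            eng = GPEngine(dag, pats)
            theta, _ = run_schedule(eng, OptimizerConfig(seed=0))
            results.append(theta.tobytes())
        assert results[0] == results[1]


class TestDirtyNodes:
    def test_leaf_edge_edit_flags_the_root_path(self):
        taxa = TaxonSet(["a", "b", "c", "d"])
        tau = Topology.from_nested(taxa, (("a", "b"), ("c", "d")))
        dag = build_dag([tau])
        rng = np.random.default_rng(31)
        pats = random_patterns(taxa, 4, rng)
        eng = GPEngine(dag, pats)
        eng.full_passes()
        # edge from the cherry {a|b} down to leaf a
        from gpdag import LEFT, Subsplit

        cherry = Subsplit.make(taxa.mask("a"), taxa.mask("b"))
        k = dag.edge_id(cherry, LEFT, Subsplit.leaf(0))
        eng.set_branch_length(k, eng.theta[k] + 0.05)
        flagged = {dag.nodes[i] for i in np.flatnonzero(eng.dirty)}
        assert flagged == {cherry, tau.rootsplit}

    def test_rho_edge_edit_flags_nothing(self, three_tree_dag):
        rng = np.random.default_rng(37)
        pats = random_patterns(three_tree_dag.taxa, 4, rng)
        eng = GPEngine(three_tree_dag, pats)
        eng.full_passes()
        for k, (i, _s, _j) in enumerate(three_tree_dag.edges):
            if i == three_tree_dag.root_node:
                eng.set_branch_length(k, 1.23)
        assert not eng.dirty.any()

    def test_cleaned_plvs_equal_fresh_rootward_pass(self):
        rng = np.random.default_rng(41)
        dag = random_dag_instance(rng)
        pats = random_patterns(dag.taxa, 7, rng)
        eng = GPEngine(dag, pats)
        eng.full_passes()
        non_root = [
            k for k, (i, _s, _j) in enumerate(dag.edges) if i != dag.root_node
        ]
        for step in range(50):
            k = int(rng.choice(non_root))
            eng.set_branch_length(k, float(rng.uniform(0.001, 2.0)))
            if step % 3 == 0:  # interleaved reads trigger lazy cleanup
                eng.per_edge_log_marginals(int(rng.choice(non_root)))
            if step % 7 == 0:
                eng.site_log_marginals()
        for t in dag.rootsplits():
            eng.ensure_clean(t)
        fresh = GPEngine(dag, pats, branch_lengths=eng.theta.copy())
        fresh.rootward_pass()
        np.testing.assert_allclose(
            effective_log_p(eng), effective_log_p(fresh), atol=1e-12
        )

    def test_invalidate_and_clean_reports_refresh_count(self):
        rng = np.random.default_rng(43)
        dag = random_dag_instance(rng)
        pats = random_patterns(dag.taxa, 5, rng)
        eng = GPEngine(dag, pats)
        eng.full_passes()
        k = next(
            k for k, (i, _s, _j) in enumerate(dag.edges) if i != dag.root_node
        )
        n = invalidate_and_clean(eng, k, eng.theta[k] + 0.1)
        assert n >= 1 and not eng.dirty.any()
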