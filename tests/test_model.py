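"""Model definition, simulation and benchmark-fixture behavior."""

import numpy as np
import pytest

from grnrestore import (CTMParameters, NetworkStructure, StructureError,
                        UnstableModelError, add_random_pairs, make_benchmark,
                        sample_parameters, simulate, transition_mean,
                        undirected_to_directed)
from grnrestore.model import CompiledModel


class TestTransitionMean:
    def test_identity_when_all_coefficients_zero(self):
        s = NetworkStructure(p=2)
        params = CTMParameters.zeros(s)
        out = transition_mean(params, s, np.array([1.0, 2.0]))
        np.testing.assert_allclose(out, [1.0, 2.0])

    def test_hand_computed_quadratic_example(self):
        # gene 1 regulated by genes 2 and 3 with a pair term:
        # 0.8 (self) + 1.0 (a12 x2) + 0.4 (a13 x3) + 0.8 (b x2 x3) + 0.3 (u)
        s = NetworkStructure(p=3, linear_sets=[{1, 2}, set(), set()],
                             pair_sets=[{(1, 2)}, set(), set()])
        params = CTMParameters.zeros(s)
        params.a[0, 0] = -0.2
        params.a[0, 1] = 0.5
        params.a[0, 2] = 0.1
        params.b = {(0, (1, 2)): 0.1}
        params.u[0] = 0.3
        out = transition_mean(params, s, np.array([1.0, 2.0, 4.0]))
        assert out[0] == pytest.approx(3.3, abs=1e-12)

    def test_zero_state_returns_intercept(self):
        s = NetworkStructure(p=3, linear_sets=[{1}, {2}, {0}])
        params = CTMParameters.zeros(s)
        params.u = np.array([0.7, -0.2, 1.5])
        out = transition_mean(params, s, np.zeros(3))
        np.testing.assert_allclose(out, params.u)

    def test_linear_in_coefficients(self):
        """The map is exactly linear in (a, b, g, u) for fixed state."""
        s = NetworkStructure(p=3, M=1, linear_sets=[{1, 2}, set(), set()],
                             pair_sets=[{(1, 2)}, set(), set()],
                             drug_sets=[{0}, set(), set()])
        x = np.array([0.5, -1.2, 2.0])
        d = np.array([0.8])
        rng = np.random.default_rng(0)

        def random_params(scale):
            params = CTMParameters.zeros(s)
            params.a[0, 1] = scale * rng.uniform(-1, 1)
            params.b = {(0, (1, 2)): scale * rng.uniform(-1, 1)}
            params.g[0, 0] = scale * rng.uniform(-1, 1)
            params.u[0] = scale * rng.uniform(-1, 1)
            return params

        pa, pb = random_params(1.0), random_params(1.0)
        combo = CTMParameters.zeros(s)
        combo.a = 2.0 * pa.a + 3.0 * pb.a
        combo.b = {k: 2.0 * pa.b[k] + 3.0 * pb.b[k] for k in pa.b}
        combo.g = 2.0 * pa.g + 3.0 * pb.g
        combo.u = 2.0 * pa.u + 3.0 * pb.u
        base = x  # zero-coefficient map returns x itself
        lhs = transition_mean(combo, s, x, d) - base
        rhs = (2.0 * (transition_mean(pa, s, x, d) - base)
               + 3.0 * (transition_mean(pb, s, x, d) - base))
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        s = NetworkStructure(p=2)
        params = CTMParameters.zeros(s)
        with pytest.raises(StructureError):
            CompiledModel(params, s).mean(np.ones(3))

    def test_pair_outside_active_set_rejected(self):
        with pytest.raises(StructureError):
            NetworkStructure(p=3, linear_sets=[{1}, set(), set()],
                             pair_sets=[{(1, 2)}, set(), set()])

    def test_self_pair_rejected(self):
        with pytest.raises(StructureError):
            NetworkStructure(p=3, linear_sets=[{1, 2}, set(), set()],
                             pair_sets=[{(1, 1)}, set(), set()])


class TestSimulate:
    def test_noise_free_identity_dynamics_constant(self):
        s = NetworkStructure(p=2)
        params = CTMParameters.zeros(s, q=0.0, r=0.0)
        params.mu0 = np.array([1.5, -2.0])
        params.sigma0_diag = np.zeros(2)
        traj, obs = simulate(s, params, T=10, n_series=1, rng_seed=0)
        np.testing.assert_allclose(traj.x[0], np.tile(params.mu0, (10, 1)))
        for t in obs[0].observed_times:
            np.testing.assert_allclose(obs[0].y[t - 1][0], params.mu0)

    def test_noise_free_equals_iterated_transition(self, chain3,
                                                   linear_params_chain3):
        params = linear_params_chain3.copy()
        params.q_diag = np.zeros(3)
        params.r_diag = np.zeros(3)
        params.sigma0_diag = np.zeros(3)
        traj, _ = simulate(chain3, params, T=12, n_series=1, rng_seed=3)
        x = params.mu0.copy()
        for t in range(1, 12):
            x = transition_mean(params, chain3, x)
            np.testing.assert_allclose(traj.x[0][t], x, atol=1e-12)

    def test_five_series_of_thirty_points(self, chain3, linear_params_chain3):
        traj, obs = simulate(chain3, linear_params_chain3, T=30, n_series=5,
                             rng_seed=7)
        assert len(traj.x) == 5 and len(obs) == 5
        assert all(x.shape == (30, 3) for x in traj.x)
        assert all(o.T == 30 and len(o.observed_times) == 30 for o in obs)

    def test_observation_noise_variance_matches(self):
        """Sample variance of y - x recovers the configured 0.3."""
        s = NetworkStructure(p=2)
        params = CTMParameters.zeros(s, q=0.01, r=0.3)
        np.fill_diagonal(params.a, -0.5)
        traj, obs = simulate(s, params, T=2000, n_series=1, rng_seed=11)
        resid = np.vstack([obs[0].y[t - 1][0] - traj.x[0][t - 1]
                           for t in obs[0].observed_times])
        n = resid.size
        se = 0.3 * np.sqrt(2.0 / n)
        assert abs(resid.var() - 0.3) < 3 * se

    def test_reproducible_from_seed(self, chain3, linear_params_chain3):
        t1, o1 = simulate(chain3, linear_params_chain3, T=15, n_series=2,
                          rng_seed=5)
        t2, o2 = simulate(chain3, linear_params_chain3, T=15, n_series=2,
                          rng_seed=5)
        np.testing.assert_array_equal(t1.x[1], t2.x[1])
        np.testing.assert_array_equal(o1[0].y[4], o2[0].y[4])

    def test_divergence_raises_explicitly(self):
        s = NetworkStructure(p=1)
        params = CTMParameters.zeros(s, q=0.0, r=0.0)
        params.a[0, 0] = 2.0  # multiplier 3: explosive
        params.mu0 = np.array([1.0])
        params.sigma0_diag = np.zeros(1)
        with pytest.raises(UnstableModelError):
            simulate(s, params, T=60, n_series=1, rng_seed=0)


class TestSampleParameters:
    def test_coefficients_within_unit_interval(self):
        truth = make_benchmark("wnt5a")
        truth = add_random_pairs(truth, 0.2, rng_seed=1)
        params = sample_parameters(truth, rng_seed=1)
        diag_multiplier = 1.0 + np.diag(params.a)
        assert np.all(np.abs(diag_multiplier) <= 1.0)
        off = params.a[~np.eye(10, dtype=bool)]
        assert np.all(np.abs(off) <= 1.0)
        assert all(abs(v) <= 1.0 for v in params.b.values())
        assert np.all(np.abs(params.u) <= 1.0)

    def test_deterministic_given_seed(self):
        truth = make_benchmark("yeast_cell_cycle")
        p1 = sample_parameters(truth, rng_seed=42)
        p2 = sample_parameters(truth, rng_seed=42)
        np.testing.assert_array_equal(p1.a, p2.a)
        assert p1.b == p2.b

    def test_stability_screen_holds(self):
        """The accepted draw passes its own noise-free-bound criterion."""
        truth = make_benchmark("wnt5a")
        params = sample_parameters(truth, rng_seed=9, bound=50.0)
        x = params.mu0.copy()
        for _ in range(30):
            x = transition_mean(params, truth, x)
            assert np.all(np.abs(x) <= 50.0)


class TestBenchmarks:
    @pytest.mark.parametrize("name,n_edges", [("wnt5a", 30),
                                              ("yeast_cell_cycle", 26)])
    def test_sizes_and_universe(self, name, n_edges):
        s = make_benchmark(name)
        assert s.p == 10
        assert s.n_edges() == n_edges
        assert all(j != i for (j, i) in s.edges())
        # directed evaluation universe: TP+FP+TN+FN must sum to p(p-1)=90
        assert s.p * (s.p - 1) == 90

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            make_benchmark("nonsense")


class TestUndirectedToDirected:
    def test_correct_edges_keep_true_orientation(self):
        truth = NetworkStructure(p=4, linear_sets=[set(), {0}, {1}, {2}])
        out = undirected_to_directed([(0, 1), (1, 2)], truth, rng_seed=0)
        assert out == {(0, 1), (1, 2)}

    def test_incorrect_edge_gets_exactly_one_orientation(self):
        truth = NetworkStructure(p=4, linear_sets=[set(), {0}, set(), set()])
        seen = set()
        for seed in range(40):
            out = undirected_to_directed([(2, 3)], truth, rng_seed=seed)
            assert len(out) == 1
            seen |= out
        assert seen == {(2, 3), (3, 2)}  # both orientations occur over seeds

    def test_reproducible(self):
        truth = NetworkStructure(p=5, linear_sets=[set(), {0}, set(), set(),
                                                   set()])
        edges = [(0, 1), (2, 3), (1, 4), (0, 3)]
        a = undirected_to_directed(edges, truth, rng_seed=3)
        b = undirected_to_directed(edges, truth, rng_seed=3)
        assert a == b


class TestStructureInvariants:
    def test_locked_edge_must_exist(self):
        with pytest.raises(StructureError):
            NetworkStructure(p=3, linear_sets=[set(), {0}, set()],
                             locked_edges={(1, 2)})

    def test_tf_mask_enforced(self):
        with pytest.raises(StructureError):
            NetworkStructure(p=3, linear_sets=[set(), {0}, set()],
                             tf_mask=np.array([False, True, True]))

    def test_add_random_pairs_respects_subset_rule(self):
        truth = make_benchmark("wnt5a")
        with_pairs = add_random_pairs(truth, fraction=0.5, rng_seed=2)
        for i in range(10):
            for (j, k) in with_pairs.pair_sets[i]:
                assert j in with_pairs.linear_sets[i]
                assert k in with_pairs.linear_sets[i]
                assert j < k
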