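import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmlc import (
    MultilayerNetwork,
    SolverOptions,
    adjacent_importance,
    interleaved_power_iteration,
    power_iteration_single,
    residuals,
    solve,
    solve_acyclic_direct,
)
from conftest import make_dependency, random_connected_layer

# known unit-length centrality vectors (2 dp) for the worked example
EXPECTED = {
    "independent": [
        [0.50, 0.60, 0.50, 0.34, 0.15],
        [0.34, 0.15, 0.60, 0.50, 0.50],
        [0.53, 0.43, 0.36, 0.53, 0.36],
    ],
    "chain": [
        [0.50, 0.60, 0.50, 0.34, 0.15],
        [0.58, 0.26, 0.53, 0.34, 0.44],
        [0.48, 0.39, 0.43, 0.54, 0.37],
    ],
    "mixed": [
        [0.50, 0.60, 0.50, 0.34, 0.15],
        [0.58, 0.26, 0.53, 0.34, 0.44],
        [0.51, 0.41, 0.39, 0.53, 0.37],
    ],
    "negative": [
        [0.50, 0.60, 0.50, 0.34, 0.15],
        [0.58, 0.26, 0.53, 0.34, 0.44],
        [0.54, 0.44, 0.34, 0.53, 0.35],
    ],
    # layer-2 element 1 is 0.59 from the exact fixed point: x2 is proportional
    # to A2 @ x1 with x1 the Perron vector of A1 @ A3 @ A2, giving 0.5889
    "cycle": [
        [0.40, 0.68, 0.42, 0.38, 0.25],
        [0.59, 0.21, 0.55, 0.36, 0.43],
        [0.48, 0.40, 0.43, 0.52, 0.39],
    ],
}

EXPECTED_METHOD = {
    "independent": "independent",
    "chain": "direct-acyclic",
    "mixed": "interleaved",
    "negative": "interleaved",
    "cycle": "interleaved",
}


def _solve_quiet(net, D, opts):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return solve(net, D, opts)


class TestAdjacentImportance:
    def test_identity_returns_own_vector(self):
        D = make_dependency(np.eye(3))
        X = [np.arange(5.0) + j for j in range(3)]
        for i in (1, 2, 3):
            assert np.array_equal(adjacent_importance(i, D, X), X[i - 1])

    def test_full_dependency_returns_other_vector(self):
        D = make_dependency([[0, 0, 1], [1, 0, 0], [0, 1, 0]])
        X = [np.arange(5.0) + j for j in range(3)]
        assert np.array_equal(adjacent_importance(3, D, X), X[1])

    def test_linearity_with_negative_weight(self):
        D = make_dependency([[1.1, -0.1], [0, 1]])
        c = adjacent_importance(1, D, [np.array([1.0, 0.0]), np.array([0.0, 1.0])])
        assert np.allclose(c, [1.1, -0.1])

    def test_length_mismatch(self):
        D = make_dependency(np.eye(2))
        with pytest.raises(ValueError):
            adjacent_importance(1, D, [np.zeros(3), np.zeros(4)])


class TestPowerIterationSingle:
    def test_example_layer_one(self, example_net, tight_opts):
        x, lam, _ = power_iteration_single(example_net.layers[0], tight_opts)
        assert np.round(x, 2).tolist() == [0.50, 0.60, 0.50, 0.34, 0.15]
        assert lam > 0

    def test_identity_matrix_uniform_start(self):
        x, lam, _ = power_iteration_single(np.eye(2))
        assert np.allclose(x, [1 / np.sqrt(2)] * 2)
        assert lam == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 7])
    def test_matches_dense_eigendecomposition(self, seed, tight_opts):
        rng = np.random.default_rng(seed)
        A = rng.random((6, 6))
        x, lam, _ = power_iteration_single(A, tight_opts)
        w, V = np.linalg.eig(A)
        i = np.argmax(w.real)
        ref = V[:, i].real
        ref = ref / np.linalg.norm(ref)
        ref = ref if ref.sum() >= 0 else -ref
        assert np.allclose(x, ref, atol=1e-6)
        assert lam == pytest.approx(w.real[i], abs=1e-6)

    def test_zero_matrix_degenerate(self):
        with pytest.raises(ValueError, match="zero"):
            power_iteration_single(np.zeros((3, 3)))


class TestWorkedExample:
    @pytest.mark.parametrize("name", list(EXPECTED))
    def test_scenario_vectors(self, name, example_net, scenarios, tight_opts):
        res = _solve_quiet(example_net, scenarios[name], tight_opts)
        assert res.converged
        assert res.method == EXPECTED_METHOD[name]
        for got, want in zip(res.X, EXPECTED[name]):
            assert np.round(got, 2).tolist() == want

    def test_interleaved_on_identity_matches_single(self, example_net):
        # delta-on-lambda stopping resolves the eigenvector only to about
        # sqrt(tol) on symmetric layers, hence the tight tol here
        opts = SolverOptions(tol=1e-14)
        D = make_dependency(np.eye(3))
        res = interleaved_power_iteration(example_net, D, opts)
        for a, x in zip(example_net.layers, res.X):
            ref, _, _ = power_iteration_single(a, opts)
            assert np.allclose(x, ref, atol=1e-6)


class TestDirectAcyclic:
    def test_two_layer_full_dependency(self, tight_opts):
        rng = np.random.default_rng(3)
        net = MultilayerNetwork([random_connected_layer(6, rng) for _ in range(2)])
        D = make_dependency([[1, 0], [1, 0]])
        res = solve_acyclic_direct(net, D, tight_opts)
        x1, lam1, _ = power_iteration_single(net.layers[0], tight_opts)
        y = net.layers[1] @ x1
        assert np.allclose(res.X[0], x1, atol=1e-8)
        assert np.allclose(res.X[1], y / np.linalg.norm(y), atol=1e-8)

    def test_agrees_with_interleaved_on_chain(self, example_net, scenarios):
        opts = SolverOptions(tol=1e-13)
        direct = solve_acyclic_direct(example_net, scenarios["chain"], opts)
        iterative = interleaved_power_iteration(example_net, scenarios["chain"], opts)
        for a, b in zip(direct.X, iterative.X):
            assert np.allclose(a, b, atol=1e-6)

    def test_identity_reduces_to_independent(self, example_net, tight_opts):
        res = solve_acyclic_direct(example_net, make_dependency(np.eye(3)), tight_opts)
        for a, x in zip(example_net.layers, res.X):
            ref, _, _ = power_iteration_single(a, tight_opts)
            assert np.allclose(x, ref, atol=1e-8)

    def test_precondition_rejects_iterative_structures(self, example_net, scenarios):
        for name in ("mixed", "cycle"):
            with pytest.raises(ValueError, match="requires"):
                solve_acyclic_direct(example_net, scenarios[name])

    @pytest.mark.parametrize("seed", range(8))
    def test_direct_interleaved_equivalence_random(self, seed, tight_opts):
        """Direct and interleaved solvers share the fixed point on random
        acyclic case-A/B structures with k <= 4."""
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 5))
        net = MultilayerNetwork([random_connected_layer(5, rng) for _ in range(k)])
        W = np.zeros((k, k))
        W[0, 0] = 1.0  # root layer independent; each later layer depends on an earlier one
        for i in range(1, k):
            W[i, int(rng.integers(0, i))] = 1.0
        D = make_dependency(W)
        direct = solve_acyclic_direct(net, D, tight_opts)
        iterative = interleaved_power_iteration(net, D, tight_opts)
        for a, b in zip(direct.X, iterative.X):
            assert np.allclose(a, b, atol=1e-6)


class TestSolverProperties:
    @given(st.integers(min_value=0, max_value=1000))
    @settings(max_examples=15, deadline=None)
    def test_identity_reduction_matches_dense_oracle(self, seed):
        """With no inter-layer dependencies the solver returns each layer's
        principal eigenvector (dense eigendecomposition oracle)."""
        rng = np.random.default_rng(seed)
        k = int(rng.integers(1, 4))
        net = MultilayerNetwork([random_connected_layer(5, rng) for _ in range(k)])
        res = _solve_quiet(net, make_dependency(np.eye(k)), SolverOptions(tol=1e-12))
        assert res.method == "independent"
        for a, x in zip(net.layers, res.X):
            w, V = np.linalg.eig(a)
            i = np.argmax(w.real)
            ref = V[:, i].real
            ref = ref / np.linalg.norm(ref)
            ref = ref if ref.sum() >= 0 else -ref
            assert np.allclose(x, ref, atol=1e-6)

    @pytest.mark.parametrize("name", list(EXPECTED))
    def test_unit_norm_and_positivity(self, name, example_net, scenarios, tight_opts):
        res = _solve_quiet(example_net, scenarios[name], tight_opts)
        for x in res.X:
            assert np.linalg.norm(x) == pytest.approx(1.0, abs=1e-9)
            if not scenarios[name].has_negative:
                assert np.all(x > 0)  # Perron-Frobenius: irreducible nonnegative layers

    def test_permutation_equivariance(self, example_net, scenarios, tight_opts):
        rng = np.random.default_rng(0)
        perm = rng.permutation(example_net.p)
        permuted = MultilayerNetwork([a[np.ix_(perm, perm)] for a in example_net.layers])
        for name in ("chain", "mixed", "cycle"):
            res = _solve_quiet(example_net, scenarios[name], tight_opts)
            res_p = _solve_quiet(permuted, scenarios[name], tight_opts)
            for x, xp in zip(res.X, res_p.X):
                assert np.allclose(x[perm], xp, atol=1e-8)

    @pytest.mark.parametrize("name", list(EXPECTED))
    def test_update_schedule_invariance(self, name, example_net, scenarios):
        """Simultaneous and in-sweep schedules converge to the same fixed point."""
        a = _solve_quiet(example_net, scenarios[name], SolverOptions(tol=1e-10))
        b = _solve_quiet(
            example_net, scenarios[name], SolverOptions(tol=1e-10, update_schedule="in-sweep")
        )
        for xa, xb in zip(a.X, b.X):
            assert np.allclose(xa, xb, atol=1e-6)

    def test_seeded_random_init_reaches_same_fixed_point(self, example_net, scenarios):
        base = _solve_quiet(example_net, scenarios["mixed"], SolverOptions(tol=1e-10))
        rand = _solve_quiet(
            example_net,
            scenarios["mixed"],
            SolverOptions(tol=1e-10, init_mode="seeded-random", seed=42),
        )
        for xa, xb in zip(base.X, rand.X):
            assert np.allclose(xa, xb, atol=1e-6)


class TestResiduals:
    def test_exact_two_layer_solution_has_zero_residual(self, tight_opts):
        rng = np.random.default_rng(5)
        net = MultilayerNetwork([random_connected_layer(5, rng) for _ in range(2)])
        D = make_dependency([[1, 0], [1, 0]])
        res = solve_acyclic_direct(net, D, tight_opts)
        # layer-2 residual is exactly zero by construction; layer 1 is an
        # eigen-residual bounded by the solver tolerance
        assert res.residuals[1] == pytest.approx(0.0, abs=1e-9)
        assert res.residuals[0] <= 1e-6

    def test_converged_mixed_scenario_small_residuals(self, example_net, scenarios):
        res = _solve_quiet(example_net, scenarios["mixed"], SolverOptions(tol=1e-8))
        assert np.all(res.residuals <= 1e-4)

    def test_perturbation_increases_residual(self, example_net, scenarios, tight_opts):
        from dataclasses import replace

        res = _solve_quiet(example_net, scenarios["mixed"], tight_opts)
        x0 = res.X[0].copy()
        x0[0] += 0.1
        x0 /= np.linalg.norm(x0)
        perturbed = replace(res, X=(x0,) + res.X[1:])
        r0 = residuals(example_net, scenarios["mixed"], res)
        r1 = residuals(example_net, scenarios["mixed"], perturbed)
        assert r1[0] > r0[0]


class TestSolverOptionsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"tol": 0.0},
            {"max_iter": 0},
            {"init_mode": "seeded-random"},  # missing seed
            {"update_schedule": "bogus"},
        ],
    )
    def test_invalid_options(self, kwargs):
        with pytest.raises(ValueError):
            SolverOptions(**kwargs)

    def test_non_convergence_warns(self, example_net, scenarios):
        with pytest.warns(UserWarning, match="did not converge"):
            res = interleaved_power_iteration(
                example_net, scenarios["mixed"], SolverOptions(tol=1e-15, max_iter=3)
            )
        assert not res.converged
        assert res.iterations == 3
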