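"""The AMDML optimizer: closed-form updates vs numeric oracles, eigen-solve
optimality, and the coordinate-descent loop."""

import numpy as np
import pytest
from scipy.optimize import minimize, minimize_scalar

from amdml import (
    AMDML,
    AMDMLResults,
    FitConfig,
    MultiViewDataset,
    ViewGraphs,
    objective,
    solve_H,
    trace_terms,
    update_gamma,
    update_theta,
)
from amdml.model import NumericalError, system_matrix
from conftest import manual_instance, random_labeled_dataset, synthetic_instance


def random_orthonormal(rng, D, d):
    return np.linalg.qr(rng.normal(size=(D, d)))[0]


# -- trace terms -------------------------------------------------------------


def test_trace_terms_match_pairwise_oracle(rng):
    """a_m and b_m recomputed through the explicit pairwise-sum forms."""
    ds, graphs = synthetic_instance(rng, n=12, D=5, M=2)
    H = random_orthonormal(rng, 5, 3)
    a, b = trace_terms(H, ds, graphs)
    for m, (_, X) in enumerate(ds.views):
        L_diff = graphs.L_G[m] - graphs.L_P[m]
        a_direct = np.trace(H.T @ X @ L_diff @ X.T @ H)
        # b via the pairwise form over the uniform adjacency W = 1/N^2
        n = ds.n_samples
        b_direct = 0.5 * sum(
            (1.0 / n**2) * np.sum((H.T @ (X[:, i] - X[:, j])) ** 2)
            for i in range(n)
            for j in range(n)
        )
        assert abs(a[m] - a_direct) < 1e-8
        assert abs(b[m] - b_direct) < 1e-8
        assert b[m] >= -1e-12


def test_identical_graphs_zero_fisher_term(rng):
    ds, graphs = synthetic_instance(rng, n=10, D=4, M=1)
    graphs.L_P = [g.copy() for g in graphs.L_G]
    graphs._scatter_cache = None
    H = random_orthonormal(rng, 4, 2)
    a, _ = trace_terms(H, ds, graphs)
    np.testing.assert_allclose(a, 0, atol=1e-12)


def test_constant_view_zero_structure_term(rng):
    n = 8
    labels = np.array([1] * 4 + [-1] * 4)
    X = np.tile(rng.normal(size=(4, 1)), (1, n))
    X[0, :4] += 1e-9  # avoid degenerate all-identical neighbour pools
    ds = MultiViewDataset(views=[("v", X)], labels=labels)
    graphs = ViewGraphs.build(ds, 1, 1)
    _, b = trace_terms(np.eye(4), ds, graphs)
    np.testing.assert_allclose(b, 0, atol=1e-12)


# -- solve_H -----------------------------------------------------------------


@pytest.mark.parametrize("d", [1, 2, 4])
def test_solve_H_eigen_optimality(rng, d):
    ds, graphs = synthetic_instance(rng, n=14, D=6, M=2)
    Theta = np.array([0.6, 0.4])
    gamma = 0.7
    H = solve_H(Theta, gamma, ds, graphs, d)
    np.testing.assert_allclose(H.T @ H, np.eye(d), atol=1e-8)
    A = system_matrix(Theta, gamma, ds, graphs, 2.0)
    eigvals = np.linalg.eigvalsh(A)
    assert abs(np.trace(H.T @ A @ H) - eigvals[:d].sum()) < 1e-8
    # no random orthonormal basis does better
    for _ in range(100):
        Hp = random_orthonormal(rng, 6, d)
        assert np.trace(Hp.T @ A @ Hp) >= np.trace(H.T @ A @ H) - 1e-8


def test_solve_H_sign_convention_and_d_check(rng):
    ds, graphs = synthetic_instance(rng, n=10, D=4, M=1)
    H = solve_H(np.array([1.0]), 1.0, ds, graphs, 3)
    for j in range(3):
        assert H[np.argmax(np.abs(H[:, j])), j] > 0
    with pytest.raises(ValueError, match="exceeds"):
        solve_H(np.array([1.0]), 1.0, ds, graphs, 5)


# -- update_theta ------------------------------------------------------------


def test_theta_symmetric_costs_give_uniform(rng):
    ds, graphs = manual_instance(rng, traces_a=[3.0, 3.0], trace_b=1.0)
    Theta = update_theta(np.eye(4), 1.0, ds, graphs, exponent_t=2.0)
    np.testing.assert_allclose(Theta, [0.5, 0.5], atol=1e-12)


def test_theta_closed_form_example(rng):
    """c = (1, 4) at gamma=1, t=2  ->  Theta = (0.8, 0.2)."""
    ds, graphs = manual_instance(rng, traces_a=[2.0, 5.0], trace_b=1.0)
    # with H = I: a = (2, 5), b = 1 -> c = gamma^2 a - gamma b = (1, 4)
    Theta = update_theta(np.eye(4), 1.0, ds, graphs, exponent_t=2.0)
    np.testing.assert_allclose(Theta, [0.8, 0.2], atol=1e-10)


@pytest.mark.parametrize("M, t", [(2, 2.0), (3, 2.0), (2, 3.0), (3, 1.5)])
def test_theta_matches_simplex_minimizer(rng, M, t):
    """For all-positive costs, Theta minimises sum Theta^t c on the simplex."""
    traces_a = list(rng.uniform(2.0, 8.0, size=M))
    ds, graphs = manual_instance(rng, traces_a=traces_a, trace_b=1.0, random_S=True)
    Theta = update_theta(np.eye(4), 1.0, ds, graphs, exponent_t=t)
    assert np.all(Theta >= 0) and abs(Theta.sum() - 1) < 1e-10
    a, b = trace_terms(np.eye(4), ds, graphs)
    c = a - b
    assert np.all(c > 0)
    res = minimize(
        lambda th: np.sum(th**t * c),
        np.full(M, 1.0 / M),
        method="SLSQP",
        bounds=[(0, 1)] * M,
        constraints={"type": "eq", "fun": lambda th: th.sum() - 1},
        options={"ftol": 1e-14, "maxiter": 500},
    )
    assert np.max(np.abs(Theta - res.x)) < 1e-3


def test_theta_shift_clamp_keeps_simplex(rng):
    ds, graphs = manual_instance(rng, traces_a=[-3.0, 2.0], trace_b=1.0)
    Theta = update_theta(np.eye(4), 1.0, ds, graphs, exponent_t=2.0)
    assert np.all(Theta >= 0) and abs(Theta.sum() - 1) < 1e-10
    assert Theta[0] > Theta[1]  # cheaper (more negative) view gets more weight


# -- update_gamma ------------------------------------------------------------


def test_gamma_single_view_closed_form(rng):
    """a=1, b=2, Theta=1  ->  gamma = 2 / (2*1) = 1."""
    ds, graphs = manual_instance(rng, traces_a=[1.0], trace_b=2.0)
    gamma, clamped = update_gamma(np.eye(4), np.array([1.0]), ds, graphs, 2.0)
    assert not clamped
    assert abs(gamma - 1.0) < 1e-12


def test_gamma_matches_1d_minimizer(rng):
    for _ in range(5):
        M = int(rng.integers(2, 4))
        traces_a = list(rng.uniform(1.0, 6.0, size=M))
        ds, graphs = manual_instance(
            rng, traces_a=traces_a, trace_b=float(rng.uniform(1, 5)),
            random_S=True,
        )
        Theta = rng.dirichlet(np.ones(M))
        gamma, clamped = update_gamma(np.eye(4), Theta, ds, graphs, 2.0)
        assert not clamped
        a, b = trace_terms(np.eye(4), ds, graphs)
        w = Theta**2.0
        res = minimize_scalar(
            lambda g: float(w @ (g**2 * a - g * b)),
            bounds=(1e-8, 50.0), method="bounded",
            options={"xatol": 1e-12},
        )
        assert abs(gamma - res.x) / abs(res.x) < 1e-4


def test_gamma_clamped_when_fisher_term_negative(rng):
    ds, graphs = manual_instance(rng, traces_a=[-2.0], trace_b=1.0)
    gamma, clamped = update_gamma(np.eye(4), np.array([1.0]), ds, graphs, 2.0)
    assert clamped and gamma == pytest.approx(1e-10)


def test_gamma_zero_denominator_raises(rng):
    ds, graphs = manual_instance(rng, traces_a=[0.0], trace_b=1.0)
    with pytest.raises(NumericalError, match="denominator"):
        update_gamma(np.eye(4), np.array([1.0]), ds, graphs, 2.0)


# -- objective ---------------------------------------------------------------


def test_objective_direct_substitution(rng):
    ds, graphs = manual_instance(rng, traces_a=[1.0], trace_b=2.0)
    J = objective(np.eye(4), np.array([1.0]), 1.0, ds, graphs, 2.0)
    assert abs(J - (-1.0)) < 1e-12


def test_objective_zero_weight_view_contributes_nothing(rng):
    ds, graphs = manual_instance(rng, traces_a=[1.0, 100.0], trace_b=2.0)
    J = objective(np.eye(4), np.array([1.0, 0.0]), 1.0, ds, graphs, 2.0)
    assert abs(J - (-1.0)) < 1e-12


def test_objective_matches_independent_recompute(rng):
    ds, graphs = synthetic_instance(rng, n=12, D=5, M=3)
    H = random_orthonormal(rng, 5, 2)
    Theta = rng.dirichlet(np.ones(3))
    gamma = 0.8
    J = objective(H, Theta, gamma, ds, graphs, 2.0)
    J_direct = 0.0
    for m, (_, X) in enumerate(ds.views):
        a_m = np.trace(H.T @ X @ (graphs.L_G[m] - graphs.L_P[m]) @ X.T @ H)
        b_m = np.trace(H.T @ X @ graphs.L_W @ X.T @ H)
        J_direct += Theta[m] ** 2 * (gamma**2 * a_m - gamma * b_m)
    assert abs(J - J_direct) < 1e-8


# -- fit ---------------------------------------------------------------------


def test_fit_single_view_theta_is_one(rng):
    ds = random_labeled_dataset(rng, n=16, D=6, M=1, separation=2.0)
    res = AMDML(ds, FitConfig(k1=2, k2=2, d=3)).fit()
    np.testing.assert_allclose(res.theta, [1.0], atol=1e-12)


def test_fit_duplicated_view_gives_half_half(rng):
    ds1 = random_labeled_dataset(rng, n=16, D=6, M=1, separation=2.0)
    X = ds1.views[0][1]
    ds = MultiViewDataset(
        views=[("a", X.copy()), ("b", X.copy())], labels=ds1.labels
    )
    res = AMDML(ds, FitConfig(k1=2, k2=2, d=3)).fit()
    np.testing.assert_allclose(res.theta, [0.5, 0.5], atol=1e-6)


def test_fit_exact_steps_never_increase_objective(rng):
    """Every exact block minimisation step is non-increasing in J; the fit
    terminates by the |dJ| <= delta rule within t_max."""
    for seed in range(5):
        r = np.random.default_rng(seed)
        ds, _ = synthetic_instance(r, n=20, D=6, M=2, separation=1.5)
        res = AMDML(ds, FitConfig(k1=3, k2=3, d=3)).fit()
        assert res.converged and res.n_iter <= res.config.t_max
        prev = None
        for _, _, exact, J in res.step_trace:
            if prev is not None and exact:
                assert J <= prev + 1e-8
            prev = J
        assert np.all(np.isfinite(res.objective_trace))


def test_fit_orthonormal_and_simplex_invariants(rng):
    ds, _ = synthetic_instance(rng, n=18, D=6, M=3, separation=1.0)
    res = AMDML(ds, FitConfig(k1=2, k2=2, d=4)).fit()
    np.testing.assert_allclose(res.H.T @ res.H, np.eye(4), atol=1e-8)
    assert np.all(res.theta >= 0)
    assert abs(res.theta.sum() - 1) < 1e-10


def test_fit_deterministic(rng):
    ds, _ = synthetic_instance(rng, n=16, D=6, M=2)
    cfg = FitConfig(k1=2, k2=2, d=3)
    r1 = AMDML(ds, cfg).fit()
    r2 = AMDML(ds, cfg).fit()
    assert np.array_equal(r1.theta, r2.theta)
    assert r1.gamma == r2.gamma
    np.testing.assert_array_equal(r1.H, r2.H)


def test_fit_requires_both_classes(rng):
    X = rng.normal(size=(4, 6))
    ds = MultiViewDataset(views=[("v", X)], labels=np.ones(6, dtype=int))
    with pytest.raises(ValueError, match="both classes"):
        AMDML(ds)


# -- transform ---------------------------------------------------------------


def test_transform_modes_and_distance_identity(rng):
    ds, _ = synthetic_instance(rng, n=14, D=6, M=2, separation=2.0)
    res = AMDML(ds, FitConfig(k1=2, k2=2, d=3)).fit()
    F = res.transform()
    assert F.shape == (3 * 2, 14)
    # weighted-concat distances decompose over views
    i, j = 0, 9
    direct = sum(
        res.theta[m] ** 2
        * np.sum((res.H.T @ (X[:, i] - X[:, j])) ** 2)
        for m, (_, X) in enumerate(ds.views)
    )
    assert abs(np.sum((F[:, i] - F[:, j]) ** 2) - direct) < 1e-10
    assert res.transform(mode="unweighted-concat").shape == (6, 14)
    assert res.transform(mode="weighted-mean").shape == (3, 14)
    with pytest.raises(ValueError, match="fusion"):
        res.transform(mode="bogus")


def test_transform_single_view_is_projection(rng):
    ds = random_labeled_dataset(rng, n=12, D=5, M=1, separation=2.0)
    res = AMDML(ds, FitConfig(k1=2, k2=2, d=2)).fit()
    np.testing.assert_allclose(
        res.transform(), res.H.T @ ds.views[0][1], atol=1e-12
    )


# -- serialization -----------------------------------------------------------


def test_model_round_trip(rng, tmp_path):
    ds, _ = synthetic_instance(rng, n=14, D=6, M=2, separation=2.0)
    res = AMDML(ds, FitConfig(k1=2, k2=2, d=3)).fit()
    path = tmp_path / "model.json"
    res.save(path)
    loaded = AMDMLResults.load(path)
    np.testing.assert_array_equal(loaded.H, res.H)
    np.testing.assert_array_equal(loaded.theta, res.theta)
    assert loaded.gamma == res.gamma
    assert loaded.config == res.config
    np.testing.assert_array_equal(
        loaded.transform(ds), res.transform(ds)
    )
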