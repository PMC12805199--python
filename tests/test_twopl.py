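"""Likelihood, quadrature, E-step and M-step checks against hand values
and brute-force numerical integration."""

import numpy as np
import pytest
from scipy.special import expit

from oracles import dense_grid_loglik, plain_em_2pl
from pairdif.data import ResponseData
from pairdif.penalty import PairState
from pairdif.simulate import SimulationConfig, simulate_dataset
from pairdif.twopl import (ModelParams, QuadratureGrid, build_quadrature,
                           estep_posteriors, irf, item_block_objective,
                           log_marginal_likelihood, mstep_impact,
                           _posterior_and_loglik, _posterior_counts,
                           update_items)


@pytest.mark.parametrize("theta,a,b,expected", [
    (0.0, 1.0, 0.0, 0.5),
    (0.5, 2.0, 1.0, 0.5),          # a*theta = b symmetry point
    (1.0, 1.0, 0.0, 0.7310585786300049),
])
def test_irf_values(theta, a, b, expected):
    assert irf(theta, a, b) == pytest.approx(expected, abs=1e-12)


def test_irf_monotone_in_theta():
    thetas = np.linspace(-4, 4, 50)
    p = irf(thetas, 1.3, 0.2)
    assert (np.diff(p) > 0).all() and ((p > 0) & (p < 1)).all()


def test_quadrature_symmetry_shift_and_moments():
    g0 = build_quadrature([0.0], [1.0], 21)
    np.testing.assert_allclose(g0.nodes[0] + g0.nodes[0][::-1], 0, atol=1e-12)
    assert g0.weights.sum() == pytest.approx(1.0, abs=1e-14)
    g2 = build_quadrature([2.0], [1.0], 21)
    np.testing.assert_allclose(g2.nodes[0], g0.nodes[0] + 2.0, atol=1e-12)
    # exact second moment of N(0,1)
    second = (g0.weights[0] * g0.nodes[0] ** 2).sum()
    assert second == pytest.approx(1.0, abs=1e-10)


def test_quadrature_rejects_single_node():
    with pytest.raises(ValueError):
        build_quadrature([0.0], [1.0], 1)


def test_loglik_slope_zero_exact():
    # with a = 0 the integrand is constant: loglik = log expit(-b)
    data = ResponseData(np.array([[1.0]]), np.array([0]))
    params = ModelParams([[0.0]], [[0.4]], [0.0], [1.0])
    grid = build_quadrature(params.mu, params.sigma2, 21)
    ll = log_marginal_likelihood(data, params, grid)
    assert ll == pytest.approx(np.log(expit(-0.4)), abs=1e-12)
    assert ll == pytest.approx(-0.9130152523999526, abs=1e-6)


def test_loglik_missing_entries_drop_out():
    # the marginal loglik is additive over respondents and each respondent
    # contributes only through observed items, so a missing cell behaves
    # as an empty factor in the product
    resp = np.array([[1.0, 0.0], [np.nan, 1.0]])
    data2 = ResponseData(resp, np.array([0, 0]))
    params = ModelParams([[1.2], [0.7]], [[0.3], [-0.2]], [0.0], [1.0])
    grid = build_quadrature(params.mu, params.sigma2, 31)
    ll_full = log_marginal_likelihood(data2, params, grid)
    row1 = ResponseData(np.array([[1.0, 0.0]]), np.array([0]))
    # respondent 2 only observed item 2: its contribution equals a
    # one-item dataset holding just that item's parameters
    row2 = ResponseData(np.array([[1.0]]), np.array([0]))
    params_item2 = ModelParams([[0.7]], [[-0.2]], [0.0], [1.0])
    assert ll_full == pytest.approx(
        log_marginal_likelihood(row1, params, grid)
        + log_marginal_likelihood(row2, params_item2, grid), abs=1e-10)


def test_loglik_matches_dense_grid_small_instance():
    cfg = SimulationConfig(S=2, group_sizes=[10, 10], J=5, n_dif_items=1,
                           missing_rate=0.1, seed=7)
    data = simulate_dataset(cfg).data
    rng = np.random.default_rng(1)
    params = ModelParams(rng.lognormal(0, 0.3, (5, 2)),
                         rng.normal(0, 1, (5, 2)), [0.0, 0.4], [1.0, 1.3])
    grid = build_quadrature(params.mu, params.sigma2, 49)
    ll = log_marginal_likelihood(data, params, grid)
    oracle = dense_grid_loglik(np.nan_to_num(data.responses), data.mask,
                               data.groups, params.a, params.b,
                               params.mu, params.sigma2)
    assert ll == pytest.approx(oracle, abs=1e-6)


def test_loglik_invariant_to_permutations(small_sim, rng):
    data = small_sim.data
    params = small_sim.true_params
    grid = build_quadrature(params.mu, params.sigma2, 21)
    ll = log_marginal_likelihood(data, params, grid)
    pr = rng.permutation(data.n_respondents)
    pj = rng.permutation(data.n_items)
    permuted = ResponseData(data.responses[pr][:, pj], data.groups[pr])
    params_p = ModelParams(params.a[pj], params.b[pj], params.mu, params.sigma2)
    ll_p = log_marginal_likelihood(permuted, params_p, grid)
    assert ll_p == pytest.approx(ll, abs=1e-9)


def test_estep_flat_likelihood_returns_prior():
    data = ResponseData(np.ones((3, 2)), np.array([0, 0, 0]))
    params = ModelParams(np.zeros((2, 1)), np.zeros((2, 1)), [0.0], [1.0])
    grid = build_quadrature(params.mu, params.sigma2, 15)
    post = estep_posteriors(data, params, grid)
    np.testing.assert_allclose(post, np.tile(grid.weights[0], (3, 1)),
                               atol=1e-12)


def test_estep_two_node_bayes():
    data = ResponseData(np.array([[1.0]]), np.array([0]))
    params = ModelParams([[1.0]], [[0.0]], [0.0], [1.0])
    grid = QuadratureGrid(np.array([[-1.0, 1.0]]), np.array([[0.5, 0.5]]))
    post = estep_posteriors(data, params, grid)
    np.testing.assert_allclose(post[0], [0.2689414, 0.7310586], atol=1e-6)


def test_estep_rows_sum_to_one(medium_sim):
    data = medium_sim.data
    params = medium_sim.true_params
    grid = build_quadrature(params.mu, params.sigma2, 21)
    post = estep_posteriors(data, params, grid)
    np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-10)
    assert (post >= 0).all()


def test_mstep_impact_group1_pinned_and_hand_moments():
    # group 2 has two respondents with degenerate posteriors at 0.2 and 0.4
    resp = np.array([[1.0], [0.0], [1.0], [0.0]])
    data = ResponseData(resp, np.array([0, 0, 1, 1]))
    nodes = np.array([[0.2, 0.4], [0.2, 0.4]])
    grid = QuadratureGrid(nodes, np.full((2, 2), 0.5))
    post = np.array([[0.5, 0.5], [0.5, 0.5], [1.0, 0.0], [0.0, 1.0]])
    mu, sigma2 = mstep_impact(post, grid, data)
    assert (mu[0], sigma2[0]) == (0.0, 1.0)
    assert mu[1] == pytest.approx(0.3, abs=1e-12)
    assert sigma2[1] == pytest.approx(0.01, abs=1e-12)


def test_mstep_impact_symmetric_posterior_centered_at_c():
    c = 0.7
    resp = np.array([[1.0], [0.0]])
    data = ResponseData(resp, np.array([0, 1]))
    nodes = np.array([[c - 1, c, c + 1]] * 2)
    grid = QuadratureGrid(nodes, np.full((2, 3), 1 / 3))
    post = np.full((2, 3), 1 / 3)
    mu, _ = mstep_impact(post, grid, data)
    assert mu[1] == pytest.approx(c, abs=1e-12)


def test_item_block_gradient_matches_finite_differences(medium_sim, rng):
    data = medium_sim.data
    S, J = data.n_groups, data.n_items
    params = medium_sim.true_params
    grid = build_quadrature(params.mu, params.sigma2, 15)
    post = estep_posteriors(data, params, grid)
    r1, r0 = _posterior_counts(post, data, 15)
    from pairdif.penalty import diff_matrix
    D = diff_matrix(S)
    P = D.shape[0]
    for j in (0, J - 1):
        x = rng.normal(0.5, 0.5, 2 * S)
        args = (r1[:, :, j], r0[:, :, j], grid.nodes,
                rng.normal(0, 0.3, P), rng.normal(0, 0.3, P),
                rng.normal(0, 0.1, P), rng.normal(0, 0.1, P), 50.0, D)
        val, grad = item_block_objective(x, *args)
        num = np.empty_like(grad)
        h = 1e-5
        for k in range(2 * S):
            e = np.zeros(2 * S)
            e[k] = h
            fp, _ = item_block_objective(x + e, *args)
            fm, _ = item_block_objective(x - e, *args)
            num[k] = (fp - fm) / (2 * h)
        np.testing.assert_allclose(grad, num, rtol=1e-4, atol=1e-6)


def test_update_items_descent_and_stationarity(medium_sim):
    data = medium_sim.data
    params = medium_sim.true_params.copy()
    grid = build_quadrature(params.mu, params.sigma2, 21)
    post = estep_posteriors(data, params, grid)
    pairs = PairState.zeros(data.n_items, data.n_groups)
    new = update_items(params, post, grid, pairs, 30.0, data)
    r1, r0 = _posterior_counts(post, data, 21)
    from pairdif.penalty import diff_matrix
    D = diff_matrix(data.n_groups)
    def total(p):
        t = 0.0
        for j in range(data.n_items):
            v, _ = item_block_objective(
                np.concatenate([p.a[j], p.b[j]]), r1[:, :, j], r0[:, :, j],
                grid.nodes, pairs.delta_a[j], pairs.delta_b[j],
                pairs.u_a[j], pairs.u_b[j], 30.0, D)
            t += v
        return t
    assert total(new) <= total(params) + 1e-9
    # starting at the minimizer moves (almost) nowhere
    again = update_items(new, post, grid, pairs, 30.0, data)
    assert np.abs(again.a - new.a).max() < 1e-4
    assert np.abs(again.b - new.b).max() < 1e-4


def test_single_group_mle_recovery():
    # one group, a few items (a lone item would leave the slope
    # unidentified): EM with rho=0 recovers (a=1.5, b=0.5) within 0.25
    rng = np.random.default_rng(17)
    n = 500
    true_a = np.array([1.5, 1.0, 0.8, 1.2])
    true_b = np.array([0.5, -0.3, 0.0, 0.9])
    theta = rng.normal(0, 1, n)
    y = (rng.random((n, 4)) < expit(true_a * theta[:, None] - true_b)).astype(float)
    data = ResponseData(y, np.zeros(n, dtype=int))
    a, b, mu, s2, ll = plain_em_2pl(y, np.ones_like(y, dtype=bool),
                                    np.zeros(n, dtype=int), 1, tol=1e-6)
    params = ModelParams(np.ones((4, 1)), np.zeros((4, 1)), [0.0], [1.0])
    for _ in range(500):
        grid = build_quadrature(params.mu, params.sigma2, 21)
        post, _ = _posterior_and_loglik(data, params, grid)
        new = update_items(params, post, grid, None, 0.0, data)
        moved = max(np.abs(new.a - params.a).max(), np.abs(new.b - params.b).max())
        params = new
        if moved < 1e-6:
            break
    assert abs(params.a[0, 0] - 1.5) < 0.25
    assert abs(params.b[0, 0] - 0.5) < 0.25
    # and the independent oracle lands at the same MLE
    np.testing.assert_allclose(params.a[:, 0], a[:, 0], atol=1e-3)
    np.testing.assert_allclose(params.b[:, 0], b[:, 0], atol=1e-3)


def test_em_iteration_never_decreases_loglik():
    cfg = SimulationConfig(S=2, group_sizes=[40, 40], J=5, n_dif_items=1,
                           seed=2)
    data = simulate_dataset(cfg).data
    from pairdif.solver import _neutral_start
    from pairdif.twopl import mstep_impact as mstep
    params, pairs = _neutral_start(data)
    prev = -np.inf
    for _ in range(25):
        grid = build_quadrature(params.mu, params.sigma2, 21)
        post, ll = _posterior_and_loglik(data, params, grid)
        assert ll >= prev - 1e-8
        prev = ll
        params.mu, params.sigma2 = mstep(post, grid, data)
        params = update_items(params, post, grid, pairs, 0.0, data)
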