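"""Gradients, the Beta prior, Rprop, and the fit loop."""

import numpy as np
import pytest

from conftest import central_fd, random_instance
from orn.core import compute_expr_hat, compute_path, log_likelihood
from orn.errors import ConfigError, DomainError, ShapeError
from orn.estimation import (
    FitConfig,
    RpropConfig,
    RpropState,
    apply_beta_prior,
    beta_log_density,
    fit,
    grad_mu,
    grad_zeta,
    rprop_step,
)
from orn.matrices import RelationMatrix


def penalized_objective(mut, expr, u_leak, z_leak, alpha, beta):
    """Closure over raw parameters: LL + Beta log-prior on both matrices."""

    def f(mu_raw, zeta_raw):
        u = RelationMatrix(mu_raw, leak=u_leak)
        z = RelationMatrix(zeta_raw, leak=z_leak)
        path = compute_path(mut, u)
        ll = log_likelihood(expr, compute_expr_hat(path, z))
        ll += beta_log_density(u.values, alpha, beta)
        ll += beta_log_density(z.values, alpha, beta)
        return ll

    return f


@pytest.mark.parametrize("seed", range(20))
def test_penalized_gradients_match_finite_differences(seed):
    """The backbone check: analytic grads vs central differences, 1e-5 rel."""
    rng = np.random.default_rng(seed)
    S = int(rng.integers(3, 11))
    M = int(rng.integers(2, 7))
    P = int(rng.integers(1, 5))
    G = int(rng.integers(2, 9))
    leak_u = bool(rng.integers(2))
    leak_z = bool(rng.integers(2))
    alpha, beta = (0.95, 0.95) if seed % 2 == 0 else (0.95, 0.5)
    mut, expr, u, z = random_instance(seed, S, M, P, G, leak_u, leak_z)
    obj = penalized_objective(mut, expr, leak_u, leak_z, alpha, beta)

    path = compute_path(mut, u)
    expr_hat = compute_expr_hat(path, z)
    gz = apply_beta_prior(grad_zeta(expr, expr_hat, path, z), z.values, alpha, beta)
    gm = apply_beta_prior(grad_mu(expr, expr_hat, mut, u, path, z), u.values, alpha, beta)

    fd_z = central_fd(lambda zr: obj(u.raw, zr), z.raw)
    fd_m = central_fd(lambda mr: obj(mr, z.raw), u.raw)
    np.testing.assert_allclose(gz, fd_z, rtol=1e-5, atol=1e-7)
    np.testing.assert_allclose(gm, fd_m, rtol=1e-5, atol=1e-7)


def test_gradient_zero_rows():
    """Inactive causes receive exactly zero gradient."""
    mut, expr, u, z = random_instance(1, S=6, M=4, P=3, G=5)
    mut[:, 2] = 0.0  # gene 2 never mutated
    path = compute_path(mut, u)
    path[:, 1] = 0.0  # pathway 1 never abnormal
    expr_hat = compute_expr_hat(path, z)
    gm = grad_mu(expr, expr_hat, mut, u, path, z)
    assert np.all(gm[2] == 0.0)
    gz = grad_zeta(expr, expr_hat, path, z)
    assert np.all(gz[1] == 0.0)


def test_gradient_vanishes_at_sigmoid_saturation():
    mut, expr, u, z = random_instance(2, S=6, M=4, P=2, G=5)
    z.raw[0, :] = 30.0  # Z -> 1: sigmoid factor Z(1-Z) -> ~0
    path = compute_path(mut, u)
    expr_hat = compute_expr_hat(path, z)
    gz = grad_zeta(expr, expr_hat, path, z)
    # orders of magnitude below the unsaturated rows
    assert np.all(np.abs(gz[0]) < 1e-4)
    assert np.abs(gz[0]).max() < 1e-3 * np.abs(gz[1:]).max()


def test_saturated_or_blocks_mu_gradient():
    """A pathway forced on by a weight-1 edge gives (1 - Path) = 0 factors."""
    mut = np.array([[1.0, 1.0]])
    expr = np.array([[1.0]])
    u = RelationMatrix.from_values(np.array([[1 - 1e-16], [0.5]]))
    z = RelationMatrix.from_values(np.array([[0.5]]))
    path = compute_path(mut, u)
    assert path[0, 0] == pytest.approx(1.0)
    gm = grad_mu(expr, compute_expr_hat(path, z), mut, u, path, z)
    assert np.all(np.abs(gm) < 1e-6)


def test_beta_prior_identity_and_symmetry():
    grad = np.array([[0.3, -0.2]])
    v = np.array([[0.5, 0.5]])
    np.testing.assert_array_equal(apply_beta_prior(grad, v, 1.0, 1.0), grad)
    # alpha == beta at v = 0.5: the two terms cancel exactly
    np.testing.assert_array_equal(apply_beta_prior(grad, v, 0.95, 0.95), grad)
    with pytest.raises(DomainError):
        apply_beta_prior(grad, np.array([[0.0, 0.5]]), 0.95, 0.95)


def test_rprop_step_rules():
    cfg = RpropConfig(delta0=0.1)
    raw = np.zeros((2, 2))
    state = RpropState.fresh(raw.shape, cfg.delta0)

    out, st = rprop_step(raw, np.zeros_like(raw), state, cfg)
    np.testing.assert_array_equal(out, raw)
    np.testing.assert_array_equal(st.step, state.step)

    grad = np.array([[1.0, -2.0], [0.5, 0.0]])
    out, st = rprop_step(raw, grad, state, cfg)
    np.testing.assert_array_equal(out, 0.1 * np.sign(grad))

    # same sign again: step grows by eta_plus
    out2, st2 = rprop_step(out, grad, st, cfg)
    np.testing.assert_allclose(
        np.abs(out2 - out)[grad != 0], 0.1 * cfg.eta_plus
    )
    # sign flip: step shrinks, parameter holds, gradient memory zeroed
    out3, st3 = rprop_step(out2, -grad, st2, cfg)
    np.testing.assert_array_equal(out3, out2)
    np.testing.assert_allclose(st3.step[grad != 0], 0.1 * cfg.eta_plus * cfg.eta_minus)
    assert np.all(st3.prev_grad[grad != 0] == 0.0)


def test_fit_improves_penalized_likelihood_and_is_deterministic(small_truth):
    cfg = FitConfig(n_pathways=3, seed=11, max_iter=120, n_restarts=1)
    res = fit(small_truth.mut, small_truth.expr, cfg)
    assert res.ll_trace[-1] >= res.ll_trace[0]
    assert res.iterations_run == len(res.ll_trace)
    # PAS is recomputable from (mut, U) bit-identically
    np.testing.assert_array_equal(res.path, compute_path(small_truth.mut, res.u))
    res2 = fit(small_truth.mut, small_truth.expr, cfg)
    np.testing.assert_array_equal(res.u.raw, res2.u.raw)
    np.testing.assert_array_equal(res.z.raw, res2.z.raw)
    assert res.ll_trace == res2.ll_trace


def test_fit_with_nothing_to_explain_drives_z_to_zero(small_truth):
    expr0 = np.zeros_like(small_truth.expr.values)
    cfg = FitConfig(
        n_pathways=2, seed=3, max_iter=150, leak_sga=False, leak_deg=False, n_restarts=1
    )
    res = fit(small_truth.mut.values, expr0, cfg)
    assert res.z.values.mean() < 0.05


def test_fit_permutation_equivalence(small_truth):
    """Permuting the initialization's pathway axis permutes the fit."""
    cfg = FitConfig(n_pathways=3, seed=5, max_iter=60, n_restarts=1, tol=0.0)
    rng = np.random.default_rng(9)
    mu0 = rng.normal(-2.0, 0.5, (small_truth.mut.n_genes + 1, 3))
    zeta0 = rng.normal(-2.0, 0.5, (4, small_truth.expr.n_genes))
    perm = np.array([2, 0, 1])
    res = fit(small_truth.mut, small_truth.expr, cfg, init=(mu0, zeta0))
    zeta0_p = zeta0.copy()
    zeta0_p[:3] = zeta0[perm]
    res_p = fit(small_truth.mut, small_truth.expr, cfg, init=(mu0[:, perm], zeta0_p))
    np.testing.assert_array_equal(
        res_p.u.values > 0.5, (res.u.values > 0.5)[:, perm]
    )
    np.testing.assert_array_equal(
        res_p.z.values[:3] > 0.5, (res.z.values > 0.5)[perm]
    )


def test_fit_config_validation_and_warnings(small_truth):
    with pytest.raises(ConfigError):
        FitConfig(n_pathways=0)
    with pytest.raises(ConfigError):
        FitConfig(n_pathways=2, alpha=-1.0)
    with pytest.raises(ConfigError):
        RpropConfig(eta_plus=0.9)
    with pytest.raises(ShapeError):
        fit(np.zeros((0, 3)), np.zeros((0, 2)), FitConfig(n_pathways=1))
    with pytest.warns(UserWarning, match="n_pathways"):
        fit(
            small_truth.mut.values[:5, :4],
            small_truth.expr.values[:5, :6],
            FitConfig(n_pathways=4, max_iter=2, n_restarts=1),
        )
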