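"""The OR-gate primitive and the two-layer forward model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import loop_log_likelihood, loop_or_gate, loop_path
from orn.core import EPS, compute_expr_hat, compute_path, log_likelihood, or_gate
from orn.errors import DomainError, ShapeError
from orn.matrices import RelationMatrix

unit = st.floats(0.0, 1.0, allow_nan=False)
vecs = st.integers(1, 6).flatmap(
    lambda n: st.tuples(st.lists(unit, min_size=n, max_size=n), st.lists(unit, min_size=n, max_size=n))
)


@pytest.mark.parametrize(
    "x, delta, leak, expected",
    [
        ([0, 0, 0], [0.9, 0.1, 0.5], 0.0, 0.0),
        ([1, 1], [0.5, 0.5], 0.0, 0.75),
        ([1], [0.3], 0.2, 0.44),
        ([], [], 0.3, 0.3),
    ],
)
def test_or_gate_known_values(x, delta, leak, expected):
    assert or_gate(x, delta, leak) == pytest.approx(expected, abs=1e-12)


def test_or_gate_rejects_out_of_range_naming_index():
    with pytest.raises(DomainError, match=r"x\[1\]"):
        or_gate([0.5, 1.5], [0.5, 0.5])
    with pytest.raises(DomainError, match="delta"):
        or_gate([0.5], [-0.1])
    with pytest.raises(DomainError, match="leak"):
        or_gate([0.5], [0.5], leak=2.0)


@settings(derandomize=True, max_examples=80, deadline=None)
@given(vecs, unit)
def test_or_gate_matches_loop_oracle_and_complement(xd, leak):
    x, delta = xd
    got = or_gate(x, delta, leak)
    assert got == pytest.approx(loop_or_gate(x, delta, leak), abs=1e-12)
    # complement identity at zero leak
    assert 1 - or_gate(x, delta, 0.0) == pytest.approx(
        float(np.prod(1 - np.array(x) * np.array(delta))), abs=1e-12
    )


@settings(derandomize=True, max_examples=60, deadline=None)
@given(vecs, st.integers(0, 5), st.floats(0.0, 1.0))
def test_or_gate_monotone_in_each_argument(xd, idx, bump):
    x, delta = xd
    base = or_gate(x, delta)
    i = idx % len(x)
    x2 = list(x)
    x2[i] = min(1.0, x2[i] + bump)
    assert or_gate(x2, delta) >= base - 1e-12
    d2 = list(delta)
    d2[i] = min(1.0, d2[i] + bump)
    assert or_gate(x, d2) >= base - 1e-12


@pytest.mark.parametrize("leak", [False, True])
def test_compute_path_matches_double_loop(leak):
    rng = np.random.default_rng(3)
    mut = (rng.random((4, 3)) < 0.5).astype(float)
    u = RelationMatrix(rng.normal(0, 1, (3 + leak, 2)), leak=leak)
    expected = loop_path(mut, u.values, leak)
    np.testing.assert_array_equal(compute_path(mut, u), expected)


def test_compute_path_leak_only_and_sufficient_cause():
    mut = np.zeros((3, 2))
    u = RelationMatrix.from_values(
        np.array([[0.4], [0.2], [0.7]]), leak=True, cause_ids=["a", "b", "__leak__"]
    )
    np.testing.assert_allclose(compute_path(mut, u), 0.7)
    # a single mutation with edge weight 1 forces the pathway on
    mut2 = np.array([[1.0, 0.0]])
    u2 = np.array([[1.0], [0.0]])
    assert compute_path(mut2, u2)[0, 0] == 1.0


def test_compute_expr_hat_matches_double_loop_and_clips():
    rng = np.random.default_rng(4)
    path = rng.random((5, 3))
    z = RelationMatrix(rng.normal(0, 1, (4, 6)), leak=True)
    expected = loop_path(path, z.values, True)  # same OR algebra, PAS as cause
    np.testing.assert_allclose(compute_expr_hat(path, z), np.clip(expected, EPS, 1 - EPS), atol=1e-15)
    # all-zero path with zero leak clips to EPS; saturated cause clips to 1-EPS
    z0 = np.full((3, 2), 1e-12)
    assert np.all(compute_expr_hat(np.zeros((2, 3)), z0) == EPS)
    assert compute_expr_hat(np.ones((1, 1)), np.ones((1, 1)) - 1e-16)[0, 0] == 1 - EPS


def test_forward_model_commutes_with_sample_permutation():
    rng = np.random.default_rng(5)
    mut = (rng.random((6, 4)) < 0.5).astype(float)
    u = RelationMatrix(rng.normal(0, 1, (5, 3)), leak=True)
    z = RelationMatrix(rng.normal(0, 1, (4, 7)), leak=True)
    perm = rng.permutation(6)
    path = compute_path(mut, u)
    np.testing.assert_array_equal(compute_path(mut[perm], u), path[perm])
    np.testing.assert_array_equal(
        compute_expr_hat(path[perm], z), compute_expr_hat(path, z)[perm]
    )


def test_binary_inputs_give_exactly_binary_outputs():
    """The generative case: binary U, Z, Mut and zero leak stay boolean."""
    rng = np.random.default_rng(6)
    mut = (rng.random((10, 8)) < 0.3).astype(float)
    u = (rng.random((8, 3)) < 0.3).astype(float)
    z = (rng.random((3, 9)) < 0.4).astype(float)
    path = compute_path(mut, u)
    assert set(np.unique(path)) <= {0.0, 1.0}
    expr_hat = compute_expr_hat(path, z, clip=False)
    assert set(np.unique(expr_hat)) <= {0.0, 1.0}


def test_log_likelihood_matches_loop_oracle():
    rng = np.random.default_rng(7)
    expr = (rng.random((6, 7)) < 0.5).astype(float)
    expr_hat = rng.uniform(0.01, 0.99, (6, 7))
    got = log_likelihood(expr, expr_hat)
    want = loop_log_likelihood(expr, expr_hat)
    assert got == pytest.approx(want, rel=1e-12)
    assert got <= 0.0


def test_log_likelihood_extremes_and_maximum():
    assert log_likelihood(np.array([[1.0]]), np.array([[0.5]])) == pytest.approx(
        np.log(0.5)
    )
    expr = np.array([[1.0, 0.0]])
    # perfectly confident correct prediction is ~0 (clip bound)
    perfect = log_likelihood(expr, expr)
    assert perfect == pytest.approx(2 * np.log(1 - EPS), abs=1e-12)
    # perturbing any cell away from the observation decreases the LL
    for s, g, d in [(0, 0, -0.2), (0, 1, 0.2)]:
        worse = expr.astype(float).copy()
        worse[s, g] += d
        assert log_likelihood(expr, worse) < perfect


def test_shape_errors():
    with pytest.raises(ShapeError):
        compute_path(np.zeros((2, 3)), np.zeros((4, 2)))
    with pytest.raises(ShapeError):
        log_likelihood(np.zeros((2, 2)), np.zeros((2, 3)))
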