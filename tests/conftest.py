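"""Shared fixtures and independent oracles.

The oracles here are deliberately naive (explicit Python loops over
scalars) so they stay independent of the vectorized implementations they
check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from orn.matrices import RelationMatrix


def loop_or_gate(x, delta, leak=0.0) -> float:
    """Scalar OR-gate by explicit iteration."""
    prod = 1.0 - leak
    for xi, di in zip(x, delta):
        prod *= 1.0 - xi * di
    return 1.0 - prod


def loop_path(mut, u_vals, leak: bool) -> np.ndarray:
    """Double-loop PAS computation against which compute_path is checked."""
    S = mut.shape[0]
    P = u_vals.shape[1]
    out = np.zeros((S, P))
    for s in range(S):
        row = list(mut[s]) + ([1.0] if leak else [])
        for p in range(P):
            out[s, p] = loop_or_gate(row, u_vals[:, p])
    return out


def loop_log_likelihood(expr, expr_hat) -> float:
    total = 0.0
    for s in range(expr.shape[0]):
        for g in range(expr.shape[1]):
            h = min(max(expr_hat[s, g], 1e-10), 1 - 1e-10)
            total += expr[s, g] * math.log(h) + (1 - expr[s, g]) * math.log(1 - h)
    return total


def random_instance(seed, S=8, M=4, P=3, G=5, leak_u=True, leak_z=True):
    """A small random (mut, expr, u, z) quadruple for gradient checks."""
    rng = np.random.default_rng(seed)
    mut = (rng.random((S, M)) < 0.4).astype(float)
    expr = (rng.random((S, G)) < 0.3).astype(float)
    u = RelationMatrix(rng.normal(-1.5, 0.8, (M + leak_u, P)), leak=leak_u)
    z = RelationMatrix(rng.normal(-1.5, 0.8, (P + leak_z, G)), leak=leak_z)
    return mut, expr, u, z


def central_fd(f, raw: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of a scalar function of a raw matrix."""
    out = np.zeros_like(raw)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            plus = raw.copy()
            plus[i, j] += eps
            minus = raw.copy()
            minus[i, j] -= eps
            out[i, j] = (f(plus) - f(minus)) / (2 * eps)
    return out


@pytest.fixture
def small_truth():
    """A small pruned synthetic dataset with planted relation matrices."""
    from orn.simulate import SimConfig, generate

    return generate(
        SimConfig(
            n_samples=60,
            n_sga=30,
            n_deg=40,
            n_pathways=3,
            mut_density=0.1,
            u_density=0.12,
            z_density=0.15,
            seed=7,
        )
    )
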