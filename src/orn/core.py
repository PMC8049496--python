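"""The probabilistic OR-gate and the two-layer forward model.

An OR-gate combines independent sufficient causes: if cause ``i`` is active
with probability ``x_i`` and, when active, produces the effect with
probability ``delta_i``, the effect fires with probability

    OR(x, delta) = 1 - (1 - leak) * prod_i (1 - x_i * delta_i)

The network stacks two such layers: somatic events drive latent pathway
abnormality status (PAS), and PAS drives differential expression:

    Path[s, p]     = OR(Mut[s, :],  U[:, p])
    ExprHat[s, g]  = OR(Path[s, :], Z[:, g])

so a single sufficiently-linked mutation can flip a pathway, and a single
abnormal pathway can flip each gene of its regulon — the logical structure
behind mutual exclusivity of driver mutations.
"""

from __future__ import annotations

import numpy as np

from .errors import DomainError, ShapeError
from .matrices import RelationMatrix

__all__ = [
    "EPS",
    "or_gate",
    "or_reduce",
    "compute_path",
    "compute_expr_hat",
    "log_likelihood",
]

#: Clipping bound keeping predicted probabilities away from {0, 1} before logs.
EPS = 1e-10


def _check_unit_interval(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    bad = (arr < 0) | (arr > 1) | ~np.isfinite(arr)
    if bad.any():
        idx = tuple(int(i) for i in np.argwhere(bad)[0])
        raise DomainError(
            f"{name}{list(idx)} = {arr[idx]!r} lies outside [0, 1]"
        )
    return arr


def or_gate(x, delta, leak: float = 0.0) -> float:
    """Scalar probabilistic OR-gate over one cause vector.

    Parameters
    ----------
    x : array-like in [0, 1]
        Activation probabilities of the causes.
    delta : array-like in [0, 1]
        Per-cause probabilities of being sufficient for the effect.
    leak : float in [0, 1]
        Probability contributed by an always-active unmodeled cause.

    Returns
    -------
    float
        ``1 - (1 - leak) * prod_i (1 - x_i * delta_i)``; monotone
        non-decreasing in every argument.
    """
    x = _check_unit_interval(np.atleast_1d(x), "x")
    delta = _check_unit_interval(np.atleast_1d(delta), "delta")
    if x.shape != delta.shape:
        raise ShapeError(f"x {x.shape} and delta {delta.shape} differ in length")
    leak_arr = _check_unit_interval(np.atleast_1d(leak), "leak")
    return float(1.0 - (1.0 - leak_arr[0]) * np.prod(1.0 - x * delta))


def or_reduce(x: np.ndarray, w: np.ndarray, chunk: int = 128) -> np.ndarray:
    """Vectorized OR-gate: ``out[s, k] = 1 - prod_n (1 - x[s, n] * w[n, k])``.

    Exact for binary inputs (0/1 weights give exactly 0/1 outputs). The
    product is accumulated over cause chunks to bound peak memory.
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    if x.ndim != 2 or w.ndim != 2 or x.shape[1] != w.shape[0]:
        raise ShapeError(
            f"cause axis mismatch: x is {x.shape}, w is {w.shape}"
        )
    surv = np.ones((x.shape[0], w.shape[1]))
    for lo in range(0, w.shape[0], chunk):
        hi = min(lo + chunk, w.shape[0])
        surv *= np.prod(1.0 - x[:, lo:hi, None] * w[None, lo:hi, :], axis=1)
    return 1.0 - surv


def _as_cause_matrix(w, n_causes: int, name: str):
    """Return (weight array incl. leak row if any, has_leak) for `w`."""
    if isinstance(w, RelationMatrix):
        vals, leak = w.values, w.leak
    else:
        vals = _check_unit_interval(np.asarray(w, dtype=float), name)
        leak = False
    expected = n_causes + (1 if leak else 0)
    if vals.shape[0] != expected:
        raise ShapeError(
            f"{name} has {vals.shape[0]} cause rows; expected {expected} "
            f"for {n_causes} causes" + (" plus leak" if leak else "")
        )
    return vals, leak


def _augment(x: np.ndarray, leak: bool) -> np.ndarray:
    if not leak:
        return x
    ones = np.ones((x.shape[0], 1))
    return np.concatenate([np.asarray(x, dtype=float), ones], axis=1)


def compute_path(mut, u) -> np.ndarray:
    """Pathway abnormality probabilities: ``Path[s, p] = OR(Mut[s, :], U[:, p])``.

    ``mut`` may be an :class:`EventMatrix` or a binary array; ``u`` a
    :class:`RelationMatrix` (its leak row, if present, acts as an
    always-active pseudo-mutation) or a plain probability array with one
    row per gene.
    """
    mut_vals = np.asarray(getattr(mut, "values", mut), dtype=float)
    if mut_vals.ndim != 2:
        raise ShapeError(f"mut must be 2-D, got shape {mut_vals.shape}")
    u_vals, leak = _as_cause_matrix(u, mut_vals.shape[1], "u")
    return or_reduce(_augment(mut_vals, leak), u_vals)


def compute_expr_hat(path, z, clip: bool = True) -> np.ndarray:
    """Predicted DEG probabilities: ``ExprHat[s, g] = OR(Path[s, :], Z[:, g])``.

    With ``clip`` (default) the result is pushed into ``[EPS, 1 - EPS]`` so
    the Bernoulli likelihood never evaluates ``log(0)``.
    """
    path_vals = _check_unit_interval(
        np.asarray(getattr(path, "values", path), dtype=float), "path"
    )
    if path_vals.ndim != 2:
        raise ShapeError(f"path must be 2-D, got shape {path_vals.shape}")
    z_vals, leak = _as_cause_matrix(z, path_vals.shape[1], "z")
    out = or_reduce(_augment(path_vals, leak), z_vals)
    if clip:
        np.clip(out, EPS, 1.0 - EPS, out=out)
    return out


def log_likelihood(expr, expr_hat) -> float:
    """Bernoulli log-likelihood of observed DEG calls under the prediction.

    ``sum_{s,g} [ Expr * log(ExprHat) + (1 - Expr) * log(1 - ExprHat) ]``;
    always <= 0.
    """
    e = np.asarray(getattr(expr, "values", expr), dtype=float)
    h = np.asarray(getattr(expr_hat, "values", expr_hat), dtype=float)
    if e.shape != h.shape:
        raise ShapeError(f"expr {e.shape} and expr_hat {h.shape} differ")
    h = np.clip(h, EPS, 1.0 - EPS)
    return float(np.sum(e * np.log(h) + (1.0 - e) * np.log1p(-h)))
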