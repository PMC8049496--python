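"""Scoring fitted models against planted truth and a neural-net baseline.

The recovery metric is the *Jaccard score*: for each true pathway, the
best-match Jaccard similarity of its upstream (U) column over all fitted
columns and of its downstream (Z) row over all fitted rows; the score is
the mean over true pathways of the product of the two similarities. Taking
the max over fitted indices makes the score invariant to pathway
relabeling, which is unidentifiable by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import EPS, compute_expr_hat
from .errors import ConfigError, ShapeError
from .estimation import FitConfig, RpropConfig, RpropState, fit, rprop_step
from .matrices import RelationMatrix
from .simulate import SimConfig, generate

__all__ = [
    "reconstruction_error",
    "jaccard_similarity",
    "cosine_similarity",
    "jaccard_score",
    "nn_baseline",
    "NNBaselineResult",
    "run_benchmark",
]


def reconstruction_error(expr, expr_hat) -> float:
    """Mean absolute difference between observed and predicted DEG matrices."""
    e = np.asarray(getattr(expr, "values", expr), dtype=float)
    h = np.asarray(getattr(expr_hat, "values", expr_hat), dtype=float)
    if e.shape != h.shape:
        raise ShapeError(f"expr {e.shape} and expr_hat {h.shape} differ")
    return float(np.mean(np.abs(h - e)))


def jaccard_similarity(a, b) -> float:
    """Soft Jaccard: ``sum(a*b) / sum(a + b - a*b)``.

    Coincides with set Jaccard ``|A & B| / |A | B|`` on binary vectors.
    Two all-zero vectors have an empty union; defined as 0 with a warning.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ShapeError(f"length mismatch: {a.shape} vs {b.shape}")
    denom = float(np.sum(a + b - a * b))
    if denom == 0.0:
        warnings.warn("Jaccard of two all-zero vectors; returning 0", stacklevel=2)
        return 0.0
    return float(np.sum(a * b) / denom)


def cosine_similarity(a, b) -> float:
    """Cosine of the angle between two non-negative vectors (0 if either is 0)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(a @ b / (na * nb))


def _fitted_array(x, drop_leak_row: bool) -> np.ndarray:
    if isinstance(x, RelationMatrix):
        return x.real_values() if drop_leak_row else x.values
    return np.asarray(x, dtype=float)


def jaccard_score(
    u_star,
    z_star,
    u_hat,
    z_hat,
    binarize_cutoff: float | None = 0.5,
    metric: str = "jaccard",
    return_per_pathway: bool = False,
):
    """Best-match recovery score of fitted (U, Z) against binary truth.

    Fitted matrices are binarized at ``binarize_cutoff`` before scoring
    (pass ``None`` for the soft variant). Leak rows of fitted
    :class:`RelationMatrix` objects are dropped before comparison.
    """
    us = np.asarray(u_star, dtype=float)
    zs = np.asarray(z_star, dtype=float)
    uh = _fitted_array(u_hat, drop_leak_row=True)
    zh = _fitted_array(z_hat, drop_leak_row=True)
    P = us.shape[1]
    if zs.shape[0] != P:
        raise ShapeError("u_star columns and z_star rows disagree on P")
    if uh.shape[1] != P or zh.shape[0] != P:
        raise ShapeError(
            f"fitted matrices have {uh.shape[1]} / {zh.shape[0]} pathways, "
            f"truth has {P}"
        )
    if uh.shape[0] != us.shape[0] or zh.shape[1] != zs.shape[1]:
        raise ShapeError("gene axes of truth and fit disagree")
    if binarize_cutoff is not None:
        uh = (uh > binarize_cutoff).astype(float)
        zh = (zh > binarize_cutoff).astype(float)
    simfun = {"jaccard": jaccard_similarity, "cosine": cosine_similarity}.get(metric)
    if simfun is None:
        raise ConfigError(f"metric must be 'jaccard' or 'cosine', got {metric!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-zero columns score 0 silently here
        sim_u = np.array(
            [max(simfun(us[:, p], uh[:, q]) for q in range(P)) for p in range(P)]
        )
        sim_z = np.array(
            [max(simfun(zs[p], zh[q]) for q in range(P)) for p in range(P)]
        )
    score = float(np.mean(sim_u * sim_z))
    if return_per_pathway:
        return score, sim_u, sim_z
    return score


# ------------------------------------------------------------- NN baseline


@dataclass
class NNBaselineResult:
    """A trained one-hidden-layer sigmoid network and its evaluation."""

    reconstruction_error: float
    input_to_hidden: np.ndarray  # M x H, min-max normalized to [0, 1] per unit
    hidden_to_output: np.ndarray  # H x G, min-max normalized to [0, 1] per unit
    expr_hat: np.ndarray
    ll_trace: list[float]


def _unit_normalize(w: np.ndarray, axis: int) -> np.ndarray:
    """Min-max map each hidden unit's weight vector into [0, 1]."""
    lo = w.min(axis=axis, keepdims=True)
    hi = w.max(axis=axis, keepdims=True)
    span = np.where(hi > lo, hi - lo, 1.0)
    return (w - lo) / span


def nn_baseline(
    mut,
    expr,
    n_hidden: int,
    seed: int = 0,
    max_iter: int = 500,
    rprop: RpropConfig = RpropConfig(),
) -> NNBaselineResult:
    """Train a one-hidden-layer sigmoid network mapping Mut to Expr.

    The comparison network: sigmoid activations throughout (so hidden
    units live in [0, 1] like pathway probabilities), the same Bernoulli
    log-likelihood objective, and the same Rprop optimizer as the OR-gate
    model — only the combination rule (weighted sum vs OR) differs.
    Weight matrices are returned min-max normalized per hidden unit so
    they can be scored against binary truth like relation matrices.
    """
    if n_hidden < 1:
        raise ConfigError(f"n_hidden must be >= 1, got {n_hidden}")
    X = np.asarray(getattr(mut, "values", mut), dtype=float)
    Y = np.asarray(getattr(expr, "values", expr), dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ShapeError("mut and expr must have the same samples")
    S, M = X.shape
    G = Y.shape[1]
    rng = np.random.default_rng(seed)
    params = {
        "W1": rng.normal(0.0, 0.1, (M, n_hidden)),
        "b1": np.zeros(n_hidden),
        "W2": rng.normal(0.0, 0.1, (n_hidden, G)),
        "b2": np.zeros(G),
    }
    states = {k: RpropState.fresh(v.shape, rprop.delta0) for k, v in params.items()}
    trace: list[float] = []
    from scipy.special import expit

    for _ in range(max_iter):
        H = expit(X @ params["W1"] + params["b1"])
        Yhat = expit(H @ params["W2"] + params["b2"])
        Yc = np.clip(Yhat, EPS, 1.0 - EPS)
        trace.append(float(np.sum(Y * np.log(Yc) + (1.0 - Y) * np.log1p(-Yc))))
        d2 = Y - Yhat  # dLL/dlogits of the output layer
        grads = {
            "W2": H.T @ d2,
            "b2": d2.sum(axis=0),
        }
        dH = (d2 @ params["W2"].T) * H * (1.0 - H)
        grads["W1"] = X.T @ dH
        grads["b1"] = dH.sum(axis=0)
        for k in params:
            params[k], states[k] = rprop_step(params[k], grads[k], states[k], rprop)
    H = expit(X @ params["W1"] + params["b1"])
    Yhat = expit(H @ params["W2"] + params["b2"])
    return NNBaselineResult(
        reconstruction_error=reconstruction_error(Y, Yhat),
        input_to_hidden=_unit_normalize(params["W1"], axis=0),
        hidden_to_output=_unit_normalize(params["W2"], axis=1),
        expr_hat=Yhat,
        ll_trace=trace,
    )


# --------------------------------------------------------------- benchmark


def run_benchmark(
    settings: dict[str, SimConfig],
    n_replicates: int = 3,
    base_seed: int = 0,
    fit_config: FitConfig | None = None,
) -> pd.DataFrame:
    """Generate -> fit -> score over a grid of simulation settings.

    Returns a tidy table with one row per (setting, replicate):
    columns setting, replicate, seed, reconstruction_error, jaccard_score.
    """
    rows = []
    for si, (name, sim_cfg) in enumerate(settings.items()):
        for r in range(n_replicates):
            seed = base_seed + 1009 * si + r
            truth = generate(replace(sim_cfg, seed=seed))
            cfg = fit_config or FitConfig(n_pathways=sim_cfg.n_pathways)
            cfg = replace(cfg, n_pathways=sim_cfg.n_pathways, seed=seed + 1)
            res = fit(truth.mut, truth.expr, cfg)
            expr_hat = compute_expr_hat(res.path, res.z)
            rows.append(
                {
                    "setting": name,
                    "replicate": r,
                    "seed": seed,
                    "reconstruction_error": reconstruction_error(truth.expr, expr_hat),
                    "jaccard_score": jaccard_score(truth.u_star, truth.z_star, res.u, res.z),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["setting", "replicate", "seed", "reconstruction_error", "jaccard_score"],
    )
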