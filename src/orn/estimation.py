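"""MAP estimation of the OR-gate network by Rprop.

The relation matrices are reparameterized through an element-wise sigmoid,
``U = sigmoid(mu)`` and ``Z = sigmoid(zeta)``, so the optimizer works on
unconstrained reals. The objective is the Bernoulli log-likelihood of the
observed DEG matrix plus the log-density of a Beta(alpha, beta) prior on
each relation probability; with alpha = beta = 0.95 the prior is weakly
bimodal and pushes entries away from the uninformative middle.

Gradients are derived analytically from the likelihood and the OR-gate
(chain rule through both layers and the sigmoid) and are verified against
central finite differences in the test suite. Optimization uses iRprop-,
a sign-based scheme with per-parameter adaptive step sizes: steps grow
geometrically while the gradient sign is stable and shrink when it flips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, logit

from .core import EPS, compute_path
from .errors import ConfigError, DomainError, ShapeError
from .matrices import LEAK_ID, RAW_BOUND, RelationMatrix

__all__ = [
    "RpropConfig",
    "FitConfig",
    "RpropState",
    "FitResult",
    "grad_zeta",
    "grad_mu",
    "apply_beta_prior",
    "beta_log_density",
    "rprop_step",
    "fit",
]


@dataclass(frozen=True)
class RpropConfig:
    """iRprop- hyperparameters.

    ``delta_max`` is kept small because parameters live on a logit scale,
    where a unit step already moves a probability substantially.
    """

    eta_plus: float = 1.2
    eta_minus: float = 0.5
    delta0: float = 0.01
    delta_min: float = 1e-6
    delta_max: float = 1.0

    def __post_init__(self) -> None:
        if not (self.eta_plus > 1.0 > self.eta_minus > 0.0):
            raise ConfigError(
                f"need eta_plus > 1 > eta_minus > 0; got "
                f"{self.eta_plus}, {self.eta_minus}"
            )
        if not (0 < self.delta_min <= self.delta0 <= self.delta_max):
            raise ConfigError("need 0 < delta_min <= delta0 <= delta_max")


@dataclass(frozen=True)
class FitConfig:
    """Configuration of a single model fit.

    Parameters
    ----------
    n_pathways : int
        Number of latent pathway modules P.
    alpha, beta : float
        Beta-prior hyperparameters (default 0.95 each).
    max_iter : int
        Maximum number of full-batch Rprop iterations.
    tol : float
        Relative change of the penalized log-likelihood over a
        ``tol_window``-iteration window below which the fit stops early.
    leak_sga, leak_deg : bool
        Whether each layer carries an always-active leak pseudo-cause.
    prior_on : {"both", "z"}
        Apply the Beta prior to both relation matrices or only to Z.
    prior_gradient : {"derived", "printed"}
        Sign convention of the prior gradient term; "derived" is the MAP
        gradient of the Beta log-density, verified by finite differences.
    init_mean_prob, init_sd : float
        Raw parameters start at Normal(logit(init_mean_prob), init_sd);
        small initial probabilities avoid a saturated-OR regime where
        gradients vanish.
    n_restarts : int
        Number of independently initialized optimization runs; the run
        with the highest final penalized log-likelihood is returned. The
        objective is multimodal (latent pathways can merge or starve), and
        restart selection on the model's own objective resolves this
        without reference to any ground truth.
    """

    n_pathways: int
    alpha: float = 0.95
    beta: float = 0.95
    max_iter: int = 500
    tol: float = 1e-6
    tol_window: int = 10
    rprop: RpropConfig = field(default_factory=RpropConfig)
    seed: int = 0
    leak_sga: bool = True
    leak_deg: bool = True
    prior_on: str = "both"
    prior_gradient: str = "derived"
    init_mean_prob: float = 0.1
    init_sd: float = 0.5
    n_restarts: int = 5

    def __post_init__(self) -> None:
        if self.n_restarts < 1:
            raise ConfigError(f"n_restarts must be >= 1, got {self.n_restarts}")
        if self.n_pathways < 1:
            raise ConfigError(f"n_pathways must be >= 1, got {self.n_pathways}")
        if self.alpha <= 0 or self.beta <= 0:
            raise ConfigError("alpha and beta must be positive")
        if self.max_iter < 1:
            raise ConfigError("max_iter must be >= 1")
        if self.tol < 0:
            raise ConfigError("tol must be non-negative")
        if self.prior_on not in ("both", "z"):
            raise ConfigError(f"prior_on must be 'both' or 'z', got {self.prior_on!r}")
        if self.prior_gradient not in ("derived", "printed"):
            raise ConfigError("prior_gradient must be 'derived' or 'printed'")


@dataclass
class RpropState:
    """Per-parameter step sizes and previous gradients for one matrix."""

    step: np.ndarray
    prev_grad: np.ndarray

    @classmethod
    def fresh(cls, shape: tuple[int, ...], delta0: float) -> "RpropState":
        return cls(np.full(shape, delta0), np.zeros(shape))


@dataclass
class FitResult:
    u: RelationMatrix
    z: RelationMatrix
    path: np.ndarray
    ll_trace: list[float]
    converged: bool
    iterations_run: int


# ---------------------------------------------------------------- gradients


def _values_arr(x) -> np.ndarray:
    return np.asarray(getattr(x, "values", x), dtype=float)


def _leak_of(x) -> bool:
    return bool(getattr(x, "leak", False))


def _augment_ones(x: np.ndarray, leak: bool) -> np.ndarray:
    if not leak:
        return np.asarray(x, dtype=float)
    return np.concatenate([np.asarray(x, dtype=float), np.ones((x.shape[0], 1))], axis=1)


def _dll_dhat(expr: np.ndarray, expr_hat: np.ndarray) -> np.ndarray:
    h = np.clip(expr_hat, EPS, 1.0 - EPS)
    return expr / h - (1.0 - expr) / (1.0 - h)


def _expr_backward(
    E: np.ndarray, path_aug: np.ndarray, zv: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Backward pass through the PAS -> DEG layer.

    Returns (dLL/dzeta, dLL/dPath_aug). ``path_aug`` includes the leak
    column if the layer has one; ``zv`` is the matching (rows x G)
    probability matrix.
    """
    n_rows = zv.shape[0]
    S, G = E.shape
    # survivor products f_p = 1 - Path_p * Z_p and their full product Q
    fs = np.empty((n_rows, S, G))
    for p in range(n_rows):
        fs[p] = 1.0 - path_aug[:, p, None] * zv[None, p, :]
    Q = fs.prod(axis=0)
    gz = np.empty_like(zv)
    dpath = np.empty_like(path_aug)
    for p in range(n_rows):
        T = E * (Q / fs[p])
        gz[p] = zv[p] * (1.0 - zv[p]) * (path_aug[:, p] @ T)
        dpath[:, p] = T @ zv[p]
    return gz, dpath


def grad_zeta(expr, expr_hat, path, z) -> np.ndarray:
    """Analytic gradient of the log-likelihood w.r.t. the raw Z parameters.

    ``dLL/dzeta_pg = Z_pg (1 - Z_pg) * sum_s dLL/dExprHat_sg *
    Path_sp * prod_{p' != p} (1 - Path_sp' Z_p'g)`` — the chain rule
    through the OR-gate and the sigmoid.
    """
    e = _values_arr(expr)
    h = _values_arr(expr_hat)
    pv = _values_arr(path)
    zv, leak = _values_arr(z), _leak_of(z)
    if e.shape != h.shape:
        raise ShapeError(f"expr {e.shape} and expr_hat {h.shape} differ")
    path_aug = _augment_ones(pv, leak)
    if path_aug.shape[1] != zv.shape[0]:
        raise ShapeError(
            f"path has {path_aug.shape[1]} cause columns but z has "
            f"{zv.shape[0]} rows"
        )
    gz, _ = _expr_backward(_dll_dhat(e, h), path_aug, zv)
    return gz


def grad_mu(expr, expr_hat, mut, u, path, z) -> np.ndarray:
    """Analytic gradient of the log-likelihood w.r.t. the raw U parameters.

    Chains ``dLL/dPath_sp`` (computed through the expression layer,
    symmetric to the Z gradient) with
    ``dPath_sp/dU_mp = Mut_sm (1 - Path_sp) / (1 - Mut_sm U_mp)`` and the
    sigmoid factor ``U_mp (1 - U_mp)``. For a binary event matrix the
    denominator simplifies to ``1 - U_mp`` wherever the gene is mutated.
    """
    e = _values_arr(expr)
    h = _values_arr(expr_hat)
    mv = _values_arr(mut)
    uv, leak_u = _values_arr(u), _leak_of(u)
    pv = _values_arr(path)
    zv, leak_z = _values_arr(z), _leak_of(z)
    path_aug = _augment_ones(pv, leak_z)
    if path_aug.shape[1] != zv.shape[0]:
        raise ShapeError("path / z cause-axis mismatch")
    mut_aug = _augment_ones(mv, leak_u)
    if mut_aug.shape[1] != uv.shape[0]:
        raise ShapeError(
            f"mut has {mut_aug.shape[1]} cause columns but u has "
            f"{uv.shape[0]} rows"
        )
    _, dpath_aug = _expr_backward(_dll_dhat(e, h), path_aug, zv)
    dpath = dpath_aug[:, : pv.shape[1]]
    # binary mut: 1 - Mut*U equals 1-U where mutated, 1 elsewhere, and the
    # Mut factor in the numerator kills the unmutated terms
    inner = mut_aug.T @ (dpath * (1.0 - pv))
    return uv * (1.0 - uv) * inner / (1.0 - uv)


def beta_log_density(values: np.ndarray, alpha: float, beta: float) -> float:
    """Unnormalized Beta log-density summed over all entries."""
    v = np.asarray(values, dtype=float)
    return float((alpha - 1.0) * np.sum(np.log(v)) + (beta - 1.0) * np.sum(np.log1p(-v)))


def apply_beta_prior(
    grad: np.ndarray,
    values: np.ndarray,
    alpha: float,
    beta: float,
    variant: str = "derived",
) -> np.ndarray:
    """Add the Beta-prior gradient (w.r.t. the raw parameter) to ``grad``.

    The log Beta(alpha, beta) density of ``v = sigmoid(r)`` differentiates
    to ``(alpha - 1)(1 - v) - (beta - 1) v`` in ``r`` ("derived"); the
    "printed" variant flips the sign of the second term.
    """
    v = np.asarray(values, dtype=float)
    if np.any((v <= 0) | (v >= 1)):
        raise DomainError("prior values must lie strictly inside (0, 1)")
    if variant == "derived":
        term = (alpha - 1.0) * (1.0 - v) - (beta - 1.0) * v
    elif variant == "printed":
        term = (alpha - 1.0) * (1.0 - v) + (beta - 1.0) * v
    else:
        raise ConfigError(f"unknown prior-gradient variant {variant!r}")
    return np.asarray(grad, dtype=float) + term


def rprop_step(
    raw: np.ndarray,
    grad: np.ndarray,
    state: RpropState,
    config: RpropConfig = RpropConfig(),
) -> tuple[np.ndarray, RpropState]:
    """One iRprop- ascent update.

    Step sizes are multiplied by ``eta_plus`` when the gradient keeps its
    sign, by ``eta_minus`` when it flips (in which case the gradient is
    zeroed so the next comparison starts fresh), then each parameter moves
    by ``step * sign(grad)``. Returns new arrays; inputs are not mutated.
    """
    raw = np.asarray(raw, dtype=float)
    grad = np.asarray(grad, dtype=float)
    if raw.shape != grad.shape or raw.shape != state.step.shape:
        raise ShapeError("raw, grad and state shapes must agree")
    prod = grad * state.prev_grad
    step = np.where(
        prod > 0,
        np.minimum(state.step * config.eta_plus, config.delta_max),
        np.where(prod < 0, np.maximum(state.step * config.eta_minus, config.delta_min), state.step),
    )
    g = np.where(prod < 0, 0.0, grad)
    new_raw = raw + step * np.sign(g)
    return new_raw, RpropState(step=step, prev_grad=g)


# ---------------------------------------------------------------------- fit


def _forward_path(mut_aug: np.ndarray, uv: np.ndarray) -> np.ndarray:
    """Fast forward pass for binary causes: Path = 1 - exp(Mut @ log(1-U))."""
    path = 1.0 - np.exp(mut_aug @ np.log1p(-uv))
    return np.clip(path, 0.0, 1.0)


def fit(mut, expr, config: FitConfig, init=None) -> FitResult:
    """Estimate the relation matrices U and Z from paired binary matrices.

    Full-batch penalized-likelihood ascent: forward pass through both
    OR-gate layers, analytic gradients, Beta-prior term, one iRprop- update
    per matrix per iteration. ``config.n_restarts`` independently seeded
    runs are performed and the one with the highest final penalized
    log-likelihood wins. Deterministic for a fixed config (the only
    randomness is the seeded initialization).

    ``init``, if given, is a ``(mu_raw, zeta_raw)`` pair of explicit
    starting points; it replaces the random initialization and implies a
    single run.
    """
    mv = _values_arr(mut)
    ev = _values_arr(expr)
    if mv.ndim != 2 or ev.ndim != 2:
        raise ShapeError("mut and expr must be 2-D")
    if mv.size == 0 or ev.size == 0:
        raise ShapeError("mut and expr must be non-empty")
    if mv.shape[0] != ev.shape[0]:
        raise ShapeError(
            f"mut has {mv.shape[0]} samples but expr has {ev.shape[0]}"
        )
    mut_ids = getattr(mut, "sample_ids", None)
    expr_ids = getattr(expr, "sample_ids", None)
    if mut_ids is not None and expr_ids is not None and mut_ids != expr_ids:
        raise ShapeError("mut and expr sample_ids differ or are reordered")
    S, M = mv.shape
    P = config.n_pathways
    if P >= min(S, M):
        warnings.warn(
            f"n_pathways={P} is not smaller than min(S, M)={min(S, M)}; "
            "the factorization is unlikely to be meaningful",
            stacklevel=2,
        )

    best: tuple[float, np.ndarray, np.ndarray, list[float], bool, int] | None = None
    n_runs = 1 if init is not None else config.n_restarts
    for k in range(n_runs):
        seed = (config.seed + 7919 * k) % (2**31)
        run = _fit_once(mv, ev, config, seed, init)
        if best is None or run[0] > best[0]:
            best = run
    _, mu_raw, zeta_raw, trace, converged, it = best

    gene_ids = list(getattr(mut, "gene_ids", [f"g{m}" for m in range(M)]))
    deg_ids = list(getattr(expr, "gene_ids", [f"e{g}" for g in range(ev.shape[1])]))
    pathway_ids = [f"P{p}" for p in range(P)]
    u = RelationMatrix(
        mu_raw,
        cause_ids=gene_ids + ([LEAK_ID] if config.leak_sga else []),
        effect_ids=pathway_ids,
        leak=config.leak_sga,
    )
    z = RelationMatrix(
        zeta_raw,
        cause_ids=pathway_ids + ([LEAK_ID] if config.leak_deg else []),
        effect_ids=deg_ids,
        leak=config.leak_deg,
    )
    return FitResult(
        u=u,
        z=z,
        path=compute_path(mv, u),
        ll_trace=trace,
        converged=converged,
        iterations_run=it,
    )


def _fit_once(mv: np.ndarray, ev: np.ndarray, config: FitConfig, seed: int, init=None):
    """One seeded optimization run; returns (final pll, raws, trace, ...)."""
    S, M = mv.shape
    G = ev.shape[1]
    P = config.n_pathways
    if init is not None:
        mu_raw = np.array(init[0], dtype=float)
        zeta_raw = np.array(init[1], dtype=float)
        if mu_raw.shape != (M + config.leak_sga, P) or zeta_raw.shape != (
            P + config.leak_deg,
            G,
        ):
            raise ShapeError("explicit init shapes do not match the model")
    else:
        rng = np.random.default_rng(seed)
        mu0 = float(logit(config.init_mean_prob))
        mu_raw = rng.normal(mu0, config.init_sd, size=(M + config.leak_sga, P))
        zeta_raw = rng.normal(mu0, config.init_sd, size=(P + config.leak_deg, G))

    mut_aug = _augment_ones(mv, config.leak_sga)
    state_mu = RpropState.fresh(mu_raw.shape, config.rprop.delta0)
    state_zeta = RpropState.fresh(zeta_raw.shape, config.rprop.delta0)

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        uv = expit(mu_raw)
        zv = expit(zeta_raw)
        path = _forward_path(mut_aug, uv)
        path_aug = _augment_ones(path, config.leak_deg)

        E, pll, gz, dpath_aug = _iteration_backward(ev, path_aug, zv)
        pll += beta_log_density(zv, config.alpha, config.beta)
        if config.prior_on == "both":
            pll += beta_log_density(uv, config.alpha, config.beta)
        trace.append(pll)

        if _has_plateaued(trace, config.tol, config.tol_window):
            converged = True
            break

        dpath = dpath_aug[:, :P]
        gmu = uv * (1.0 - uv) * (mut_aug.T @ (dpath * (1.0 - path))) / (1.0 - uv)
        gz = apply_beta_prior(gz, zv, config.alpha, config.beta, config.prior_gradient)
        if config.prior_on == "both":
            gmu = apply_beta_prior(
                gmu, uv, config.alpha, config.beta, config.prior_gradient
            )
        mu_raw, state_mu = rprop_step(mu_raw, gmu, state_mu, config.rprop)
        zeta_raw, state_zeta = rprop_step(zeta_raw, gz, state_zeta, config.rprop)
        np.clip(mu_raw, -RAW_BOUND, RAW_BOUND, out=mu_raw)
        np.clip(zeta_raw, -RAW_BOUND, RAW_BOUND, out=zeta_raw)

    return trace[-1], mu_raw, zeta_raw, trace, converged, it


def _iteration_backward(ev, path_aug, zv):
    """Forward + backward through the expression layer in one sweep."""
    n_rows = zv.shape[0]
    S, G = ev.shape
    fs = np.empty((n_rows, S, G))
    for p in range(n_rows):
        fs[p] = 1.0 - path_aug[:, p, None] * zv[None, p, :]
    Q = fs.prod(axis=0)
    h = np.clip(1.0 - Q, EPS, 1.0 - EPS)
    pll = float(np.sum(ev * np.log(h) + (1.0 - ev) * np.log1p(-h)))
    E = ev / h - (1.0 - ev) / (1.0 - h)
    gz = np.empty_like(zv)
    dpath = np.empty_like(path_aug)
    for p in range(n_rows):
        T = E * (Q / fs[p])
        gz[p] = zv[p] * (1.0 - zv[p]) * (path_aug[:, p] @ T)
        dpath[:, p] = T @ zv[p]
    return E, pll, gz, dpath


def _has_plateaued(trace: list[float], tol: float, window: int) -> bool:
    if len(trace) <= window or tol <= 0:
        return False
    prev, cur = trace[-1 - window], trace[-1]
    return abs(cur - prev) <= tol * (abs(prev) + 1e-12)


def make_fit_config(**kwargs) -> FitConfig:
    """Convenience constructor allowing nested rprop overrides by name."""
    rprop_keys = {k: kwargs.pop(k) for k in list(kwargs) if hasattr(RpropConfig, k)}
    cfg = FitConfig(**kwargs)
    if rprop_keys:
        cfg = replace(cfg, rprop=replace(cfg.rprop, **rprop_keys))
    return cfg
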