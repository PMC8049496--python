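"""Synthetic data under the OR-gate generative process.

Mutations and the two ground-truth relation matrices are sampled i.i.d.
Bernoulli; pathway status and differential expression then follow by
deterministic OR-gate propagation with zero leak, so with binary truth
matrices every downstream value is exactly 0 or 1. A post-pruning step
enforces the mutual-exclusivity pattern seen in tumours: within each
(sample, pathway) pair at most one member mutation survives.

Default densities (see :class:`SimConfig`) are chosen so that at the
standard scale (1000 samples, 1000 SGAs, 1000 DEGs, 5 pathways) a sample
carries ~20 candidate mutations, a pathway module has ~10 member SGAs and
a regulon ~50 genes — neither a near-empty nor a saturated DEG matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .core import compute_expr_hat, compute_path
from .errors import ConfigError
from .matrices import DEGMatrix, EventMatrix

__all__ = ["SimConfig", "SimulationTruth", "generate", "prune_mutual_exclusivity"]


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; the defaults are the standard simulation scale."""

    n_samples: int = 1000
    n_sga: int = 1000
    n_deg: int = 1000
    n_pathways: int = 5
    mut_density: float = 0.02
    u_density: float = 0.01
    z_density: float = 0.05
    seed: int = 0
    prune: bool = True
    prune_order: str = "after"

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_sga", "n_deg", "n_pathways"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("mut_density", "u_density", "z_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.prune_order not in ("after", "before"):
            raise ConfigError(
                f"prune_order must be 'after' or 'before', got {self.prune_order!r}"
            )


@dataclass
class SimulationTruth:
    """A generated dataset with its planted ground truth."""

    mut: EventMatrix
    expr: DEGMatrix
    u_star: np.ndarray  # M x P binary
    z_star: np.ndarray  # P x G binary
    path_star: np.ndarray  # S x P binary
    config: SimConfig

    def write(self, outdir) -> None:
        """Write the five matrices plus a provenance record as TSV/JSON."""
        import json

        import pandas as pd

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            self.mut.values, index=self.mut.sample_ids, columns=self.mut.gene_ids
        ).to_csv(outdir / "mut.tsv", sep="\t")
        pd.DataFrame(
            self.expr.values, index=self.expr.sample_ids, columns=self.expr.gene_ids
        ).to_csv(outdir / "expr.tsv", sep="\t")
        paths = [f"P{p}" for p in range(self.config.n_pathways)]
        pd.DataFrame(self.u_star, index=self.mut.gene_ids, columns=paths).to_csv(
            outdir / "truth_u.tsv", sep="\t"
        )
        pd.DataFrame(self.z_star, index=paths, columns=self.expr.gene_ids).to_csv(
            outdir / "truth_z.tsv", sep="\t"
        )
        pd.DataFrame(self.path_star, index=self.mut.sample_ids, columns=paths).to_csv(
            outdir / "truth_path.tsv", sep="\t"
        )
        (outdir / "provenance.json").write_text(
            json.dumps({"generator": "orn.simulate.generate", **asdict(self.config)}, indent=2)
        )


def prune_mutual_exclusivity(mut, u_star: np.ndarray, seed: int | np.random.Generator = 0):
    """Enforce mutual exclusivity of member mutations within each pathway.

    Pathways are processed in ascending index order; for each sample, among
    its still-active mutations that are members of the pathway, one
    survivor is drawn uniformly and the rest are zeroed. A gene removed
    while processing an earlier pathway is gone for later pathways too.
    """
    values = np.array(getattr(mut, "values", mut), dtype=np.int8, copy=True)
    u_star = np.asarray(u_star)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for p in range(u_star.shape[1]):
        members = np.flatnonzero(u_star[:, p])
        if members.size == 0:
            continue
        sub = values[:, members]
        for s in np.flatnonzero(sub.sum(axis=1) > 1):
            active = members[sub[s] > 0]
            survivor = rng.choice(active)
            values[s, active] = 0
            values[s, survivor] = 1
    if isinstance(mut, EventMatrix):
        return EventMatrix(values, list(mut.sample_ids), list(mut.gene_ids))
    return values


def generate(config: SimConfig = SimConfig()) -> SimulationTruth:
    """Sample one synthetic dataset with planted truth.

    With the default ``prune_order="after"``, expression is propagated
    from the *pruned* mutation matrix, so the generative invariants
    (``path_star = OR(mut, u_star)``, ``expr = OR(path_star, z_star)``
    with zero leak) hold exactly. ``prune_order="before"`` propagates
    first and prunes afterwards — a sensitivity variant in which the
    emitted expression can be inconsistent with the pruned mutations.
    """
    rng = np.random.default_rng(config.seed)
    S, M, G, P = config.n_samples, config.n_sga, config.n_deg, config.n_pathways
    mut_vals = (rng.random((S, M)) < config.mut_density).astype(np.int8)
    u_star = (rng.random((M, P)) < config.u_density).astype(np.int8)
    z_star = (rng.random((P, G)) < config.z_density).astype(np.int8)
    if config.prune and config.prune_order == "after":
        mut_vals = prune_mutual_exclusivity(mut_vals, u_star, rng)
    # binary truth + zero leak: OR-gate propagation is exact boolean algebra
    path_star = ((mut_vals @ u_star) > 0).astype(np.int8)
    expr_vals = ((path_star @ z_star) > 0).astype(np.int8)
    if config.prune and config.prune_order == "before":
        mut_vals = prune_mutual_exclusivity(mut_vals, u_star, rng)
    mut = EventMatrix(mut_vals)
    expr = DEGMatrix(expr_vals, sample_ids=list(mut.sample_ids), gene_ids=[f"e{j}" for j in range(G)])
    return SimulationTruth(mut, expr, u_star, z_star, path_star, config)


def check_generative_consistency(truth: SimulationTruth) -> bool:
    """True iff OR-gate propagation of the truth reproduces path/expr exactly."""
    path = compute_path(truth.mut, truth.u_star.astype(float))
    expr_hat = compute_expr_hat(truth.path_star.astype(float), truth.z_star.astype(float), clip=False)
    return bool(
        np.array_equal(path, truth.path_star.astype(float))
        and np.array_equal(expr_hat, truth.expr.values.astype(float))
    )
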