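"""Labeled matrix containers for the OR-gate network.

Orientation convention: observed data matrices are samples x features
(``Mut``: samples x SGA genes, ``Expr``: samples x expression genes);
relation matrices are cause x effect (``U``: SGA -> pathway,
``Z``: pathway -> DEG). A relation matrix may carry a *leak* row — an
always-active pseudo-cause appended after the real causes — which models
the effect arising from unobserved causes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .errors import DomainError, FormatError, ShapeError

__all__ = [
    "EventMatrix",
    "DEGMatrix",
    "RelationMatrix",
    "LEAK_ID",
]

#: Reserved identifier for the leak pseudo-cause row of a relation matrix.
LEAK_ID = "__leak__"

#: Raw (logit-scale) parameters are kept inside this bound so that
#: sigmoid values stay strictly inside (0, 1) in double precision.
RAW_BOUND = 15.0


def _check_ids(ids: list[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise FormatError(f"duplicate {what}: {dupes[:5]}")
    return ids


def _check_binary(values: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.ndim != 2:
        raise ShapeError(f"{what} must be 2-D, got shape {arr.shape}")
    bad = ~np.isin(arr, (0, 1))
    if bad.any():
        s, g = np.argwhere(bad)[0]
        raise DomainError(
            f"{what} must contain only 0/1; found {arr[s, g]!r} at ({s}, {g})"
        )
    return arr.astype(np.int8)


@dataclass
class BinaryMatrix:
    """A binary samples x genes matrix with row/column labels."""

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = _check_binary(self.values, type(self).__name__)
        s, m = self.values.shape
        if not self.sample_ids:
            self.sample_ids = [f"S{i}" for i in range(s)]
        if not self.gene_ids:
            self.gene_ids = [f"g{j}" for j in range(m)]
        self.sample_ids = _check_ids(self.sample_ids, "sample_ids")
        self.gene_ids = _check_ids(self.gene_ids, "gene_ids")
        if len(self.sample_ids) != s or len(self.gene_ids) != m:
            raise ShapeError(
                f"labels ({len(self.sample_ids)} x {len(self.gene_ids)}) do not "
                f"match values shape {self.values.shape}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


class EventMatrix(BinaryMatrix):
    """Binary somatic-alteration events (samples x SGA genes)."""


class DEGMatrix(BinaryMatrix):
    """Binary differential-expression calls (samples x expression genes)."""


@dataclass
class RelationMatrix:
    """A cause x effect probability matrix backed by unconstrained parameters.

    ``values = sigmoid(raw)`` at all times; ``raw`` lives on the logit scale
    and is what the optimizer updates. If ``leak`` is true the *last* row is
    the leak pseudo-cause and ``cause_ids[-1] == LEAK_ID``.
    """

    raw: np.ndarray
    cause_ids: list[str] = field(default_factory=list)
    effect_ids: list[str] = field(default_factory=list)
    leak: bool = False

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.ndim != 2:
            raise ShapeError(f"raw must be 2-D, got shape {self.raw.shape}")
        n_causes, n_effects = self.raw.shape
        if not self.cause_ids:
            real = n_causes - 1 if self.leak else n_causes
            self.cause_ids = [f"c{i}" for i in range(real)]
            if self.leak:
                self.cause_ids.append(LEAK_ID)
        if not self.effect_ids:
            self.effect_ids = [f"e{j}" for j in range(n_effects)]
        self.cause_ids = _check_ids(self.cause_ids, "cause_ids")
        self.effect_ids = _check_ids(self.effect_ids, "effect_ids")
        if len(self.cause_ids) != n_causes or len(self.effect_ids) != n_effects:
            raise ShapeError(
                f"labels ({len(self.cause_ids)} x {len(self.effect_ids)}) do "
                f"not match raw shape {self.raw.shape}"
            )
        if self.leak and self.cause_ids[-1] != LEAK_ID:
            raise FormatError(
                f"leak relation matrix must have {LEAK_ID!r} as its last cause"
            )

    @classmethod
    def from_values(
        cls,
        values: np.ndarray,
        cause_ids: list[str] | None = None,
        effect_ids: list[str] | None = None,
        leak: bool = False,
    ) -> "RelationMatrix":
        """Build from probabilities in (0, 1); raw is their logit."""
        values = np.asarray(values, dtype=float)
        if np.any((values <= 0) | (values >= 1)):
            raise DomainError("values must lie strictly inside (0, 1)")
        return cls(logit(values), cause_ids or [], effect_ids or [], leak)

    @property
    def values(self) -> np.ndarray:
        """Probabilities ``sigmoid(raw)``, strictly inside (0, 1)."""
        return expit(np.clip(self.raw, -RAW_BOUND, RAW_BOUND))

    @property
    def n_causes(self) -> int:
        """Number of real causes (leak row excluded)."""
        return self.raw.shape[0] - (1 if self.leak else 0)

    @property
    def n_effects(self) -> int:
        return self.raw.shape[1]

    def real_values(self) -> np.ndarray:
        """Probabilities for the real causes only (leak row dropped)."""
        v = self.values
        return v[:-1] if self.leak else v
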