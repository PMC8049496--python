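"""From raw genomic/transcriptomic tables to the binary model inputs.

The model consumes two binary matrices: somatic events (non-silent SNVs
combined with high-level copy-number calls) and differential-expression
calls (|Z| exceeding the two-sided 5% normal quantile). All tables here
are pandas DataFrames with samples as rows and genes as columns.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigError, FormatError
from .matrices import DEGMatrix, EventMatrix

__all__ = [
    "binarize_cnv",
    "combine_events",
    "filter_low_expression",
    "binarize_zscores",
    "robust_zscores",
    "lasso_filter",
]

logger = logging.getLogger(__name__)

#: Two-sided 5% normal quantile used to call differential expression.
Z_CUTOFF = 1.96

#: Genes whose median raw count falls below this are dropped for power.
MIN_MEDIAN_COUNT = 10.0


def _as_frame(x, what: str) -> pd.DataFrame:
    if isinstance(x, pd.DataFrame):
        return x
    if isinstance(x, (EventMatrix, DEGMatrix)):
        return pd.DataFrame(x.values, index=x.sample_ids, columns=x.gene_ids)
    arr = np.asarray(x)
    if arr.ndim != 2:
        raise FormatError(f"{what} must be a 2-D table")
    return pd.DataFrame(arr)


def binarize_cnv(cnv) -> EventMatrix:
    """Binarize GISTIC-style integer copy-number calls.

    Only high-level events count: a cell becomes 1 iff the code is +2
    (amplification) or -2 (deep deletion); single-copy gains/losses (+/-1)
    and neutral (0) become 0.
    """
    df = _as_frame(cnv, "cnv")
    vals = df.to_numpy()
    if not np.all(np.isfinite(vals.astype(float))) or np.any(vals.astype(float) % 1 != 0):
        raise FormatError("CNV matrix must contain finite integer codes")
    binary = (np.abs(vals.astype(int)) == 2).astype(np.int8)
    return EventMatrix(binary, list(map(str, df.index)), list(map(str, df.columns)))


def combine_events(snv, cnv_bin) -> EventMatrix:
    """Elementwise OR of SNV and binarized CNV events.

    Tables are aligned on their shared samples (in SNV order) and the
    union of their genes; a gene absent from one source contributes 0.
    """
    a = _as_frame(snv, "snv")
    b = _as_frame(cnv_bin, "cnv_bin")
    shared = [s for s in a.index if s in set(b.index)]
    if not shared:
        raise AlignmentError("snv and cnv tables share no samples")
    genes = list(dict.fromkeys(list(a.columns) + list(b.columns)))
    a2 = a.reindex(index=shared, columns=genes, fill_value=0)
    b2 = b.reindex(index=shared, columns=genes, fill_value=0)
    combined = ((a2.to_numpy() + b2.to_numpy()) > 0).astype(np.int8)
    return EventMatrix(combined, list(map(str, shared)), list(map(str, genes)))


def filter_low_expression(counts) -> list[str]:
    """Gene ids whose median raw count across samples is at least 10."""
    df = _as_frame(counts, "counts")
    vals = df.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise FormatError("counts must be non-negative")
    medians = np.median(vals, axis=0)
    kept = [str(g) for g, m in zip(df.columns, medians) if m >= MIN_MEDIAN_COUNT]
    logger.info("low-expression filter kept %d of %d genes", len(kept), df.shape[1])
    return kept


def binarize_zscores(z) -> DEGMatrix:
    """Call differential expression where |Z| strictly exceeds 1.96."""
    df = _as_frame(z, "zscores")
    vals = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        bad = np.argwhere(~np.isfinite(vals))
        offenders = [
            f"({df.index[i]}, {df.columns[j]})" for i, j in bad[:5]
        ]
        raise FormatError(f"non-finite Z scores at {', '.join(offenders)}")
    binary = (np.abs(vals) > Z_CUTOFF).astype(np.int8)
    return DEGMatrix(binary, list(map(str, df.index)), list(map(str, df.columns)))


def robust_zscores(counts) -> pd.DataFrame:
    """Median/MAD Z scores per gene, for users without precomputed scores.

    MAD is scaled by 1.4826 for consistency with the normal sd; genes with
    zero MAD get Z = 0 everywhere. This is a convenience beyond the core
    pipeline, which expects externally supplied Z scores.
    """
    df = _as_frame(counts, "counts").astype(float)
    med = df.median(axis=0)
    mad = (df - med).abs().median(axis=0) * 1.4826
    safe = mad.replace(0.0, np.inf)
    return (df - med) / safe


def lasso_filter(
    mut,
    expr,
    reg_strength: float | None = None,
    fit_intercept: bool = True,
    alphas: np.ndarray | None = None,
    cv: int = 3,
    max_iter: int = 5000,
) -> list[str]:
    """Retain SGA genes with predictive power for the DEG matrix.

    Fits a multi-task (L2,1-regularized) lasso from mutation columns to
    all DEG columns jointly and keeps genes whose coefficient row is not
    identically zero. If ``reg_strength`` is None it is chosen by
    ``cv``-fold cross-validation over a logarithmic grid (deterministic:
    unshuffled folds); the grid and chosen value are logged.
    """
    from sklearn.linear_model import MultiTaskLasso, MultiTaskLassoCV

    mdf = _as_frame(mut, "mut")
    edf = _as_frame(expr, "expr")
    if mdf.shape[0] != edf.shape[0]:
        raise AlignmentError("mut and expr must have the same samples")
    X = mdf.to_numpy(dtype=float)
    Y = edf.to_numpy(dtype=float)
    if reg_strength is None:
        grid = alphas if alphas is not None else np.logspace(-3, 0, 7)
        model = MultiTaskLassoCV(
            alphas=grid, cv=cv, fit_intercept=fit_intercept, max_iter=max_iter
        ).fit(X, Y)
        logger.info(
            "lasso_filter: grid %s, selected alpha %.4g", list(grid), model.alpha_
        )
    else:
        if reg_strength <= 0:
            raise ConfigError(f"reg_strength must be positive, got {reg_strength}")
        model = MultiTaskLasso(
            alpha=reg_strength, fit_intercept=fit_intercept, max_iter=max_iter
        ).fit(X, Y)
    keep = np.any(model.coef_ != 0.0, axis=0)  # coef_ is targets x features
    return [str(g) for g, k in zip(mdf.columns, keep) if k]
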