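"""Reading and writing the package's delimited-text matrix dialect.

Matrices are stored as TSV with one header row of column labels and one
leading column of row labels. Observed data files are samples x genes by
default; a ``genes-by-samples`` orientation flag transposes on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError

__all__ = ["read_matrix", "write_matrix", "write_provenance"]

_KINDS = ("binary", "integer", "real")


def read_matrix(path, kind: str = "real", orientation: str = "samples-by-genes") -> pd.DataFrame:
    """Read a labeled TSV matrix, validating values against ``kind``.

    ``kind="binary"`` rejects anything outside {0, 1}; ``"integer"``
    rejects fractional values; ``"real"`` only rejects non-numeric cells.
    Errors report the 1-based file line of the first offending row.
    """
    if kind not in _KINDS:
        raise FormatError(f"kind must be one of {_KINDS}, got {kind!r}")
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise FormatError(f"{path}: duplicate column labels {dupes[:5]}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: malformed table ({exc})") from exc
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate row labels {dupes[:5]}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate column labels {dupes[:5]}")
    try:
        vals = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell ({exc})") from exc
    if not np.all(np.isfinite(vals)):
        row = int(np.argwhere(~np.isfinite(vals))[0][0])
        raise FormatError(f"{path}: non-finite value at line {row + 2}")
    if kind == "binary" and not np.all(np.isin(vals, (0.0, 1.0))):
        bad = np.argwhere(~np.isin(vals, (0.0, 1.0)))[0]
        raise FormatError(
            f"{path}: non-binary value {vals[tuple(bad)]!r} at line {bad[0] + 2}, "
            f"column {df.columns[bad[1]]!r}"
        )
    if kind == "integer" and np.any(vals % 1 != 0):
        bad = np.argwhere(vals % 1 != 0)[0]
        raise FormatError(f"{path}: non-integer value at line {bad[0] + 2}")
    if kind in ("binary", "integer"):
        df = df.astype(int)
    if orientation == "genes-by-samples":
        df = df.T
    elif orientation != "samples-by-genes":
        raise FormatError(f"unknown orientation {orientation!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    """Write a labeled matrix as TSV (row labels in the first column)."""
    pd.DataFrame(df).to_csv(Path(path), sep="\t")


def write_provenance(outdir, record: dict) -> None:
    """Drop a JSON provenance record (config echo, seed, version) in outdir."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {"orn_version": __version__, **record}
    (outdir / "provenance.json").write_text(json.dumps(payload, indent=2, default=str))
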