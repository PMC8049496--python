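"""Post-fit extraction of pathway modules, regulons, and patient status.

A fitted model yields probabilistic relation matrices; biological readout
needs discrete gene sets. The upstream module of pathway p is the set of
SGA genes whose U weight exceeds a cutoff (default 0.5); its regulon is
either the DEG genes with Z above an absolute floor (0.1) or the top
fraction (default 5%) of genes by Z within the pathway. Binarized
per-patient pathway status (PAS > 0.5) defines subgroups suitable for
external survival or enrichment analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .matrices import LEAK_ID, RelationMatrix

__all__ = [
    "PathwayModule",
    "extract_upstream",
    "extract_regulon",
    "binarize_pas",
    "build_modules",
    "export_modules",
    "read_gmt",
]

logger = logging.getLogger(__name__)


@dataclass
class PathwayModule:
    """One latent pathway's upstream SGA set and downstream regulon."""

    pathway_index: int
    upstream_genes: set[str]
    regulon_genes: set[str]


def _real_rows(rel: RelationMatrix | np.ndarray):
    """(values without leak row, cause ids without leak)."""
    if isinstance(rel, RelationMatrix):
        ids = rel.cause_ids[:-1] if rel.leak else rel.cause_ids
        return rel.real_values(), ids
    vals = np.asarray(rel, dtype=float)
    return vals, [f"c{i}" for i in range(vals.shape[0])]


def _check_pathway_index(p: int, n: int) -> None:
    if not 0 <= p < n:
        raise IndexError(f"pathway index {p} out of range [0, {n})")


def extract_upstream(u, p: int, cutoff: float = 0.5) -> set[str]:
    """SGA genes whose U weight for pathway ``p`` strictly exceeds ``cutoff``."""
    if not 0.0 < cutoff < 1.0:
        raise ConfigError(f"cutoff must lie in (0, 1), got {cutoff}")
    vals, ids = _real_rows(u)
    _check_pathway_index(p, vals.shape[1])
    genes = {ids[m] for m in np.flatnonzero(vals[:, p] > cutoff)}
    if not genes:
        logger.warning("pathway %d has an empty upstream module at cutoff %g", p, cutoff)
    return genes


def extract_regulon(
    z,
    p: int,
    mode: str = "top_fraction",
    threshold: float = 0.05,
    floor: float | None = None,
) -> set[str]:
    """DEG genes attributed to pathway ``p``.

    ``mode="absolute"``: genes with Z strictly above ``threshold``.
    ``mode="top_fraction"``: the ``ceil(threshold * G)`` genes with the
    largest Z in row p, ties broken by lexicographic gene id; if ``floor``
    is given, only genes above it are eligible.
    """
    if isinstance(z, RelationMatrix):
        vals = z.real_values() if z.leak else z.values
        gene_ids = z.effect_ids
        # leak lives on the cause axis of Z, so rows, not columns
    else:
        vals = np.asarray(z, dtype=float)
        gene_ids = [f"e{j}" for j in range(vals.shape[1])]
    _check_pathway_index(p, vals.shape[0])
    row = vals[p]
    if mode == "absolute":
        if not 0.0 <= threshold < 1.0:
            raise ConfigError(f"absolute threshold must lie in [0, 1), got {threshold}")
        genes = {gene_ids[g] for g in np.flatnonzero(row > threshold)}
    elif mode == "top_fraction":
        if not 0.0 < threshold < 1.0:
            raise ConfigError(
                f"top_fraction threshold must lie in (0, 1), got {threshold}"
            )
        eligible = list(range(len(row)))
        if floor is not None:
            eligible = [g for g in eligible if row[g] > floor]
        k = math.ceil(threshold * len(row))
        ranked = sorted(eligible, key=lambda g: (-row[g], gene_ids[g]))
        genes = {gene_ids[g] for g in ranked[:k]}
    else:
        raise ConfigError(f"mode must be 'absolute' or 'top_fraction', got {mode!r}")
    if not genes:
        logger.warning("pathway %d has an empty regulon", p)
    return genes


def binarize_pas(path, cutoff: float = 0.5) -> np.ndarray:
    """Binary patient-by-pathway status: 1 iff Path strictly above cutoff."""
    vals = np.asarray(getattr(path, "values", path), dtype=float)
    return (vals > cutoff).astype(np.int8)


def build_modules(
    u,
    z,
    upstream_cutoff: float = 0.5,
    regulon_mode: str = "top_fraction",
    regulon_threshold: float = 0.05,
) -> list[PathwayModule]:
    """Extract every pathway's module pair from fitted relation matrices."""
    n_pathways = (_real_rows(u)[0]).shape[1]
    return [
        PathwayModule(
            pathway_index=p,
            upstream_genes=extract_upstream(u, p, upstream_cutoff),
            regulon_genes=extract_regulon(z, p, regulon_mode, regulon_threshold),
        )
        for p in range(n_pathways)
    ]


def export_modules(modules: list[PathwayModule], path_out, format: str = "gmt") -> None:
    """Write upstream/regulon gene sets as GMT or long-format TSV.

    GMT dialect: one set per line — name, description, then tab-separated
    members. Set names are ``pathway<p>_upstream`` / ``pathway<p>_regulon``.
    """
    if not modules:
        raise ConfigError("modules must be non-empty")
    path_out = Path(path_out)
    rows = []
    for mod in modules:
        for kind, genes in (
            ("upstream", mod.upstream_genes),
            ("regulon", mod.regulon_genes),
        ):
            if LEAK_ID in genes:
                raise ConfigError("leak pseudo-gene leaked into an exported set")
            if not genes:
                logger.warning(
                    "exporting empty %s set for pathway %d", kind, mod.pathway_index
                )
            rows.append((f"pathway{mod.pathway_index}_{kind}", kind, sorted(genes)))
    if format == "gmt":
        with path_out.open("w") as fh:
            for name, kind, genes in rows:
                fh.write("\t".join([name, f"{kind} gene set"] + genes) + "\n")
    elif format == "tsv":
        long = [
            {"set": name, "kind": kind, "gene": g}
            for name, kind, genes in rows
            for g in genes
        ]
        pd.DataFrame(long, columns=["set", "kind", "gene"]).to_csv(
            path_out, sep="\t", index=False
        )
    else:
        raise ConfigError(f"format must be 'gmt' or 'tsv', got {format!r}")


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT file back into {set name: member set}."""
    out: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        out[fields[0]] = set(fields[2:])
    return out


def read_modules_tsv(path) -> dict[str, set[str]]:
    """Read the long-format TSV produced by :func:`export_modules`."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, set[str]] = {name: set() for name in df["set"].unique()}
    for _, row in df.iterrows():
        out[row["set"]].add(str(row["gene"]))
    return out
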