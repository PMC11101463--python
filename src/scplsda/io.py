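"""Readers and writers for the standard on-disk formats.

Expression comes in as Matrix Market coordinate files with one-column TSV
sidecars for gene and cell identifiers; gene sets as GMT; tabular metadata
and results as TSV with a header row; summary metrics as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datatypes import (
    CountMatrix,
    FormatError,
    GeneSetDB,
    validate_cell_metadata,
    validate_subject_markers,
)


def _read_sidecar(path: str | Path) -> np.ndarray:
    ids = pd.read_csv(path, sep="\t", header=None, dtype=str)[0].to_numpy(dtype=object)
    if len(ids) == 0:
        raise FormatError(f"empty identifier sidecar: {path}")
    return ids


def read_count_matrix(
    mtx_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
    orientation: str = "auto",
) -> CountMatrix:
    """Read a Matrix Market count file with gene/cell TSV sidecars.

    Both cells x genes and genes x cells dialects circulate; by default the
    orientation is inferred from the sidecar lengths and the matrix is
    transposed to cells x genes if needed. A square matrix with equally long
    sidecars is ambiguous and requires an explicit ``orientation`` of
    ``"cells_by_genes"`` or ``"genes_by_cells"``.
    """
    mat = sp.csr_matrix(scipy.io.mmread(mtx_path))
    genes = _read_sidecar(genes_path)
    cells = _read_sidecar(cells_path)
    n_rows, n_cols = mat.shape
    if orientation == "cells_by_genes":
        pass
    elif orientation == "genes_by_cells":
        mat = sp.csr_matrix(mat.T)
    elif orientation == "auto":
        if n_rows == len(cells) and n_cols == len(genes):
            if n_rows == n_cols and len(cells) == len(genes):
                raise FormatError(
                    "square matrix with equal sidecar lengths: orientation is "
                    "ambiguous, pass orientation='cells_by_genes' or "
                    "'genes_by_cells'"
                )
        elif n_rows == len(genes) and n_cols == len(cells):
            mat = sp.csr_matrix(mat.T)
        else:
            raise FormatError(
                f"matrix shape {mat.shape} matches neither sidecar "
                f"orientation (genes={len(genes)}, cells={len(cells)}) "
                f"in {mtx_path}"
            )
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return CountMatrix(counts=mat, gene_ids=genes, cell_ids=cells)


def write_count_matrix(
    cm: CountMatrix,
    mtx_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
) -> None:
    """Write cells x genes counts as Matrix Market plus identifier sidecars."""
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(cm.counts))
    pd.Series(cm.gene_ids).to_csv(genes_path, sep="\t", header=False, index=False)
    pd.Series(cm.cell_ids).to_csv(cells_path, sep="\t", header=False, index=False)


def read_gmt(path: str | Path) -> GeneSetDB:
    """Parse a GMT file: per line tab-separated name, description, members.

    Duplicate member symbols within a set collapse; a duplicate set name or
    a line with fewer than three fields is a format error.
    """
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and at "
                    f"least one member, got {len(fields)} fields"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = (desc, frozenset(members))
    return GeneSetDB(sets=sets)


def write_gmt(db: GeneSetDB, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in db.sets.items():
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_cell_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "subject_id": str,
                                              "cell_type": str})
    return validate_cell_metadata(meta)


def write_cell_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_subject_markers(path: str | Path) -> pd.DataFrame:
    markers = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    return validate_subject_markers(markers)


def write_subject_markers(markers: pd.DataFrame, path: str | Path) -> None:
    markers.to_csv(path, sep="\t", index=False)


def read_risk_loci(path: str | Path) -> pd.DataFrame:
    """Risk-locus list: TSV with a ``gene`` column (extra columns preserved)."""
    loci = pd.read_csv(path, sep="\t", dtype=str)
    if "gene" not in loci.columns:
        raise FormatError(f"risk-locus file {path} lacks a 'gene' column")
    if loci["gene"].duplicated().any():
        dup = loci.loc[loci["gene"].duplicated(), "gene"].iloc[0]
        raise FormatError(f"duplicate risk locus {dup!r} in {path}")
    return loci


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """All result tables go out as TSV with a header row."""
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
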