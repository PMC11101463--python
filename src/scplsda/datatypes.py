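"""Core containers shared across the pipeline.

The pipeline operates on a sparse cells x genes count matrix with string
identifiers, per-cell metadata (subject, binary diagnosis, cell-type),
per-subject pathology/cognition markers, and a gene-set database (GMT-style
mapping of set name to description and member symbols).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp


class FormatError(ValueError):
    """Raised when an input file or container violates its contract."""


@dataclass
class CountMatrix:
    """Sparse non-negative integer counts, cells x genes, with identifiers.

    Attributes
    ----------
    counts : scipy.sparse.csr_matrix
        Non-negative integer counts, one row per cell.
    gene_ids : np.ndarray of str
        Ordered unique gene symbols, one per column.
    cell_ids : np.ndarray of str
        Ordered unique cell identifiers, one per row.
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        n_cells, n_genes = self.counts.shape
        if len(self.cell_ids) != n_cells:
            raise FormatError(
                f"cell id list has {len(self.cell_ids)} entries but matrix has "
                f"{n_cells} rows"
            )
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"gene id list has {len(self.gene_ids)} entries but matrix has "
                f"{n_genes} columns"
            )
        for name, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            uniq, counts = np.unique(ids.astype(str), return_counts=True)
            if (counts > 1).any():
                dup = uniq[counts > 1][0]
                raise FormatError(f"duplicate {name} identifier: {dup!r}")
        data = self.counts.data
        if data.size:
            if not np.isfinite(data).all():
                raise FormatError("counts contain non-finite entries")
            if (data < 0).any():
                bad = data[data < 0][0]
                raise FormatError(f"negative count entry: {bad}")
            if np.any(data != np.round(data)):
                bad = data[data != np.round(data)][0]
                raise FormatError(f"non-integer count entry: {bad}")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


@dataclass
class GeneSetDB:
    """Mapping set_name -> (description, frozenset of member gene symbols)."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, tuple[str, frozenset[str]]] = {}
        for name, (desc, members) in self.sets.items():
            members = frozenset(members)
            if not members:
                raise FormatError(f"gene set {name!r} has no members")
            clean[name] = (desc, members)
        self.sets = clean

    def members(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets


REQUIRED_CELL_COLUMNS = ("cell_id", "subject_id", "diagnosis", "cell_type")
REQUIRED_MARKER_COLUMNS = (
    "subject_id", "braak", "cerad", "cognition", "tangles", "amyloid",
)


def validate_cell_metadata(meta: pd.DataFrame, cm: CountMatrix | None = None) -> pd.DataFrame:
    """Check the per-cell metadata contract.

    Every cell of the count matrix must have exactly one row, diagnosis is
    coded +1 (disease) / -1 (control), and each subject carries a single
    diagnosis.
    """
    for col in REQUIRED_CELL_COLUMNS:
        if col not in meta.columns:
            raise FormatError(f"cell metadata missing column {col!r}")
    diag = meta["diagnosis"].to_numpy()
    if not np.isin(diag, (-1, 1)).all():
        bad = diag[~np.isin(diag, (-1, 1))][0]
        raise FormatError(f"diagnosis values must be +1/-1, found {bad!r}")
    per_subject = meta.groupby("subject_id")["diagnosis"].nunique()
    if (per_subject > 1).any():
        subj = per_subject[per_subject > 1].index[0]
        raise FormatError(f"subject {subj!r} carries more than one diagnosis")
    if meta["cell_id"].duplicated().any():
        dup = meta.loc[meta["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise FormatError(f"duplicate cell_id in metadata: {dup!r}")
    if cm is not None:
        missing = set(map(str, cm.cell_ids)) - set(meta["cell_id"].astype(str))
        if missing:
            raise FormatError(
                f"{len(missing)} cells absent from metadata, e.g. {sorted(missing)[0]!r}"
            )
    return meta


def validate_subject_markers(markers: pd.DataFrame,
                             meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Check the per-subject marker contract (one row per subject)."""
    for col in REQUIRED_MARKER_COLUMNS:
        if col not in markers.columns:
            raise FormatError(f"subject markers missing column {col!r}")
    if markers["subject_id"].duplicated().any():
        dup = markers.loc[markers["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise FormatError(f"duplicate subject_id in markers: {dup!r}")
    if meta is not None:
        missing = set(meta["subject_id"].astype(str)) - set(markers["subject_id"].astype(str))
        if missing:
            raise FormatError(
                f"subjects present in cell metadata but absent from markers: "
                f"{sorted(missing)[:3]}"
            )
    return markers
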