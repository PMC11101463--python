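"""From raw counts to balanced, standardized per-cell-type matrices.

Fixed stage order: library-size normalize + log1p on the whole matrix,
subset to one cell-type, drop genes detected in too few cells of that type,
subsample the majority diagnosis class to balance, standardize columns (the
standardization is refit inside every cross-validation training portion —
parameters are never estimated on held-out cells).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .datatypes import CountMatrix


@dataclass
class StandardizedDataset:
    """Column-standardized design matrix with the parameters to reapply.

    ``X`` has column mean 0 / population sd 1 on the fitting data; ``y`` is
    the +1/-1 diagnosis vector standardized the same way. The stored means
    and sds are applied, never re-estimated, to held-out data.
    """

    X: np.ndarray
    y: np.ndarray
    gene_ids: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    y_mean: float
    y_sd: float
    provenance: dict = field(default_factory=dict)


def normalize_log1p(counts, target_sum: float = 10_000.0) -> sp.csr_matrix:
    """Scale each cell to ``target_sum`` total counts, then log1p.

    All-zero cells are returned as all-zero with a warning (they carry no
    information to rescale).
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    mat = sp.csr_matrix(counts, dtype=float)
    if mat.data.size and mat.data.min() < 0:
        raise ValueError("negative entries in count matrix")
    totals = np.asarray(mat.sum(axis=1)).ravel()
    zero_rows = totals == 0
    if zero_rows.any():
        warnings.warn(f"{int(zero_rows.sum())} cells have zero total counts; "
                      "left all-zero", stacklevel=2)
    scale = np.divide(target_sum, totals, out=np.zeros_like(totals),
                      where=~zero_rows)
    out = sp.diags(scale) @ mat
    out.data = np.log1p(out.data)
    return sp.csr_matrix(out)


def filter_genes_min_cells(matrix, gene_ids: np.ndarray,
                           min_fraction: float = 0.001):
    """Keep genes detected (count > 0) in at least ceil(min_fraction * n)
    cells of the (already cell-type-subset) matrix; order preserved."""
    gene_ids = np.asarray(gene_ids, dtype=object)
    n_cells = matrix.shape[0]
    threshold = int(np.ceil(min_fraction * n_cells))
    if sp.issparse(matrix):
        detected = np.asarray((matrix > 0).sum(axis=0)).ravel()
    else:
        detected = (np.asarray(matrix) > 0).sum(axis=0)
    keep = detected >= threshold
    if not keep.any():
        raise ValueError("gene filter removed every gene")
    return matrix[:, keep], gene_ids[keep]


def balance_classes(labels: np.ndarray, seed: int) -> np.ndarray:
    """Indices of a class-balanced subset: the minority class untouched, the
    majority uniformly subsampled without replacement. Returned in the
    original cell order."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == -1)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both diagnosis classes must be non-empty")
    k = min(pos.size, neg.size)
    keep_pos = pos if pos.size == k else np.sort(rng.choice(pos, size=k, replace=False))
    keep_neg = neg if neg.size == k else np.sort(rng.choice(neg, size=k, replace=False))
    return np.sort(np.concatenate([keep_pos, keep_neg]))


def shuffle_once(n_cells: int, seed: int) -> np.ndarray:
    """The one global permutation applied to the cell order before any other
    stage, guarding against structure in the input ordering."""
    return np.random.default_rng(seed).permutation(n_cells)


def drop_zero_variance(X: np.ndarray, gene_ids: np.ndarray):
    """Remove constant columns (undefined under standardization); returns
    (X, gene_ids, n_dropped)."""
    X = np.asarray(X)
    sd = X.std(axis=0)
    keep = sd > 0
    return X[:, keep], np.asarray(gene_ids, dtype=object)[keep], int((~keep).sum())


def standardize(X: np.ndarray, y_labels: np.ndarray,
                gene_ids: np.ndarray | None = None,
                provenance: dict | None = None) -> StandardizedDataset:
    """Column-wise zero mean / unit population sd for X and for the +1/-1
    label vector."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y_labels, dtype=float)
    if gene_ids is None:
        gene_ids = np.array([f"g{i}" for i in range(X.shape[1])], dtype=object)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"zero-variance column reached standardization "
                         f"(index {bad}); drop it first")
    y_mean = float(y.mean())
    y_sd = float(y.std())
    if y_sd == 0:
        raise ValueError("labels have zero variance")
    return StandardizedDataset(
        X=(X - mean) / sd,
        y=(y - y_mean) / y_sd,
        gene_ids=np.asarray(gene_ids, dtype=object),
        mean=mean,
        sd=sd,
        y_mean=y_mean,
        y_sd=y_sd,
        provenance=dict(provenance or {}),
    )


def apply_standardization(data: StandardizedDataset, X_new: np.ndarray) -> np.ndarray:
    """Apply the stored (training) standardization to held-out rows."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.shape[1] != data.mean.size:
        raise ValueError("column count does not match stored parameters")
    return (X_new - data.mean) / data.sd
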