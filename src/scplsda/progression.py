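"""Subject-level disease pseudo-progression from classifier confidences.

Per-cell out-of-sample continuous predictions (nested-CV validation folds
only) are grouped by subject within each cell-type and summarized by the
median, giving a (cell-types x subjects) confidence matrix. Its first
principal component, after centering each cell-type row across subjects,
orders the subjects from most control-like to most disease-like; the sign
is fixed so disease-labelled subjects score higher on average. The ordering
is validated by Spearman correlation against pathology and cognition
markers (tangles, amyloid, Braak, CERAD increase with severity; cognition
decreases).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .datatypes import FormatError


@dataclass
class SubjectConfidence:
    """Median out-of-sample prediction per (cell-type, subject)."""

    matrix: np.ndarray          # (n_cell_types, n_subjects)
    cell_types: list
    subject_ids: list
    imputed: np.ndarray         # True where the subject had no cells of the type


@dataclass
class PseudoProgression:
    subject_ids: list
    score: np.ndarray
    rank: np.ndarray            # 1 = most control-like
    flipped: bool


def aggregate_confidence(predictions: pd.DataFrame,
                         cell_metadata: pd.DataFrame) -> SubjectConfidence:
    """Median per (subject, cell-type) of out-of-sample predictions.

    ``predictions`` needs columns cell_id, cell_type, prediction. Missing
    (subject, cell-type) entries are imputed with that cell-type's
    cross-subject mean and flagged.
    """
    known = set(cell_metadata["subject_id"].astype(str))
    merged = predictions.merge(cell_metadata[["cell_id", "subject_id"]],
                               on="cell_id", how="left")
    if merged["subject_id"].isna().any():
        bad = merged.loc[merged["subject_id"].isna(), "cell_id"].iloc[0]
        raise FormatError(f"cell {bad!r} absent from metadata")
    extra = set(merged["subject_id"].astype(str)) - known
    if extra:
        raise FormatError(f"subjects absent from metadata: {sorted(extra)[:3]}")
    subject_ids = sorted(known)
    cell_types = sorted(merged["cell_type"].unique())
    med = merged.groupby(["cell_type", "subject_id"])["prediction"].median()
    matrix = np.full((len(cell_types), len(subject_ids)), np.nan)
    for i, ct in enumerate(cell_types):
        for j, s in enumerate(subject_ids):
            if (ct, s) in med.index:
                matrix[i, j] = med.loc[(ct, s)]
    imputed = np.isnan(matrix)
    if imputed.any():
        row_means = np.nanmean(matrix, axis=1)
        for i in range(matrix.shape[0]):
            matrix[i, imputed[i]] = row_means[i]
    return SubjectConfidence(matrix=matrix, cell_types=cell_types,
                             subject_ids=subject_ids, imputed=imputed)


def pseudo_progression_pc1(conf: SubjectConfidence,
                           diagnosis: pd.Series | dict) -> PseudoProgression:
    """Project subjects on the first principal component of the confidence
    matrix (rows centered across subjects, no row scaling — cell-types stay
    on the common standardized-prediction scale)."""
    M = np.asarray(conf.matrix, dtype=float)
    if M.shape[1] < 2 or M.shape[0] < 1:
        raise ValueError("need at least 2 subjects and 1 cell-type")
    centered = M - M.mean(axis=1, keepdims=True)
    if not np.any(centered):
        raise ValueError("confidence matrix has zero variance")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    score = s[0] * vt[0]
    diag = pd.Series(dict(diagnosis)) if not isinstance(diagnosis, pd.Series) \
        else diagnosis
    d = diag.reindex(conf.subject_ids).to_numpy(dtype=float)
    flipped = False
    ad, ctl = score[d == 1], score[d == -1]
    if ad.size and ctl.size and ad.mean() < ctl.mean():
        score = -score
        flipped = True
    order = np.argsort(score, kind="stable")
    rank = np.empty(score.size, dtype=int)
    rank[order] = np.arange(1, score.size + 1)
    return PseudoProgression(subject_ids=list(conf.subject_ids), score=score,
                             rank=rank, flipped=flipped)


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of mid-ranked values; NaN when either input has
    no rank variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def validate_markers(pp: PseudoProgression,
                     markers: pd.DataFrame) -> pd.DataFrame:
    """Spearman rho between the pseudo-progression score and every marker
    (braak, cerad, cognition, tangles, amyloid)."""
    m = markers.set_index("subject_id").reindex(pp.subject_ids)
    if m.isna().any().any():
        missing = m.index[m.isna().any(axis=1)][0]
        raise FormatError(f"markers missing for subject {missing!r}")
    rows = []
    for col in ("braak", "cerad", "cognition", "tangles", "amyloid"):
        rho = spearman(pp.score, m[col].to_numpy(dtype=float))
        rows.append({"marker": col, "spearman_rho": rho,
                     "degenerate": bool(np.isnan(rho))})
    return pd.DataFrame(rows)
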