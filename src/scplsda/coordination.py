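"""Coordination between gene modules of different cell-types.

For each enriched gene set of a module, a single-component PLS-DA restricted
to that set's genes yields a per-cell activity prediction; the per-subject
mean is that subject's activity for the gene program. Coordination between
two modules of different cell-types is the median |Pearson| over all pairs
of their top gene-set activity columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import pls
from .enrichment import EnrichmentRecord
from .preprocess import StandardizedDataset
from .progression import spearman

logger = logging.getLogger(__name__)


@dataclass
class ActivityMatrix:
    """Per-subject mean activity, one column per selected gene set."""

    values: np.ndarray          # (n_subjects, n_sets)
    subject_ids: list
    set_names: list
    cell_type: str = ""
    module: int = 0


def geneset_activity(data: StandardizedDataset, members: frozenset,
                     subject_ids: np.ndarray,
                     cv_folds: int | None = None,
                     seed: int = 0) -> np.ndarray | None:
    """Per-subject mean prediction of a 1-component PLS-DA restricted to the
    gene set's columns; None (logged) when fewer than 2 set genes survive in
    the matrix.

    By default the mini-model is fitted in-sample on all cells (a known
    optimism source, documented); ``cv_folds`` switches to out-of-sample
    activity via stratified cross-validation.
    """
    cols = np.flatnonzero(np.isin(data.gene_ids, list(members)))
    if cols.size < 2:
        logger.info("gene set with <2 overlapping genes skipped")
        return None
    # a column subset of a standardized matrix is itself standardized
    sub = StandardizedDataset(
        X=data.X[:, cols], y=data.y, gene_ids=data.gene_ids[cols],
        mean=data.mean[cols], sd=data.sd[cols],
        y_mean=data.y_mean, y_sd=data.y_sd)
    if cv_folds is None:
        model = pls.fit_pls(sub, n_components=1)
        pred = pls.predict_continuous(model, sub.X)
    else:
        from .model_selection import stratified_splits
        labels = np.where(sub.y > 0, 1, -1)
        folds = stratified_splits(labels, k=cv_folds, seed=seed)
        pred = np.empty(sub.X.shape[0])
        for f in range(cv_folds):
            val = folds == f
            train = StandardizedDataset(
                X=sub.X[~val], y=sub.y[~val], gene_ids=sub.gene_ids,
                mean=sub.mean, sd=sub.sd, y_mean=sub.y_mean, y_sd=sub.y_sd)
            model = pls.fit_pls(train, n_components=1)
            pred[val] = pls.predict_continuous(model, sub.X[val])
    subjects = np.asarray(subject_ids)
    uniq = sorted(set(subjects))
    return np.array([pred[subjects == s].mean() for s in uniq])


def select_top_sets(records: list[EnrichmentRecord], k: int = 50,
                    rank_by: str = "NES",
                    pseudo_progression: np.ndarray | None = None,
                    activities: dict[str, np.ndarray] | None = None
                    ) -> list[str]:
    """Top-k gene sets of a module, by |NES| (default) or by |Spearman|
    between their activity and the pseudo-progression."""
    if not records:
        raise ValueError("no enrichment records to select from")
    if rank_by.upper() == "NES":
        order = sorted(records,
                       key=lambda r: (-abs(r.nes) if np.isfinite(r.nes)
                                      else 0.0, r.set_name))
        names = [r.set_name for r in order]
    elif rank_by.lower() in ("spearman", "progression"):
        if pseudo_progression is None or activities is None:
            raise ValueError("progression ranking needs the pseudo-progression "
                             "scores and per-set activities")
        scored = [(r.set_name,
                   abs(spearman(activities[r.set_name], pseudo_progression)))
                  for r in records if r.set_name in activities]
        scored.sort(key=lambda t: (-t[1] if np.isfinite(t[1]) else 0.0, t[0]))
        names = [n for n, _ in scored]
    else:
        raise ValueError(f"unknown rank_by {rank_by!r}")
    if len(names) < k:
        logger.info("only %d sets available (k=%d); taking all", len(names), k)
    return names[:k]


def module_coordination(act_a: ActivityMatrix, act_b: ActivityMatrix) -> float:
    """Median |Pearson| over all column pairs of two activity matrices
    (different cell-types, same subject order)."""
    if act_a.subject_ids != act_b.subject_ids:
        raise ValueError("activity matrices must share the subject ordering")
    A = np.asarray(act_a.values, dtype=float)
    B = np.asarray(act_b.values, dtype=float)
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    sa = Ac.std(axis=0)
    sb = Bc.std(axis=0)
    ok_a, ok_b = sa > 0, sb > 0
    if not ok_a.all() or not ok_b.all():
        logger.info("skipping %d zero-variance activity columns",
                    int((~ok_a).sum() + (~ok_b).sum()))
    Ac, sa = Ac[:, ok_a], sa[ok_a]
    Bc, sb = Bc[:, ok_b], sb[ok_b]
    if Ac.shape[1] == 0 or Bc.shape[1] == 0:
        return float("nan")
    corr = (Ac / sa).T @ (Bc / sb) / A.shape[0]
    return float(np.median(np.abs(corr)))


def coordination_matrix(activities: list[ActivityMatrix]) -> pd.DataFrame:
    """Median-|Pearson| coordination for every cross-cell-type module pair;
    within-cell-type pairs are excluded."""
    if len({a.cell_type for a in activities}) < 2:
        raise ValueError("need modules from at least 2 cell-types")
    labels = [f"{a.cell_type}::m{a.module}" for a in activities]
    n = len(activities)
    mat = pd.DataFrame(np.nan, index=labels, columns=labels)
    for i in range(n):
        for j in range(i + 1, n):
            if activities[i].cell_type == activities[j].cell_type:
                continue
            v = module_coordination(activities[i], activities[j])
            mat.iloc[i, j] = v
            mat.iloc[j, i] = v
    return mat
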