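"""Nested cross-validation for choosing the number of latent components.

Outer 5-fold stratified CV gives unbiased out-of-sample predictions; inside
each outer training portion an inner 5-fold CV scans the component grid
(default 1..8) and keeps the value with the highest mean inner AUROC (ties
break to the smallest, parsimonious, value). Standardization is refit inside
every training portion, never on held-out cells. The grid scan fits one
model at the largest grid value per inner fold and evaluates truncations:
sequentially extracted PLS components are nested, so the truncated model is
identical to a refit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from . import pls
from .preprocess import apply_standardization, drop_zero_variance, standardize


@dataclass
class CVResult:
    cell_type: str
    n_components: int
    fold_choices: list
    fold_aurocs: np.ndarray
    fold_r2: np.ndarray
    oos_prediction: np.ndarray  # every cell predicted once, by the model that excluded it
    fold_assignment: np.ndarray

    @property
    def auroc_mean(self) -> float:
        return float(np.mean(self.fold_aurocs))

    @property
    def auroc_sd(self) -> float:
        return float(np.std(self.fold_aurocs, ddof=1))


def stratified_splits(labels: np.ndarray, k: int = 5, seed: int = 0) -> np.ndarray:
    """Fold ids 0..k-1 with per-class counts differing by at most one:
    each class is shuffled (seeded) then dealt round-robin."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    folds = np.full(labels.size, -1, dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < k:
            raise ValueError(f"class {cls!r} has {idx.size} members, fewer than "
                             f"k={k}")
        idx = rng.permutation(idx)
        folds[idx] = np.arange(idx.size) % k
    return folds


def auroc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Probability a random disease cell outranks a random control cell
    (Mann-Whitney U / (n+ * n-), ties counted half)."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    pos = y_true == 1
    neg = y_true == -1
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = scipy.stats.rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def r_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("y_true has zero variance")
    ss_res = float(((y_true - y_pred) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def truncated_coef(model: pls.PLSModel, g: int) -> np.ndarray:
    """Regression coefficients of the first ``g`` components of a fitted
    model — identical to the coefficients of a fresh ``g``-component fit."""
    if g == model.n_components:
        return model.coef
    W, L, c = model.W[:, :g], model.L[:, :g], model.c[:g]
    return W @ np.linalg.pinv(L.T @ W) @ c


def _fit_predict(X_train, y_train, X_val, grid) -> dict[int, np.ndarray]:
    """Fit once at max(grid) and return validation predictions per grid value."""
    Xt, gids, _ = drop_zero_variance(X_train, np.arange(X_train.shape[1]))
    data = standardize(Xt, y_train)
    k_max = min(max(grid), min(Xt.shape) - 1) if min(Xt.shape) > 1 else 1
    k_max = max(k_max, 1)
    model = pls.fit_pls(data, n_components=k_max)
    Xv = apply_standardization(data, np.asarray(X_val)[:, gids.astype(int)])
    out = {}
    for g in grid:
        gg = min(g, k_max)
        out[g] = Xv @ truncated_coef(model, gg)
    return out


def nested_cv(X: np.ndarray, y_labels: np.ndarray,
              grid: tuple[int, ...] = tuple(range(1, 9)),
              outer_k: int = 5, inner_k: int = 5, seed: int = 0,
              cell_type: str = "") -> CVResult:
    """Nested stratified CV over cells; returns per-cell out-of-sample
    predictions, per-fold AUROC/R^2, and the modal component choice."""
    X = np.asarray(X, dtype=float)
    y_labels = np.asarray(y_labels)
    grid = tuple(sorted(set(int(g) for g in grid)))
    ss = np.random.SeedSequence(seed)
    outer_seed, *inner_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                                for s in ss.spawn(outer_k + 1)]
    outer_folds = stratified_splits(y_labels, k=outer_k, seed=outer_seed)

    oos = np.full(y_labels.size, np.nan)
    fold_aurocs = np.empty(outer_k)
    fold_r2 = np.empty(outer_k)
    fold_choices = []
    for fold in range(outer_k):
        val = outer_folds == fold
        train = ~val
        X_tr, y_tr = X[train], y_labels[train]
        inner_folds = stratified_splits(y_tr, k=inner_k, seed=inner_seeds[fold])
        inner_scores = {g: [] for g in grid}
        for ifold in range(inner_k):
            ival = inner_folds == ifold
            preds = _fit_predict(X_tr[~ival], y_tr[~ival], X_tr[ival], grid)
            for g in grid:
                inner_scores[g].append(auroc(y_tr[ival], preds[g]))
        mean_inner = {g: float(np.mean(inner_scores[g])) for g in grid}
        best = max(mean_inner.values())
        chosen = min(g for g in grid if mean_inner[g] == best)
        fold_choices.append(chosen)

        preds = _fit_predict(X_tr, y_tr, X[val], (chosen,))
        oos[val] = preds[chosen]
        fold_aurocs[fold] = auroc(y_labels[val], oos[val])
        y_val_std = (y_labels[val] - y_tr.mean()) / y_tr.std()
        fold_r2[fold] = r_squared(y_val_std, oos[val])

    choices, counts = np.unique(fold_choices, return_counts=True)
    n_components = int(min(choices[counts == counts.max()]))
    return CVResult(cell_type=cell_type, n_components=n_components,
                    fold_choices=fold_choices, fold_aurocs=fold_aurocs,
                    fold_r2=fold_r2, oos_prediction=oos,
                    fold_assignment=outer_folds)
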