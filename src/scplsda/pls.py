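"""Supervised latent-factor model: PLS-DA by the power method.

Components are extracted sequentially. With the current deflated ``X`` and
``y``: the weight vector ``w`` (unit norm) is found by the power iteration
``w = X^T u``, ``t = X w``, ``c = y^T t / t^T t``, ``u = c y``, repeated
until the weight stabilizes; with a single-column outcome this converges
after one pass. Loadings are ``l = X^T t / (t^T t)``; both ``X`` and ``y``
are then deflated by the rank-one structure the component explains. Each
component solves max_alpha Corr^2(y, X alpha) * Var(X alpha) subject to
|alpha| = 1 and S-orthogonality to earlier loadings (S the gene covariance).

Every component is oriented so its y-weight ``c`` is positive: positive
scores align with the disease (+1) label. Per-component sign is the only
non-identifiability of the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import StandardizedDataset


@dataclass
class PLSModel:
    """A fitted PLS-DA classifier.

    ``W`` x-weights (p x k, unit columns), ``T`` cell scores (n x k),
    ``L`` loadings (p x k), ``c`` y-weights (k,), ``U`` y-side scores
    (n x k), ``coef`` (p,) regression coefficients on the standardized
    scales. Standardization parameters travel with the model so held-out
    cells are always transformed with the training statistics.
    """

    W: np.ndarray
    T: np.ndarray
    L: np.ndarray
    c: np.ndarray
    U: np.ndarray
    coef: np.ndarray
    gene_ids: np.ndarray
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    n_components: int
    converged: list = field(default_factory=list)

    @property
    def rotations(self) -> np.ndarray:
        """x-rotations R = W (L^T W)^{-1}: X_std @ R reproduces T despite
        deflation."""
        return self.W @ np.linalg.pinv(self.L.T @ self.W)


def fit_pls(data: StandardizedDataset, n_components: int, tol: float = 1e-6,
            max_iter: int = 500, seed: int | None = None,
            random_init: bool = False) -> PLSModel:
    """Extract ``n_components`` latent components from standardized data.

    ``u`` is initialized from the outcome vector (deterministic); pass
    ``random_init=True`` with a seed for the randomized start, which for a
    single-column outcome reaches the same fixed point.
    """
    X = np.array(data.X, dtype=float)
    y = np.array(data.y, dtype=float)
    n, p = X.shape
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > min(n, p):
        raise ValueError(f"n_components={n_components} exceeds min(n, p)={min(n, p)}")
    rng = np.random.default_rng(seed) if random_init else None
    eps = np.finfo(float).eps

    W = np.empty((p, n_components))
    T = np.empty((n, n_components))
    L = np.empty((p, n_components))
    U = np.empty((n, n_components))
    c_vec = np.empty(n_components)
    converged = []

    for m in range(n_components):
        u = rng.normal(size=n) if random_init else y.copy()
        if np.linalg.norm(u) < eps:
            raise ValueError(f"outcome fully deflated before component {m + 1}; "
                             "n_components exceeds the effective rank")
        w_old = np.zeros(p)
        ok = False
        for _ in range(max_iter):
            w = X.T @ u / (u @ u)
            nw = np.linalg.norm(w)
            if nw < eps:
                raise ValueError(f"weight vector vanished at component {m + 1}; "
                                 "n_components exceeds the effective rank")
            w /= nw
            t = X @ w
            tt = t @ t
            if tt < eps:
                raise ValueError(f"score variance vanished at component {m + 1}; "
                                 "n_components exceeds the effective rank")
            c = (y @ t) / tt
            u = y * c / (c * c + eps)
            diff = w - w_old
            if diff @ diff < tol:
                ok = True
                break
            w_old = w
        if not ok:
            warnings.warn(f"component {m + 1}: power iteration did not converge "
                          f"in {max_iter} iterations; using last iterate",
                          stacklevel=2)
        converged.append(ok)
        t = X @ w
        tt = t @ t
        l = X.T @ t / tt
        c = (y @ t) / tt
        if c < 0:  # orient positive scores toward the disease label
            w, t, l, c = -w, -t, -l, -c
        W[:, m], T[:, m], L[:, m], c_vec[m] = w, t, l, c
        U[:, m] = y * c
        X -= np.outer(t, l)
        y = y - t * c

    coef = W @ np.linalg.pinv(L.T @ W) @ c_vec
    return PLSModel(W=W, T=T, L=L, c=c_vec, U=U, coef=coef,
                    gene_ids=np.asarray(data.gene_ids, dtype=object),
                    x_mean=data.mean, x_sd=data.sd,
                    y_mean=data.y_mean, y_sd=data.y_sd,
                    n_components=n_components, converged=converged)


def _check_genes(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2 or X_new.shape[1] != model.W.shape[0]:
        raise ValueError(f"expected {model.W.shape[0]} gene columns, got "
                         f"{X_new.shape[1] if X_new.ndim == 2 else X_new.shape}")
    return X_new


def transform(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Per-cell component scores for new (already standardized) cells,
    using the fitted rotations (which account for deflation)."""
    return _check_genes(model, X_new) @ model.rotations


def predict_continuous(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Disease-confidence prediction on the standardized-label scale.

    A cell at the training mean (all-zero standardized row) predicts 0; the
    raw PLS output is an unbounded linear score, not a calibrated
    probability.
    """
    return _check_genes(model, X_new) @ model.coef


def predict_class(model: PLSModel, X_new: np.ndarray,
                  threshold: float = 0.0) -> np.ndarray:
    """+1 iff the continuous prediction exceeds ``threshold``; exact ties
    go to the control class (-1)."""
    return np.where(predict_continuous(model, X_new) > threshold, 1, -1)


def score_diagnosis_association(T: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|Pearson r| between each component's cell scores and the +1/-1
    diagnosis vector; components with zero score variance report NaN."""
    T = np.atleast_2d(np.asarray(T, dtype=float))
    if T.shape[0] == 1 and np.asarray(y).size != 1:
        T = T.T
    y = np.asarray(y, dtype=float)
    yc = y - y.mean()
    ysd = np.sqrt((yc ** 2).sum())
    out = np.full(T.shape[1], np.nan)
    for m in range(T.shape[1]):
        tc = T[:, m] - T[:, m].mean()
        tsd = np.sqrt((tc ** 2).sum())
        if tsd > 0 and ysd > 0:
            out[m] = abs(float(tc @ yc) / (tsd * ysd))
    return out


def pls_objective(X: np.ndarray, y: np.ndarray, alpha: np.ndarray) -> float:
    """Corr^2(y, X alpha) * Var(X alpha) for a unit direction alpha — the
    quantity each successive component maximizes."""
    t = np.asarray(X) @ (np.asarray(alpha) / np.linalg.norm(alpha))
    y = np.asarray(y, dtype=float)
    tc = t - t.mean()
    yc = y - y.mean()
    denom = np.sqrt((tc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        return 0.0
    corr = float(tc @ yc) / denom
    return corr ** 2 * float(tc.var())
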