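"""Bootstrap stability of the PLS loadings: the final gene modules.

Cells are resampled with replacement (stratified by diagnosis class, so the
balance the model was trained under is preserved), the model is refit with
the component count fixed at the full-data choice, and the loading of every
gene is collected across iterations. Because a loading vector is only
identified up to sign, each bootstrap replicate is aligned to the full-data
reference by cosine similarity before summarizing. A gene is silenced
(loading set to exactly zero) when its empirical 5/95% interval contains
zero or when any bootstrap replicate produced an exact zero for it (which
happens when the gene had no variance in that resample).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import pls
from .preprocess import drop_zero_variance, standardize


@dataclass
class BootstrapResult:
    loadings: np.ndarray        # (B, p, k)
    reference: np.ndarray       # (p, k) full-data loadings
    gene_ids: np.ndarray
    seed: int
    B: int
    aligned: np.ndarray | None = None  # (B, k) flip flags after alignment


@dataclass
class ModuleResult:
    """Per-gene, per-component bootstrap summary defining each module."""

    gene_ids: np.ndarray
    median: np.ndarray          # (p, k); exactly 0 where zeroed
    ci_low: np.ndarray
    ci_high: np.ndarray
    zero_mask: np.ndarray       # True -> silenced

    @property
    def n_components(self) -> int:
        return self.median.shape[1]

    def ranked_genes(self, component: int) -> pd.DataFrame:
        """Retained genes of one module, ranked by |median loading|
        descending (ties by symbol for determinism)."""
        keep = ~self.zero_mask[:, component]
        df = pd.DataFrame({
            "gene": self.gene_ids[keep],
            "median_loading": self.median[keep, component],
            "ci_low": self.ci_low[keep, component],
            "ci_high": self.ci_high[keep, component],
        })
        df["abs_loading"] = df["median_loading"].abs()
        df = df.sort_values(["abs_loading", "gene"],
                            ascending=[False, True]).drop(columns="abs_loading")
        return df.reset_index(drop=True)

    def table(self, component: int) -> pd.DataFrame:
        """Full per-gene table (gene, median_loading, ci_low, ci_high,
        zeroed) for one component."""
        return pd.DataFrame({
            "gene": self.gene_ids,
            "median_loading": self.median[:, component],
            "ci_low": self.ci_low[:, component],
            "ci_high": self.ci_high[:, component],
            "zeroed": self.zero_mask[:, component],
        })


def _fit_loadings(X: np.ndarray, y: np.ndarray, n_components: int) -> np.ndarray:
    """Standardize and fit; genes constant in this sample get loading
    exactly 0 (feeding the exact-zero exclusion rule)."""
    p = X.shape[1]
    Xk, keep_idx, _ = drop_zero_variance(X, np.arange(p))
    data = standardize(Xk, y)
    model = pls.fit_pls(data, n_components=n_components)
    out = np.zeros((p, n_components))
    out[keep_idx.astype(int), :] = model.L
    return out


def bootstrap_loadings(X: np.ndarray, y_labels: np.ndarray, n_components: int,
                       B: int = 1000, seed: int = 0,
                       gene_ids: np.ndarray | None = None) -> BootstrapResult:
    """Resample cells with replacement (per class) B times and refit."""
    X = np.asarray(X, dtype=float)
    y_labels = np.asarray(y_labels)
    p = X.shape[1]
    if gene_ids is None:
        gene_ids = np.array([f"g{i}" for i in range(p)], dtype=object)
    reference = _fit_loadings(X, y_labels, n_components)
    rng = np.random.default_rng(seed)
    class_idx = [np.flatnonzero(y_labels == cls) for cls in (-1, 1)]
    loadings = np.empty((B, p, n_components))
    for b in range(B):
        take = np.concatenate([idx[rng.integers(0, idx.size, idx.size)]
                               for idx in class_idx])
        loadings[b] = _fit_loadings(X[take], y_labels[take], n_components)
    return BootstrapResult(loadings=loadings, reference=reference,
                           gene_ids=np.asarray(gene_ids, dtype=object),
                           seed=seed, B=B)


def align_signs(boot: BootstrapResult) -> BootstrapResult:
    """Flip any replicate loading vector whose mirror is closer (cosine) to
    the reference; exact ties keep the original orientation."""
    aligned = np.array(boot.loadings, copy=True)
    flips = np.zeros((boot.B, boot.reference.shape[1]), dtype=bool)
    for m in range(boot.reference.shape[1]):
        ref = boot.reference[:, m]
        for b in range(boot.B):
            v = aligned[b, :, m]
            nv = np.linalg.norm(v)
            if nv == 0:
                warnings.warn(f"zero-norm bootstrap loading (iteration {b}, "
                              f"component {m}); left unflipped", stacklevel=2)
                continue
            # cosine(-v, ref) > cosine(v, ref)  <=>  v . ref < 0
            if float(v @ ref) < 0:
                aligned[b, :, m] = -v
                flips[b, m] = True
    return BootstrapResult(loadings=aligned, reference=boot.reference,
                           gene_ids=boot.gene_ids, seed=boot.seed, B=boot.B,
                           aligned=flips)


def select_genes(aligned: BootstrapResult, lo: float = 0.05,
                 hi: float = 0.95) -> ModuleResult:
    """Summarize aligned bootstrap distributions into the final modules.

    Quantiles use linear interpolation (type 7). The CI-contains-zero rule
    is inclusive at both ends.
    """
    qs = np.quantile(aligned.loadings, [lo, 0.5, hi], axis=0, method="linear")
    ci_low, median, ci_high = qs[0], qs[1], qs[2]
    spans_zero = (ci_low <= 0) & (ci_high >= 0)
    any_exact_zero = (aligned.loadings == 0).any(axis=0)
    zero_mask = spans_zero | any_exact_zero
    median = np.where(zero_mask, 0.0, median)
    return ModuleResult(gene_ids=aligned.gene_ids, median=median,
                        ci_low=ci_low, ci_high=ci_high, zero_mask=zero_mask)
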