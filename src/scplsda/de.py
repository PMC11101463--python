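"""Univariate differential expression and its comparison with modules.

Per gene: Wilcoxon rank-sum disease-vs-control on the log-normalized
expression (exact p for small tie-free samples, normal approximation with
tie correction otherwise), log2 fold-change of class means with a small
pseudocount, Benjamini-Hochberg adjustment. The module comparison
correlates bootstrap-median loadings (silenced genes at 0) with the
fold-change and intersects the top-k gene lists of the two rankings.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from .bootstrap import ModuleResult
from .progression import spearman

PSEUDOCOUNT = 1e-9


def wilcoxon_fold_change(expression: np.ndarray, diagnosis: np.ndarray,
                         gene_ids: np.ndarray) -> pd.DataFrame:
    """Rank-sum test and log2 fold-change per gene (disease vs control).

    Constant genes report p = 1 and fold-change 0.
    """
    X = np.asarray(expression, dtype=float)
    diagnosis = np.asarray(diagnosis)
    pos = diagnosis == 1
    neg = diagnosis == -1
    if pos.sum() < 2 or neg.sum() < 2:
        raise ValueError("need at least 2 cells per class")
    n_genes = X.shape[1]
    pvals = np.ones(n_genes)
    stats = np.zeros(n_genes)
    lfc = np.zeros(n_genes)
    for g in range(n_genes):
        a, b = X[pos, g], X[neg, g]
        if np.ptp(X[:, g]) == 0:
            continue
        res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided",
                                       method="auto")
        stats[g] = float(res.statistic)
        pvals[g] = float(res.pvalue)
        # normalized expression is non-negative; clip guards synthetic input
        lfc[g] = np.log2((max(a.mean(), 0.0) + PSEUDOCOUNT) /
                         (max(b.mean(), 0.0) + PSEUDOCOUNT))
    padj = scipy.stats.false_discovery_control(pvals, method="bh")
    return pd.DataFrame({
        "gene": np.asarray(gene_ids, dtype=object),
        "log2_fold_change": lfc,
        "statistic": stats,
        "pval": pvals,
        "padj": padj,
    })


def module_de_correlation(module: ModuleResult, de: pd.DataFrame
                          ) -> pd.DataFrame:
    """Spearman (primary) and Pearson rho between each module's loading
    vector (zeroed genes included at 0) and the per-gene fold-change, over
    the shared gene universe."""
    de_idx = de.set_index("gene")
    shared = [g for g in module.gene_ids if g in de_idx.index]
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared genes")
    fc = de_idx.loc[shared, "log2_fold_change"].to_numpy(dtype=float)
    pos = {g: i for i, g in enumerate(module.gene_ids)}
    rows = []
    for m in range(module.n_components):
        load = np.array([module.median[pos[g], m] for g in shared])
        if np.ptp(load) == 0 or np.ptp(fc) == 0:
            rows.append({"component": m, "spearman_rho": np.nan,
                         "pearson_r": np.nan, "degenerate": True})
            continue
        rows.append({
            "component": m,
            "spearman_rho": spearman(load, fc),
            "pearson_r": float(np.corrcoef(load, fc)[0, 1]),
            "degenerate": False,
        })
    return pd.DataFrame(rows)


def _top_k(genes: np.ndarray, values: np.ndarray, k: int) -> list[str]:
    """Top-k genes by descending value, ties broken by symbol."""
    genes = np.asarray(genes, dtype=object)
    values = np.asarray(values, dtype=float)
    order = np.lexsort((genes.astype(str), -values))
    return genes[order[:k]].tolist()


def top_overlap(module: ModuleResult, component: int, de: pd.DataFrame,
                k: int = 10) -> dict:
    """Intersect the top-k module genes (by |median loading|) with the top-k
    DE genes ranked by significance and, separately, by |fold-change|."""
    if len(module.gene_ids) < k or len(de) < k:
        raise ValueError("need at least k genes on both sides")
    top_module = set(_top_k(module.gene_ids,
                            np.abs(module.median[:, component]), k))
    top_sig = set(_top_k(de["gene"].to_numpy(),
                         -de["padj"].to_numpy(dtype=float), k))
    top_fc = set(_top_k(de["gene"].to_numpy(),
                        np.abs(de["log2_fold_change"].to_numpy(dtype=float)), k))
    return {
        "module_top": sorted(top_module),
        "overlap_significance": sorted(top_module & top_sig),
        "overlap_fold_change": sorted(top_module & top_fc),
    }


def marker_module_association(scores: np.ndarray, expression: np.ndarray,
                              gene_ids: np.ndarray,
                              marker_genes: list[str]) -> pd.DataFrame:
    """Spearman rho between each marker gene's per-cell normalized
    expression and each module's per-cell score; absent or constant markers
    report NaN with a flag."""
    T = np.atleast_2d(np.asarray(scores, dtype=float))
    if T.shape[0] == 1:
        T = T.T
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    rows = []
    for marker in marker_genes:
        for m in range(T.shape[1]):
            if marker not in gene_pos:
                rows.append({"marker": marker, "component": m,
                             "spearman_rho": np.nan, "missing": True})
                continue
            expr = np.asarray(expression[:, gene_pos[marker]]).ravel()
            rho = spearman(expr, T[:, m])
            rows.append({"marker": marker, "component": m,
                         "spearman_rho": rho, "missing": bool(np.isnan(rho))})
    return pd.DataFrame(rows)
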