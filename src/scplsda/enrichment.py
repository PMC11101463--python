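"""Preranked gene-set enrichment on bootstrap-median loadings.

Genes retained by the bootstrap are ranked by median loading (descending;
silenced genes are excluded). Each gene set is tested for concentration at
either end of the list with the weighted running-sum statistic: hits
increment proportionally to |score|^weight_exp (normalized over the set's
hits), misses decrement 1/(N - n_set); the enrichment score ES is the
extreme of the running sum. The null is n_perm random same-size gene
subsets of the ranked list; NES divides ES by the mean |null ES| of the
matching sign; p is the sign-matched empirical tail with +1 smoothing; the
FDR q compares the observed NES with the pooled normalized null the way the
classic GSEA procedure does.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bootstrap import ModuleResult
from .datatypes import GeneSetDB

logger = logging.getLogger(__name__)


@dataclass
class RankedList:
    """Ordered (gene, score) pairs, descending score, no zeros, no dupes.
    Equal scores break ties by gene symbol for determinism."""

    genes: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranked list")
        if (self.scores == 0).any():
            raise ValueError("zero scores are excluded from the ranked list")
        order = np.lexsort((self.genes.astype(str), -self.scores))
        self.genes = self.genes[order]
        self.scores = self.scores[order]

    def __len__(self) -> int:
        return len(self.genes)


def ranked_list_from_module(result: ModuleResult, component: int) -> RankedList:
    keep = ~result.zero_mask[:, component]
    if not keep.any():
        raise ValueError(f"component {component} retained no genes")
    return RankedList(genes=result.gene_ids[keep],
                      scores=result.median[keep, component])


@dataclass
class EnrichmentRecord:
    set_name: str
    es: float
    nes: float
    pval: float
    fdr_q: float
    genes: frozenset
    size: int


def _es_from_positions(pos_sorted: np.ndarray, weights: np.ndarray,
                       n_total: int) -> np.ndarray:
    """Signed ES for each row of sorted hit positions.

    The running sum is piecewise linear and decreasing between hits, so its
    extremes occur immediately after a hit (candidate maxima) or immediately
    before one (candidate minima); this evaluates only those points.
    ``weights`` are the per-hit increments, already normalized to sum 1 per
    row. Ties between the positive and negative extreme resolve positive.
    """
    n_hit = pos_sorted.shape[1]
    miss_dec = 1.0 / (n_total - n_hit) if n_total > n_hit else 0.0
    wcum = np.cumsum(weights, axis=1)
    i = np.arange(1, n_hit + 1)
    misses_before = pos_sorted - (i - 1)  # misses strictly before each hit
    after_hit = wcum - misses_before * miss_dec      # value just after hit i
    before_hit = after_hit - weights                 # value just before hit i
    max_pos = after_hit.max(axis=1)
    min_neg = np.minimum(before_hit.min(axis=1), 0.0)
    # positive on a tie; the small tolerance keeps exact rational ties
    # (e.g. ES = +-k/(N-k)) deterministic under float round-off
    return np.where(max_pos >= -min_neg - 1e-12, max_pos, min_neg)


def enrichment_score(ranked: RankedList, members: frozenset,
                     weight_exp: float = 1.0) -> float:
    """ES of one gene set against the ranked list."""
    hit = np.isin(ranked.genes, list(members))
    pos = np.flatnonzero(hit)
    if pos.size == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    w = np.abs(ranked.scores[pos]) ** weight_exp
    w = w / w.sum()
    return float(_es_from_positions(pos[None, :], w[None, :], len(ranked))[0])


def _null_es(ranked: RankedList, size: int, n_perm: int, weight_exp: float,
             rng: np.random.Generator) -> np.ndarray:
    """Null ES for ``n_perm`` random same-size subsets of the ranked list."""
    n = len(ranked)
    keys = rng.random((n_perm, n))
    idx = np.argpartition(keys, size - 1, axis=1)[:, :size]
    idx = np.sort(idx, axis=1)
    w = np.abs(ranked.scores[idx]) ** weight_exp
    w = w / w.sum(axis=1, keepdims=True)
    return _es_from_positions(idx, w, n)


def gsea_prerank(ranked: RankedList, db: GeneSetDB, min_size: int = 5,
                 n_perm: int = 1000, weight_exp: float = 1.0,
                 seed: int = 0) -> list[EnrichmentRecord]:
    """Test every gene set of the database against the ranked list."""
    rng = np.random.default_rng(seed)
    gene_index = set(ranked.genes)
    kept: list[tuple[str, frozenset, int]] = []
    for name in sorted(db.names()):
        overlap = db.members(name) & gene_index
        if not overlap:
            logger.info("gene set %r has no overlap with the ranked list; "
                        "skipped", name)
            continue
        if len(overlap) < min_size:
            continue
        kept.append((name, frozenset(overlap), len(overlap)))
    if not kept:
        return []

    null_by_size: dict[int, np.ndarray] = {}
    for size in sorted({k[2] for k in kept}):
        null_by_size[size] = _null_es(ranked, size, n_perm, weight_exp, rng)

    # sign-matched normalization constants per size
    norm_by_size: dict[int, tuple[float, float]] = {}
    null_nes_pool: list[np.ndarray] = []
    for size, null in null_by_size.items():
        pos = null[null > 0]
        neg = null[null < 0]
        mean_pos = float(pos.mean()) if pos.size else np.nan
        mean_neg = float(np.abs(neg).mean()) if neg.size else np.nan
        norm_by_size[size] = (mean_pos, mean_neg)
        nn = np.where(null >= 0,
                      null / mean_pos if np.isfinite(mean_pos) else np.nan,
                      null / mean_neg if np.isfinite(mean_neg) else np.nan)
        null_nes_pool.append(nn[np.isfinite(nn)])
    pool = np.concatenate(null_nes_pool) if null_nes_pool else np.empty(0)

    records = []
    for name, overlap, size in kept:
        pos = np.sort(np.flatnonzero(np.isin(ranked.genes, list(overlap))))
        w = np.abs(ranked.scores[pos]) ** weight_exp
        w = w / w.sum()
        es = float(_es_from_positions(pos[None, :], w[None, :], len(ranked))[0])
        null = null_by_size[size]
        mean_pos, mean_neg = norm_by_size[size]
        same_sign = null >= 0 if es >= 0 else null < 0
        n_same = int(same_sign.sum())
        n_extreme = int((np.abs(null[same_sign]) >= abs(es)).sum())
        pval = (1 + n_extreme) / (1 + n_same)
        denom = mean_pos if es >= 0 else mean_neg
        nes = es / denom if np.isfinite(denom) and denom > 0 else np.nan
        records.append(EnrichmentRecord(set_name=name, es=es, nes=nes,
                                        pval=pval, fdr_q=np.nan,
                                        genes=overlap, size=size))

    obs_nes = np.array([r.nes for r in records])
    for r in records:
        if not np.isfinite(r.nes):
            r.fdr_q = 1.0
            continue
        if r.nes >= 0:
            frac_null = float((pool >= r.nes).mean()) if pool.size else 1.0
            n_obs = int((obs_nes[np.isfinite(obs_nes)] >= r.nes).sum())
        else:
            frac_null = float((pool <= r.nes).mean()) if pool.size else 1.0
            n_obs = int((obs_nes[np.isfinite(obs_nes)] <= r.nes).sum())
        frac_obs = n_obs / max(1, int(np.isfinite(obs_nes).sum()))
        r.fdr_q = float(min(1.0, frac_null / frac_obs)) if frac_obs > 0 else 1.0
    return records


def filter_fdr(records: list[EnrichmentRecord],
               alpha: float = 0.05) -> list[EnrichmentRecord]:
    """Keep records with q strictly below alpha."""
    return [r for r in records if r.fdr_q < alpha]


def overlap_ratio(a: frozenset, b: frozenset) -> float:
    """Shared genes over the size of the smaller set."""
    smaller = min(len(a), len(b))
    if smaller == 0:
        return 0.0
    return len(a & b) / smaller


def remove_redundant(records: list[EnrichmentRecord],
                     overlap_threshold: float = 0.9) -> list[EnrichmentRecord]:
    """Greedy de-duplication: scan in descending |NES| (ties by name); a set
    whose overlap ratio with an already-kept set exceeds the threshold is
    dropped (the less-enriched of the pair)."""
    order = sorted(records, key=lambda r: (-abs(r.nes) if np.isfinite(r.nes)
                                           else 0.0, r.set_name))
    kept: list[EnrichmentRecord] = []
    for rec in order:
        if all(overlap_ratio(rec.genes, k.genes) <= overlap_threshold
               for k in kept):
            kept.append(rec)
    return kept


def _keyword_matches(keyword: str, name: str) -> bool:
    name_l = name.lower()
    kw = keyword.lower()
    if kw.endswith("*"):
        prefix = kw[:-1]
        tokens = re.split(r"[^a-z0-9]+", name_l)
        return any(tok.startswith(prefix) for tok in tokens if tok)
    return kw in name_l


def keyword_search(records_per_module: dict[str, list[EnrichmentRecord]],
                   keywords: list[str]) -> pd.DataFrame:
    """Chart which modules carry annotations matching each keyword.

    A trailing ``*`` makes the keyword a prefix match on any token of the
    set name; otherwise it is a case-insensitive substring. The reported hit
    per (keyword, module) is the most significant matching record (smallest
    p, then largest |NES|). Returns a long-format table with columns
    keyword, module, set_name, nes, neg_log10_p; keywords or modules with no
    match simply contribute no rows.
    """
    rows = []
    for kw in keywords:
        for module, records in records_per_module.items():
            hits = [r for r in records if _keyword_matches(kw, r.set_name)]
            if not hits:
                continue
            best = min(hits, key=lambda r: (r.pval,
                                            -abs(r.nes) if np.isfinite(r.nes)
                                            else 0.0, r.set_name))
            rows.append({"keyword": kw, "module": module,
                         "set_name": best.set_name, "nes": best.nes,
                         "neg_log10_p": float(-np.log10(max(best.pval, 1e-300)))})
    return pd.DataFrame(rows, columns=["keyword", "module", "set_name", "nes",
                                       "neg_log10_p"])


def records_to_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    cols = ["set_name", "es", "nes", "pval", "fdr_q", "size", "genes"]
    if not records:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([{
        "set_name": r.set_name,
        "es": r.es,
        "nes": r.nes,
        "pval": r.pval,
        "fdr_q": r.fdr_q,
        "size": r.size,
        "genes": ";".join(sorted(r.genes)),
    } for r in records])
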