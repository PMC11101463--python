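"""Localize GWAS risk loci to enriched leaf gene sets per module.

Because ontologies are hierarchical, an enriched superset mostly restates
its enriched subsets; only the leaves (enriched sets that are not strict
supersets of another enriched set in the same module) are counted. The map
counts, per (cell-type, module), how many leaf sets contain each risk
locus; loci absent from the expression data are flagged "not captured".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import EnrichmentRecord


def leaf_filter(records: list[EnrichmentRecord]) -> list[EnrichmentRecord]:
    """Drop every enriched set that is a strict superset of another enriched
    set; equal member sets under different names both survive. Idempotent."""
    out = []
    for rec in records:
        strict_super = any(
            other is not rec
            and other.genes < rec.genes
            for other in records
        )
        if not strict_super:
            out.append(rec)
    return out


@dataclass
class RiskLocusMap:
    counts: pd.DataFrame        # loci x modules, integer counts
    supporting_sets: dict       # (locus, module) -> sorted set names
    not_captured: list          # loci absent from the expression gene universe


def count_locus_occurrences(leaf_records_per_module: dict[str, list[EnrichmentRecord]],
                            risk_loci: list[str],
                            gene_universe: set | None = None) -> RiskLocusMap:
    """Count, per module, the leaf sets containing each risk locus."""
    modules = list(leaf_records_per_module)
    counts = pd.DataFrame(0, index=list(risk_loci), columns=modules, dtype=int)
    supporting: dict[tuple[str, str], list[str]] = {}
    for module, records in leaf_records_per_module.items():
        for locus in risk_loci:
            names = sorted(r.set_name for r in records if locus in r.genes)
            counts.loc[locus, module] = len(names)
            if names:
                supporting[(locus, module)] = names
    if gene_universe is not None:
        not_captured = [g for g in risk_loci if g not in gene_universe]
    else:
        seen = set().union(*[r.genes for recs in leaf_records_per_module.values()
                             for r in recs]) if leaf_records_per_module else set()
        not_captured = [g for g in risk_loci
                        if g not in seen and counts.loc[g].sum() == 0]
    return RiskLocusMap(counts=counts, supporting_sets=supporting,
                        not_captured=not_captured)
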