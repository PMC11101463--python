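"""Stage orchestration: simulate -> preprocess -> fit -> bootstrap -> gsea
-> progression -> coordination -> riskmap -> de-compare.

Each stage reads the artifacts of its predecessors from the output
directory and fails with a stage-dependency error when they are missing,
so stages can also be run one at a time from the command line. Result
tables are TSV with a header row, summary metrics JSON; binary working
arrays live under ``work/`` and are not part of the result bundle. A rerun
with the same configuration and seeds reproduces the result bundle
byte-for-byte.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import bootstrap as bs
from . import coordination as coord
from . import de as de_mod
from . import enrichment as enr
from . import io
from . import model_selection as ms
from . import pls
from . import preprocess as pp
from . import progression as prog
from . import riskmap as rm
from . import simulate as sim
from .config import RunConfig
from .datatypes import GeneSetDB

logger = logging.getLogger(__name__)


class StageDependencyError(RuntimeError):
    """An upstream artifact required by this stage is missing."""


def _need(path: Path, stage: str) -> Path:
    if not path.exists():
        raise StageDependencyError(f"stage {stage!r} needs missing artifact "
                                   f"{path}; run the upstream stage first")
    return path


def _dirs(out_dir: str | Path) -> tuple[Path, Path, Path]:
    out = Path(out_dir)
    inputs, work, results = out / "inputs", out / "work", out / "results"
    for d in (out, inputs, work, results):
        d.mkdir(parents=True, exist_ok=True)
    return inputs, work, results


# ---------------------------------------------------------------- simulate

def stage_simulate(cfg: RunConfig, out_dir: str | Path) -> None:
    inputs, _, _ = _dirs(out_dir)
    spec = sim.CohortSpec(**cfg.cohort)
    seed = cfg.seeds["simulate"]
    subjects, markers, severity = sim.generate_cohort(spec, seed)
    modules = sim.make_default_modules(spec, seed + 1,
                                       n_modules_per_type=cfg.n_modules_per_type,
                                       module_size=cfg.module_size,
                                       effect_size=cfg.effect_size)
    cm, cells = sim.generate_expression(subjects, modules, spec, seed + 2)
    db = sim.generate_genesets(spec.n_genes, modules, cfg.n_null_sets,
                               cfg.n_supersets, seed + 3)
    loci = sim.generate_risk_loci(modules, cfg.n_risk_in_module,
                                  cfg.n_risk_outside, seed + 4, spec.n_genes)
    io.write_count_matrix(cm, inputs / "counts.mtx", inputs / "genes.tsv",
                          inputs / "cells.tsv")
    io.write_cell_metadata(cells, inputs / "cell_metadata.tsv")
    io.write_subject_markers(markers, inputs / "markers.tsv")
    io.write_gmt(db, inputs / "genesets.gmt")
    io.write_table(loci, inputs / "risk_loci.tsv")
    symbols = sim.gene_symbols(spec.n_genes)
    io.write_json({
        "planted_modules": [{
            "cell_type": m.cell_type,
            "genes": sorted(symbols[m.gene_indices]),
            "effect_size": m.effect_size,
        } for m in modules],
        "severity": {s: float(v) for s, v in zip(subjects["subject_id"],
                                                 severity)},
    }, inputs / "ground_truth.json")


# -------------------------------------------------------------- preprocess

def stage_preprocess(cfg: RunConfig, out_dir: str | Path) -> None:
    inputs, work, results = _dirs(out_dir)
    cm = io.read_count_matrix(_need(inputs / "counts.mtx", "preprocess"),
                              _need(inputs / "genes.tsv", "preprocess"),
                              _need(inputs / "cells.tsv", "preprocess"))
    meta = io.read_cell_metadata(_need(inputs / "cell_metadata.tsv",
                                       "preprocess"))
    meta = meta.set_index("cell_id").loc[[str(c) for c in cm.cell_ids]] \
        .reset_index()
    norm = pp.normalize_log1p(cm, target_sum=cfg.target_sum)
    # the one global shuffle, before any per-type work
    perm = pp.shuffle_once(cm.n_cells, cfg.seeds["shuffle"])
    norm = norm[perm]
    meta = meta.iloc[perm].reset_index(drop=True)

    provenance = {}
    for ct in sorted(meta["cell_type"].unique()):
        rows = np.flatnonzero((meta["cell_type"] == ct).to_numpy())
        sub = norm[rows]
        filtered, genes = pp.filter_genes_min_cells(sub, cm.gene_ids,
                                                    min_fraction=cfg.min_cell_fraction)
        labels = meta["diagnosis"].to_numpy()[rows]
        keep = pp.balance_classes(labels, cfg.seeds["balance"])
        X = filtered[keep].toarray().astype(float)
        sel = rows[keep]
        np.savez(work / f"{ct}.npz",
                 X=X, genes=genes.astype(str),
                 labels=labels[keep],
                 subjects=meta["subject_id"].to_numpy()[sel].astype(str),
                 cell_ids=meta["cell_id"].to_numpy()[sel].astype(str))
        provenance[ct] = {
            "n_cells_total": int(rows.size),
            "n_cells_balanced": int(keep.size),
            "n_genes_kept": int(genes.size),
            "n_genes_dropped": int(cm.n_genes - genes.size),
        }
    io.write_json(provenance, results / "preprocess_provenance.json")


def _load_ct(work: Path, ct: str, stage: str) -> dict:
    data = np.load(_need(work / f"{ct}.npz", stage), allow_pickle=False)
    return {k: data[k] for k in data.files}


def _cell_types(work: Path, stage: str) -> list[str]:
    cts = sorted(p.stem for p in work.glob("*.npz")
                 if not p.stem.startswith("modules_"))
    if not cts:
        raise StageDependencyError(f"stage {stage!r} found no preprocessed "
                                   f"cell-types under {work}")
    return cts


# --------------------------------------------------------------------- fit

def stage_fit(cfg: RunConfig, out_dir: str | Path) -> None:
    _, work, results = _dirs(out_dir)
    selection = {}
    for ct in _cell_types(work, "fit"):
        d = _load_ct(work, ct, "fit")
        labels = d["labels"].astype(int)
        cv = ms.nested_cv(d["X"], labels, grid=cfg.component_grid,
                          outer_k=cfg.outer_k, inner_k=cfg.inner_k,
                          seed=cfg.seeds["cv"], cell_type=ct)
        io.write_table(pd.DataFrame({
            "cell_id": d["cell_ids"],
            "subject_id": d["subjects"],
            "cell_type": ct,
            "fold": cv.fold_assignment,
            "prediction": cv.oos_prediction,
        }), results / f"predictions_{ct}.tsv")

        # full-data reference fit at the selected component count
        Xz, gidx, _ = pp.drop_zero_variance(d["X"], np.arange(d["X"].shape[1]))
        data = pp.standardize(Xz, labels, gene_ids=d["genes"][gidx.astype(int)])
        model = pls.fit_pls(data, n_components=cv.n_components)
        assoc = pls.score_diagnosis_association(model.T, labels)
        io.write_table(pd.DataFrame({
            "component": np.arange(cv.n_components),
            "diagnosis_association": assoc,
        }), results / f"module_association_{ct}.tsv")
        np.save(work / f"scores_{ct}.npy", model.T)

        selection[ct] = {
            "n_components": cv.n_components,
            "fold_choices": [int(c) for c in cv.fold_choices],
            "auroc_mean": cv.auroc_mean,
            "auroc_sd": cv.auroc_sd,
            "fold_aurocs": [float(a) for a in cv.fold_aurocs],
            "fold_r2": [float(r) for r in cv.fold_r2],
        }
    io.write_json(selection, results / "cv_selection.json")


# --------------------------------------------------------------- bootstrap

def stage_bootstrap(cfg: RunConfig, out_dir: str | Path) -> None:
    _, work, results = _dirs(out_dir)
    selection = io.read_json(_need(results / "cv_selection.json", "bootstrap"))
    for ct in _cell_types(work, "bootstrap"):
        d = _load_ct(work, ct, "bootstrap")
        k = selection[ct]["n_components"]
        boot = bs.bootstrap_loadings(d["X"], d["labels"].astype(int), k,
                                     B=cfg.n_bootstrap,
                                     seed=cfg.seeds["bootstrap"],
                                     gene_ids=d["genes"])
        modules = bs.select_genes(bs.align_signs(boot), lo=cfg.ci_lo,
                                  hi=cfg.ci_hi)
        np.savez(work / f"modules_{ct}.npz", median=modules.median,
                 ci_low=modules.ci_low, ci_high=modules.ci_high,
                 zero_mask=modules.zero_mask,
                 genes=modules.gene_ids.astype(str))
        for m in range(k):
            io.write_table(modules.table(m), results / f"modules_{ct}_m{m}.tsv")


def _load_modules(work: Path, ct: str, stage: str) -> bs.ModuleResult:
    d = np.load(_need(work / f"modules_{ct}.npz", stage), allow_pickle=False)
    return bs.ModuleResult(gene_ids=d["genes"].astype(object),
                           median=d["median"], ci_low=d["ci_low"],
                           ci_high=d["ci_high"], zero_mask=d["zero_mask"])


# -------------------------------------------------------------------- gsea

def _records_from_frame(df: pd.DataFrame) -> list[enr.EnrichmentRecord]:
    return [enr.EnrichmentRecord(
        set_name=row.set_name, es=row.es, nes=row.nes, pval=row.pval,
        fdr_q=row.fdr_q, genes=frozenset(str(row.genes).split(";")),
        size=int(row.size)) for row in df.itertuples(index=False)]


def stage_gsea(cfg: RunConfig, out_dir: str | Path) -> None:
    inputs, work, results = _dirs(out_dir)
    db = io.read_gmt(_need(inputs / "genesets.gmt", "gsea"))
    per_module: dict[str, list[enr.EnrichmentRecord]] = {}
    for ct in _cell_types(work, "gsea"):
        modules = _load_modules(work, ct, "gsea")
        for m in range(modules.n_components):
            key = f"{ct}::m{m}"
            try:
                ranked = enr.ranked_list_from_module(modules, m)
            except ValueError:
                logger.warning("module %s retained no genes; skipped", key)
                continue
            records = enr.gsea_prerank(ranked, db, min_size=cfg.min_set_size,
                                       n_perm=cfg.n_perm,
                                       weight_exp=cfg.weight_exp,
                                       seed=cfg.seeds["gsea"])
            io.write_table(enr.records_to_frame(records),
                           results / f"enrichment_{ct}_m{m}.tsv")
            filtered = enr.remove_redundant(
                enr.filter_fdr(records, alpha=cfg.fdr_alpha),
                overlap_threshold=cfg.overlap_threshold)
            io.write_table(enr.records_to_frame(filtered),
                           results / f"enrichment_filtered_{ct}_m{m}.tsv")
            per_module[key] = filtered
    hits = enr.keyword_search(per_module, cfg.keywords)
    io.write_table(hits, results / "keyword_hits.tsv")


def _filtered_records(results: Path, work: Path, stage: str
                      ) -> dict[str, list[enr.EnrichmentRecord]]:
    out = {}
    for ct in _cell_types(work, stage):
        modules = _load_modules(work, ct, stage)
        for m in range(modules.n_components):
            path = results / f"enrichment_filtered_{ct}_m{m}.tsv"
            if not path.exists():
                continue
            df = pd.read_csv(path, sep="\t")
            out[f"{ct}::m{m}"] = _records_from_frame(df) if len(df) else []
    if not out:
        raise StageDependencyError(f"stage {stage!r} found no filtered "
                                   "enrichment results; run gsea first")
    return out


# -------------------------------------------------------------- progression

def stage_progression(cfg: RunConfig, out_dir: str | Path) -> None:
    inputs, work, results = _dirs(out_dir)
    meta = io.read_cell_metadata(_need(inputs / "cell_metadata.tsv",
                                       "progression"))
    frames = []
    for ct in _cell_types(work, "progression"):
        path = _need(results / f"predictions_{ct}.tsv", "progression")
        frames.append(pd.read_csv(path, sep="\t",
                                  dtype={"cell_id": str, "subject_id": str}))
    preds = pd.concat(frames, ignore_index=True)
    conf = prog.aggregate_confidence(preds[["cell_id", "cell_type",
                                            "prediction"]], meta)
    io.write_table(pd.DataFrame(conf.matrix, index=conf.cell_types,
                                columns=conf.subject_ids)
                   .rename_axis("cell_type").reset_index(),
                   results / "subject_confidence.tsv")
    diagnosis = meta.drop_duplicates("subject_id").set_index("subject_id")[
        "diagnosis"]
    pp_result = prog.pseudo_progression_pc1(conf, diagnosis)
    io.write_table(pd.DataFrame({
        "subject_id": pp_result.subject_ids,
        "score": pp_result.score,
        "rank": pp_result.rank,
        "diagnosis": diagnosis.reindex(pp_result.subject_ids).to_numpy(),
    }), results / "progression_scores.tsv")
    markers = io.read_subject_markers(_need(inputs / "markers.tsv",
                                            "progression"))
    io.write_table(prog.validate_markers(pp_result, markers),
                   results / "marker_correlations.tsv")


# ------------------------------------------------------------- coordination

def stage_coordination(cfg: RunConfig, out_dir: str | Path) -> None:
    _, work, results = _dirs(out_dir)
    records = _filtered_records(results, work, "coordination")
    activities = []
    for key, recs in records.items():
        if not recs:
            logger.info("module %s has no enriched sets; skipped", key)
            continue
        ct, mlabel = key.split("::")
        d = _load_ct(work, ct, "coordination")
        Xz, gidx, _ = pp.drop_zero_variance(d["X"], np.arange(d["X"].shape[1]))
        data = pp.standardize(Xz, d["labels"].astype(int),
                              gene_ids=d["genes"][gidx.astype(int)])
        top = coord.select_top_sets(recs, k=cfg.top_k_sets,
                                    rank_by=cfg.rank_sets_by)
        by_name = {r.set_name: r for r in recs}
        cols, names = [], []
        for name in top:
            act = coord.geneset_activity(data, by_name[name].genes,
                                         d["subjects"])
            if act is not None:
                cols.append(act)
                names.append(name)
        if not cols:
            continue
        subject_ids = sorted(set(d["subjects"].astype(str)))
        am = coord.ActivityMatrix(values=np.column_stack(cols),
                                  subject_ids=subject_ids, set_names=names,
                                  cell_type=ct, module=int(mlabel[1:]))
        activities.append(am)
        io.write_table(pd.DataFrame(am.values, index=subject_ids,
                                    columns=names)
                       .rename_axis("subject_id").reset_index(),
                       results / f"activity_{ct}_{mlabel}.tsv")
    if len({a.cell_type for a in activities}) >= 2:
        mat = coord.coordination_matrix(activities)
        io.write_table(mat.rename_axis("module").reset_index(),
                       results / "coordination.tsv")
    else:
        logger.warning("fewer than 2 cell-types with activities; "
                       "coordination matrix not computed")


# ------------------------------------------------------------------ riskmap

def stage_riskmap(cfg: RunConfig, out_dir: str | Path) -> None:
    inputs, work, results = _dirs(out_dir)
    loci = io.read_risk_loci(_need(inputs / "risk_loci.tsv", "riskmap"))
    records = _filtered_records(results, work, "riskmap")
    leaves = {key: rm.leaf_filter(recs) for key, recs in records.items()}
    universe = set()
    for ct in _cell_types(work, "riskmap"):
        universe |= set(_load_ct(work, ct, "riskmap")["genes"].astype(str))
    result = rm.count_locus_occurrences(leaves, loci["gene"].tolist(),
                                        gene_universe=universe)
    io.write_table(result.counts.rename_axis("locus").reset_index(),
                   results / "riskmap.tsv")
    io.write_json({
        "not_captured": result.not_captured,
        "supporting_sets": {f"{locus}|{module}": names for
                            (locus, module), names in
                            result.supporting_sets.items()},
    }, results / "riskmap_meta.json")


# ----------------------------------------------------------------- de-compare

def stage_de(cfg: RunConfig, out_dir: str | Path) -> None:
    _, work, results = _dirs(out_dir)
    corr_frames = []
    overlaps = {}
    for ct in _cell_types(work, "de-compare"):
        d = _load_ct(work, ct, "de-compare")
        de = de_mod.wilcoxon_fold_change(d["X"], d["labels"].astype(int),
                                         d["genes"])
        io.write_table(de, results / f"de_{ct}.tsv")
        modules = _load_modules(work, ct, "de-compare")
        corr = de_mod.module_de_correlation(modules, de)
        corr.insert(0, "cell_type", ct)
        corr_frames.append(corr)
        for m in range(modules.n_components):
            overlaps[f"{ct}::m{m}"] = de_mod.top_overlap(modules, m, de,
                                                         k=cfg.top_k_genes)
    io.write_table(pd.concat(corr_frames, ignore_index=True),
                   results / "de_module_correlation.tsv")
    io.write_json(overlaps, results / "top_overlap.json")


STAGES = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "fit": stage_fit,
    "bootstrap": stage_bootstrap,
    "gsea": stage_gsea,
    "progression": stage_progression,
    "coordination": stage_coordination,
    "riskmap": stage_riskmap,
    "de-compare": stage_de,
}


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Run every stage in order and return the summary (also written to
    results/summary.json)."""
    for name, stage in STAGES.items():
        logger.info("stage %s", name)
        stage(cfg, out_dir)
    _, work, results = _dirs(out_dir)
    selection = io.read_json(results / "cv_selection.json")
    markers = pd.read_csv(results / "marker_correlations.tsv", sep="\t")
    summary = {
        "cell_types": list(selection),
        "auroc_mean": {ct: s["auroc_mean"] for ct, s in selection.items()},
        "n_components": {ct: s["n_components"] for ct, s in selection.items()},
        "marker_spearman": {row.marker: float(row.spearman_rho)
                            for row in markers.itertuples(index=False)},
    }
    io.write_json(summary, results / "summary.json")
    return summary
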