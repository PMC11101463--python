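"""Synthetic cohorts with planted disease-predictive gene modules.

The generator emulates the statistical structure the downstream analysis
assumes: a balanced case/control cohort in which each disease subject carries
a latent severity, cell-type-specific gene modules whose expression shifts
scale with that severity, negative-binomial counts with library-size
variation, pathology/cognition markers that are noisy monotone functions of
severity, a gene-set database with signal sets, supersets and null sets, and
a risk-locus list partially inside the planted modules.

Severity model: controls draw |N(0, 0.2^2)| (near-zero pathology), cases draw
1 + |N(0, 0.5^2)| — disjoint classes at the default effect size but with a
within-case gradient that pseudo-progression must recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import CountMatrix, GeneSetDB


@dataclass
class ModuleSpec:
    """A planted gene module: the genes of one cell-type whose expression
    shifts (log-scale, per unit severity) in disease."""

    cell_type: str
    gene_indices: np.ndarray
    effect_size: float = 1.5
    directions: np.ndarray | None = None  # +1 up / -1 down per gene
    subject_factor: np.ndarray | None = None  # per-subject driver; None -> severity

    def __post_init__(self) -> None:
        self.gene_indices = np.asarray(self.gene_indices, dtype=int)
        if self.gene_indices.size == 0:
            raise ValueError("empty module")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.directions is None:
            self.directions = np.ones(self.gene_indices.size, dtype=float)
        self.directions = np.asarray(self.directions, dtype=float)
        if self.directions.shape != self.gene_indices.shape:
            raise ValueError("directions must match gene_indices")


@dataclass
class CohortSpec:
    """Desk-scale defaults: 48 subjects (half cases), 6 cell-types,
    30 cells per subject per type, 2,000 genes."""

    n_subjects: int = 48
    prop_ad: float = 0.5
    control_severity_sd: float = 0.2
    ad_severity_shift: float = 1.0
    ad_severity_sd: float = 0.5
    marker_noise_sd: float = 0.3
    n_cell_types: int = 6
    cells_per_subject_per_type: int = 30
    n_genes: int = 2000
    nb_dispersion: float = 10.0  # NB size parameter; inf -> Poisson
    libsize_log_sd: float = 0.3
    baseline_log_mean: float = float(np.log(0.3))
    baseline_log_sd: float = 1.0
    near_zero_fraction: float = 0.05  # genes with ~zero baseline, exercises the detection filter

    def __post_init__(self) -> None:
        if self.n_subjects < 4:
            raise ValueError("n_subjects must be >= 4")
        if not 0.0 < self.prop_ad < 1.0:
            raise ValueError("prop_ad must be in (0, 1)")
        for name in ("control_severity_sd", "ad_severity_sd", "marker_noise_sd",
                     "libsize_log_sd", "baseline_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def cell_types(self) -> list[str]:
        return [f"type{i}" for i in range(self.n_cell_types)]


def gene_symbols(n_genes: int) -> np.ndarray:
    return np.array([f"G{i:05d}" for i in range(n_genes)], dtype=object)


def _quantile_bin(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Ordinal scores by quantile binning (rank-based, ties share a bin)."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(len(values))
    return np.minimum((ranks * n_bins) // len(values), n_bins - 1)


def generate_cohort(spec: CohortSpec, seed: int
                    ) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Draw subjects, diagnoses, latent severities and noisy markers.

    Returns (subjects, markers, severity). ``subjects`` has one row per
    subject with columns subject_id, diagnosis (+1 case / -1 control) and
    severity. Markers are monotone in severity (cognition decreasing, the
    rest increasing) with Gaussian noise on the latent scale; Braak (0-6)
    and CERAD (1-4) are produced by quantile binning of a noisy latent.
    """
    rng = np.random.default_rng(seed)
    n_ad = int(round(spec.n_subjects * spec.prop_ad))
    n_ctl = spec.n_subjects - n_ad
    if n_ad == 0 or n_ctl == 0:
        raise ValueError("prop_ad leaves one diagnosis class empty")
    diagnosis = np.array([1] * n_ad + [-1] * n_ctl)
    severity = np.where(
        diagnosis == 1,
        spec.ad_severity_shift + np.abs(rng.normal(0.0, spec.ad_severity_sd,
                                                   spec.n_subjects)),
        np.abs(rng.normal(0.0, spec.control_severity_sd, spec.n_subjects)),
    )
    subject_ids = np.array([f"S{i:03d}" for i in range(spec.n_subjects)],
                           dtype=object)
    sd = spec.marker_noise_sd
    noise = rng.normal(0.0, 1.0, size=(5, spec.n_subjects))
    tangles = np.exp(severity + sd * noise[0])
    amyloid = np.exp(0.8 * severity + sd * noise[1])
    cognition = -severity + sd * noise[2]
    braak = _quantile_bin(severity + sd * noise[3], 7)
    cerad = _quantile_bin(severity + sd * noise[4], 4) + 1
    subjects = pd.DataFrame({
        "subject_id": subject_ids,
        "diagnosis": diagnosis,
        "severity": severity,
    })
    markers = pd.DataFrame({
        "subject_id": subject_ids,
        "braak": braak,
        "cerad": cerad,
        "cognition": cognition,
        "tangles": tangles,
        "amyloid": amyloid,
    })
    return subjects, markers, severity


def make_default_modules(spec: CohortSpec, seed: int, n_modules_per_type: int = 2,
                         module_size: int = 50, effect_size: float = 1.5,
                         prop_up: float = 0.7) -> list[ModuleSpec]:
    """Plant disjoint modules per cell-type among the well-expressed genes."""
    rng = np.random.default_rng(seed)
    n_eligible = int(spec.n_genes * (1 - spec.near_zero_fraction))
    modules = []
    for ct in spec.cell_types:
        chosen = rng.choice(n_eligible, size=n_modules_per_type * module_size,
                            replace=False)
        for m in range(n_modules_per_type):
            idx = np.sort(chosen[m * module_size:(m + 1) * module_size])
            directions = rng.choice([1.0, -1.0], size=module_size,
                                    p=[prop_up, 1 - prop_up])
            modules.append(ModuleSpec(cell_type=ct, gene_indices=idx,
                                      effect_size=effect_size,
                                      directions=directions))
    return modules


def generate_expression(subjects: pd.DataFrame, modules: list[ModuleSpec],
                        spec: CohortSpec, seed: int
                        ) -> tuple[CountMatrix, pd.DataFrame]:
    """Sample negative-binomial counts for every cell.

    The mean of gene g in cell i of subject j (cell-type ct) is
    ``libsize_i * baseline_g * exp(direction_g * effect * severity_j)`` for
    genes in a module of ct and ``libsize_i * baseline_g`` otherwise.
    """
    for m in modules:
        if m.gene_indices.max() >= spec.n_genes:
            raise ValueError("module gene index exceeds n_genes")
    rng = np.random.default_rng(seed)
    baseline = np.exp(rng.normal(spec.baseline_log_mean, spec.baseline_log_sd,
                                 spec.n_genes))
    n_zero = int(round(spec.near_zero_fraction * spec.n_genes))
    if n_zero:
        baseline[spec.n_genes - n_zero:] *= 1e-4

    severity = subjects["severity"].to_numpy(dtype=float)
    by_type: dict[str, list[ModuleSpec]] = {ct: [] for ct in spec.cell_types}
    for m in modules:
        if m.cell_type not in by_type:
            raise ValueError(f"module cell_type {m.cell_type!r} not in cohort")
        if m.subject_factor is not None and \
                len(m.subject_factor) != len(subjects):
            raise ValueError("subject_factor length must equal n_subjects")
        by_type[m.cell_type].append(m)

    n_per = spec.cells_per_subject_per_type
    blocks, cell_rows = [], []
    for ct in spec.cell_types:
        # per-subject log-fold shift per gene; each module scales with its
        # own subject factor (the latent severity unless overridden)
        shift_per_subject = np.zeros((len(subjects), spec.n_genes))
        for m in by_type[ct]:
            factor = severity if m.subject_factor is None \
                else np.asarray(m.subject_factor, dtype=float)
            shift_per_subject[:, m.gene_indices] += \
                factor[:, None] * (m.effect_size * m.directions)[None, :]
        for j, row in enumerate(subjects.itertuples(index=False)):
            libsize = np.exp(rng.normal(0.0, spec.libsize_log_sd, n_per))
            mean = libsize[:, None] * (baseline * np.exp(shift_per_subject[j]))[None, :]
            if np.isinf(spec.nb_dispersion):
                counts = rng.poisson(mean)
            else:
                theta = spec.nb_dispersion
                counts = rng.negative_binomial(theta, theta / (theta + mean))
            blocks.append(sp.csr_matrix(counts))
            for i in range(n_per):
                cell_rows.append((f"{row.subject_id}_{ct}_{i:03d}",
                                  row.subject_id, row.diagnosis, ct))
    counts = sp.csr_matrix(sp.vstack(blocks))
    cells = pd.DataFrame(cell_rows,
                         columns=["cell_id", "subject_id", "diagnosis", "cell_type"])
    cm = CountMatrix(counts=counts, gene_ids=gene_symbols(spec.n_genes),
                     cell_ids=cells["cell_id"].to_numpy(dtype=object))
    return cm, cells


def generate_genesets(n_genes: int, modules: list[ModuleSpec],
                      n_null_sets: int, n_supersets: int, seed: int,
                      signal_overlap: float = 0.9,
                      null_size_range: tuple[int, int] = (20, 80)) -> GeneSetDB:
    """Build a gene-set DB with ground truth encoded in the set names.

    One ``signal`` set per planted module (>= ``signal_overlap`` of its
    members plus a little random padding), ``n_null_sets`` random sets, and
    ``n_supersets`` supersets of signal sets (signal plus padding) to
    exercise redundancy and leaf filters.
    """
    if n_null_sets < 0 or n_supersets < 0:
        raise ValueError("set counts must be >= 0")
    rng = np.random.default_rng(seed)
    symbols = gene_symbols(n_genes)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    signal_names = []
    per_type_counter: dict[str, int] = {}
    for m in modules:
        k = per_type_counter.get(m.cell_type, 0)
        per_type_counter[m.cell_type] = k + 1
        n_keep = max(1, int(np.ceil(signal_overlap * m.gene_indices.size)))
        keep = rng.choice(m.gene_indices, size=n_keep, replace=False)
        n_pad = max(0, m.gene_indices.size - n_keep)
        outside = np.setdiff1d(np.arange(n_genes), m.gene_indices)
        pad = rng.choice(outside, size=n_pad, replace=False)
        name = f"signal::{m.cell_type}::m{k}"
        sets[name] = (f"planted module {k} of {m.cell_type}",
                      frozenset(symbols[np.concatenate([keep, pad]).astype(int)]))
        signal_names.append(name)
    for i in range(n_null_sets):
        size = int(rng.integers(null_size_range[0], null_size_range[1] + 1))
        idx = rng.choice(n_genes, size=size, replace=False)
        sets[f"null::{i:03d}"] = ("random null set", frozenset(symbols[idx]))
    for i in range(n_supersets):
        base = signal_names[i % len(signal_names)]
        base_members = sets[base][1]
        n_pad = max(1, len(base_members) // 2)
        outside = np.array(sorted(set(symbols) - base_members), dtype=object)
        pad = rng.choice(outside, size=n_pad, replace=False)
        sets[f"super::{i:03d}::{base}"] = (f"superset of {base}",
                                           base_members | frozenset(pad))
    return GeneSetDB(sets=sets)


def generate_risk_loci(modules: list[ModuleSpec], n_in_module: int,
                       n_outside: int, seed: int, n_genes: int) -> pd.DataFrame:
    """Sample a risk-locus gene list, flagged inside/outside planted modules."""
    rng = np.random.default_rng(seed)
    symbols = gene_symbols(n_genes)
    in_module_idx = np.unique(np.concatenate([m.gene_indices for m in modules])) \
        if modules else np.array([], dtype=int)
    outside_idx = np.setdiff1d(np.arange(n_genes), in_module_idx)
    if n_in_module > in_module_idx.size:
        raise ValueError("n_in_module exceeds available module genes")
    if n_outside > outside_idx.size:
        raise ValueError("n_outside exceeds available non-module genes")
    chosen_in = rng.choice(in_module_idx, size=n_in_module, replace=False) \
        if n_in_module else np.array([], dtype=int)
    chosen_out = rng.choice(outside_idx, size=n_outside, replace=False) \
        if n_outside else np.array([], dtype=int)
    genes = np.concatenate([chosen_in, chosen_out]).astype(int)
    return pd.DataFrame({
        "gene": symbols[genes],
        "in_module": [True] * n_in_module + [False] * n_outside,
    })


def generate_planted_rank_data(n_cells: int, n_genes: int, rank: int, seed: int,
                               noise_sd: float = 0.3,
                               factor_scales: tuple[float, ...] = (4.0, 2.0, 1.0),
                               label_noise_sd: float = 0.0
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Dense data with a known number of label-relevant latent directions.

    ``rank`` orthonormal gene-space directions carry i.i.d. standard-normal
    cell factors at well-separated scales; the label is the sign of the
    equally-weighted factor sum. Because the factors enter the label equally
    but sit in the data at distinct variances, the sequentially extracted
    components approach the optimal predictor in exactly ``rank`` steps —
    the fixture for model-selection consistency.
    """
    if rank < 1 or rank > len(factor_scales):
        raise ValueError(f"rank must be in 1..{len(factor_scales)}")
    rng = np.random.default_rng(seed)
    basis, _ = np.linalg.qr(rng.normal(size=(n_genes, rank)))
    factors = rng.normal(size=(n_cells, rank))
    scales = np.array(factor_scales[:rank])
    X = (factors * scales) @ basis.T + noise_sd * rng.normal(size=(n_cells, n_genes))
    y_latent = factors.sum(axis=1)
    if label_noise_sd:
        y_latent = y_latent + rng.normal(0.0, label_noise_sd, n_cells)
    y = np.where(y_latent > 0, 1, -1)
    # keep both classes non-degenerate
    if np.all(y == y[0]):
        y[0] = -y[0]
    return X, y
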