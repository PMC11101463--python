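"""Run configuration: one structured file drives the whole pipeline.

Every stochastic stage carries an explicit seed so a rerun with the same
configuration is bit-identical. Defaults follow the analysis protocol:
library-size target 1e4, detection filter 1/1000 cells, component grid 1-8,
1000 bootstrap iterations, 1000 enrichment permutations, minimum set size
5, FDR 0.05, overlap de-duplication at 0.9, top 50 sets per module.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

STAGES_WITH_SEEDS = ("simulate", "shuffle", "balance", "cv", "bootstrap", "gsea")

DEFAULT_KEYWORDS = [
    "microglia", "mapk", "inflamm*", "tumor necrosis", "mhc", "toll-like",
    "oligod*", "myelin", "alzheimer", "amyloid", "lipid", "cholesterol",
    "neuron", "actin", "apopto*", "phagocyt*", "copper",
]


@dataclass
class RunConfig:
    seeds: dict = field(default_factory=dict)
    # preprocessing
    target_sum: float = 10_000.0
    min_cell_fraction: float = 0.001
    # model selection
    component_grid: tuple = tuple(range(1, 9))
    outer_k: int = 5
    inner_k: int = 5
    # bootstrap
    n_bootstrap: int = 1000
    ci_lo: float = 0.05
    ci_hi: float = 0.95
    # enrichment
    min_set_size: int = 5
    n_perm: int = 1000
    weight_exp: float = 1.0
    fdr_alpha: float = 0.05
    overlap_threshold: float = 0.9
    keywords: list = field(default_factory=lambda: list(DEFAULT_KEYWORDS))
    # coordination
    top_k_sets: int = 50
    rank_sets_by: str = "NES"
    # DE comparison
    top_k_genes: int = 10
    marker_genes: list = field(default_factory=list)
    # synthetic-cohort knobs (forwarded to CohortSpec / module generator)
    cohort: dict = field(default_factory=dict)
    n_modules_per_type: int = 2
    module_size: int = 50
    effect_size: float = 1.5
    n_null_sets: int = 30
    n_supersets: int = 4
    n_risk_in_module: int = 10
    n_risk_outside: int = 10

    def __post_init__(self) -> None:
        self.component_grid = tuple(int(g) for g in self.component_grid)
        missing = [s for s in STAGES_WITH_SEEDS if s not in self.seeds]
        if missing:
            raise ValueError(f"missing stage seeds: {missing}; every "
                             "stochastic stage needs an explicit seed")
        for stage, seed in self.seeds.items():
            if not isinstance(seed, int):
                raise ValueError(f"seed for stage {stage!r} must be an integer")

    @classmethod
    def with_master_seed(cls, seed: int, **overrides) -> "RunConfig":
        """Derive all stage seeds deterministically from one master seed."""
        seeds = {stage: (seed * 1000003 + i * 7919) % (2 ** 31)
                 for i, stage in enumerate(STAGES_WITH_SEEDS)}
        seeds.update(overrides.pop("seeds", {}))
        return cls(seeds=seeds, **overrides)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        data = asdict(self)
        data["component_grid"] = list(self.component_grid)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
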