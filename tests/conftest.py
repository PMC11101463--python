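import numpy as np
import pytest

from scplsda.preprocess import balance_classes, drop_zero_variance, \
    filter_genes_min_cells, normalize_log1p, standardize
from scplsda.simulate import CohortSpec, ModuleSpec, generate_cohort, \
    generate_expression


def make_balanced_ct(seed=0, n_subjects=16, cells_per=10, n_genes=400,
                     module_size=30, effect_size=1.5, n_cell_types=1,
                     permute_labels=False):
    """One cell-type's preprocessed (normalized, filtered, balanced) matrix
    with a single planted module; the standard harness for classifier and
    bootstrap tests."""
    spec = CohortSpec(n_subjects=n_subjects, n_cell_types=n_cell_types,
                      cells_per_subject_per_type=cells_per, n_genes=n_genes)
    subjects, markers, severity = generate_cohort(spec, seed)
    rng = np.random.default_rng(seed + 1)
    n_eligible = int(n_genes * (1 - spec.near_zero_fraction))
    idx = np.sort(rng.choice(n_eligible, module_size, replace=False))
    directions = rng.choice([1.0, -1.0], module_size, p=[0.7, 0.3])
    module = ModuleSpec(cell_type=spec.cell_types[0], gene_indices=idx,
                        effect_size=effect_size, directions=directions)
    cm, cells = generate_expression(subjects, [module], spec, seed + 2)
    ct = spec.cell_types[0]
    rows = np.flatnonzero((cells["cell_type"] == ct).to_numpy())
    norm = normalize_log1p(cm)[rows]
    filtered, genes = filter_genes_min_cells(norm, cm.gene_ids)
    labels = cells["diagnosis"].to_numpy()[rows]
    if permute_labels:
        labels = np.random.default_rng(seed + 9).permutation(labels)
    keep = balance_classes(labels, seed + 3)
    X = filtered[keep].toarray().astype(float)
    return {
        "X": X,
        "labels": labels[keep],
        "genes": genes,
        "subjects": cells["subject_id"].to_numpy()[rows][keep],
        "module_genes": set(cm.gene_ids[idx]),
        "severity": severity,
        "markers": markers,
        "subject_table": subjects,
    }


@pytest.fixture(scope="session")
def balanced_ct():
    return make_balanced_ct(seed=0)


@pytest.fixture()
def standardized_random():
    rng = np.random.default_rng(42)
    X = rng.normal(size=(120, 30))
    y = rng.permutation([1] * 60 + [-1] * 60)
    return standardize(X, y)


def standardize_raw(X, y, genes=None):
    X = np.asarray(X, float)
    if genes is None:
        genes = np.array([f"g{i}" for i in range(X.shape[1])], dtype=object)
    Xz, kept, _ = drop_zero_variance(X, genes)
    return standardize(Xz, y, gene_ids=kept), kept
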