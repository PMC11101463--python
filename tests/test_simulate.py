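import numpy as np
import pytest
import scipy.stats

from scplsda.progression import spearman
from scplsda.simulate import (CohortSpec, ModuleSpec, generate_cohort,
                              generate_expression, generate_genesets,
                              generate_planted_rank_data, generate_risk_loci,
                              gene_symbols, make_default_modules)


class TestCohort:
    def test_noiseless_markers_are_exact_monotone(self):
        spec = CohortSpec(marker_noise_sd=0.0)
        _, markers, severity = generate_cohort(spec, seed=3)
        assert spearman(severity, markers["tangles"].to_numpy()) == 1.0
        assert spearman(severity, markers["cognition"].to_numpy()) == -1.0

    def test_case_severity_exceeds_control(self):
        """The case group's mean latent severity exceeds the controls' in
        essentially every draw (Monte-Carlo over seeds)."""
        spec = CohortSpec()
        wins = 0
        n = 1000
        for seed in range(n):
            subjects, _, severity = generate_cohort(spec, seed)
            d = subjects["diagnosis"].to_numpy()
            wins += severity[d == 1].mean() > severity[d == -1].mean()
        assert wins / n > 0.99

    def test_ordinal_marker_ranges(self):
        _, markers, _ = generate_cohort(CohortSpec(), seed=0)
        assert markers["braak"].between(0, 6).all()
        assert markers["cerad"].between(1, 4).all()
        assert (markers["tangles"] >= 0).all()
        assert (markers["amyloid"] >= 0).all()

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="class empty"):
            generate_cohort(CohortSpec(n_subjects=10, prop_ad=0.01), seed=0)

    def test_marker_noise_degrades_severity_correlation(self):
        """Marker-severity Spearman decreases with marker noise sd."""
        medians = []
        for sd in (0.1, 0.5, 1.5):
            rhos = [abs(spearman(sev, m["tangles"].to_numpy()))
                    for seed in range(25)
                    for (_, m, sev) in
                    [generate_cohort(CohortSpec(marker_noise_sd=sd), seed)]]
            medians.append(np.median(rhos))
        assert medians[0] > medians[1] > medians[2]

    def test_fixed_seed_bit_identical(self):
        a = generate_cohort(CohortSpec(), seed=5)
        b = generate_cohort(CohortSpec(), seed=5)
        assert a[0].equals(b[0]) and a[1].equals(b[1])
        np.testing.assert_array_equal(a[2], b[2])


def _tiny_spec(**kw):
    defaults = dict(n_subjects=12, n_cell_types=1,
                    cells_per_subject_per_type=8, n_genes=200)
    defaults.update(kw)
    return CohortSpec(**defaults)


class TestExpression:
    def test_null_effect_gives_uniform_de_pvalues(self):
        """With effect size 0 no gene separates cases from controls: the
        per-gene two-sample t-test p-values are uniform."""
        pvals = []
        for seed in range(3):
            # well-expressed genes keep the t statistic in its gaussian
            # regime so p-values can be checked for uniformity
            spec = _tiny_spec(n_genes=300, near_zero_fraction=0.0,
                              libsize_log_sd=0.0,
                              baseline_log_mean=np.log(20.0),
                              baseline_log_sd=0.3)
            subjects, _, _ = generate_cohort(spec, seed)
            module = ModuleSpec(cell_type="type0", gene_indices=[0, 1, 2],
                                effect_size=0.0)
            cm, cells = generate_expression(subjects, [module], spec, seed + 50)
            X = cm.counts.toarray()
            d = cells["diagnosis"].to_numpy()
            res = scipy.stats.ttest_ind(X[d == 1], X[d == -1], axis=0)
            pvals.append(res.pvalue[np.isfinite(res.pvalue)])
        ks = scipy.stats.kstest(np.concatenate(pvals), "uniform")
        assert ks.pvalue > 0.01

    def test_poisson_limit_variance_to_mean(self):
        """At infinite dispersion the counts are Poisson: variance/mean ~ 1."""
        spec = _tiny_spec(nb_dispersion=np.inf, libsize_log_sd=0.0,
                          near_zero_fraction=0.0, baseline_log_sd=0.0,
                          baseline_log_mean=np.log(2.0),
                          cells_per_subject_per_type=50)
        subjects, _, _ = generate_cohort(spec, 0)
        subjects = subjects.assign(severity=0.0)
        module = ModuleSpec(cell_type="type0", gene_indices=[0])
        cm, _ = generate_expression(subjects, [module], spec, 1)
        X = cm.counts.toarray().astype(float)
        ratio = X.var(axis=0).mean() / X.mean(axis=0).mean()
        assert abs(ratio - 1.0) < 0.05

    def test_overdispersion_exceeds_poisson(self):
        spec = _tiny_spec(nb_dispersion=2.0, libsize_log_sd=0.0,
                          near_zero_fraction=0.0, baseline_log_sd=0.0,
                          baseline_log_mean=np.log(2.0),
                          cells_per_subject_per_type=50)
        subjects, _, _ = generate_cohort(spec, 0)
        subjects = subjects.assign(severity=0.0)
        cm, _ = generate_expression(
            subjects, [ModuleSpec(cell_type="type0", gene_indices=[0])],
            spec, 1)
        X = cm.counts.toarray().astype(float)
        # NB: var = m + m^2/theta = 2 + 4/2 = 4 at m=2, theta=2
        ratio = (X.var(axis=0) / X.mean(axis=0)).mean()
        assert ratio > 1.5

    def test_row_sum_expectation(self):
        """With fixed library size and equal baselines, a cell's total count
        concentrates at libsize-free n_genes * baseline."""
        spec = _tiny_spec(n_subjects=4, cells_per_subject_per_type=1,
                          libsize_log_sd=0.0, baseline_log_sd=0.0,
                          baseline_log_mean=np.log(1.0),
                          near_zero_fraction=0.0, n_genes=2000)
        subjects, _, _ = generate_cohort(spec, 0)
        subjects = subjects.assign(severity=0.0)
        cm, _ = generate_expression(
            subjects, [ModuleSpec(cell_type="type0", gene_indices=[0])],
            spec, 2)
        sums = np.asarray(cm.counts.sum(axis=1)).ravel()
        # mean 2000, sd ~ sqrt(2000 * (1 + 1/theta)) ~ 47
        assert np.all(np.abs(sums - 2000) < 5 * 47)

    def test_empty_module_rejected(self):
        with pytest.raises(ValueError, match="empty module"):
            ModuleSpec(cell_type="type0", gene_indices=[])

    def test_module_index_out_of_range_rejected(self):
        spec = _tiny_spec()
        subjects, _, _ = generate_cohort(spec, 0)
        with pytest.raises(ValueError, match="exceeds n_genes"):
            generate_expression(
                subjects,
                [ModuleSpec(cell_type="type0", gene_indices=[spec.n_genes])],
                spec, 0)

    def test_fixed_seed_bit_identical(self):
        spec = _tiny_spec()
        subjects, _, _ = generate_cohort(spec, 0)
        mods = make_default_modules(spec, 1, module_size=10)
        a, _ = generate_expression(subjects, mods, spec, 2)
        b, _ = generate_expression(subjects, mods, spec, 2)
        assert (a.counts != b.counts).nnz == 0


class TestGeneSetsAndLoci:
    def _modules(self):
        return [ModuleSpec(cell_type="type0", gene_indices=np.arange(10)),
                ModuleSpec(cell_type="type1", gene_indices=np.arange(20, 35))]

    def test_signal_sets_only(self):
        db = generate_genesets(100, self._modules(), n_null_sets=0,
                               n_supersets=0, seed=0)
        assert len(db) == 2

    def test_superset_contains_signal(self):
        db = generate_genesets(100, self._modules(), n_null_sets=0,
                               n_supersets=2, seed=0)
        supers = [n for n in db.names() if n.startswith("super::")]
        assert len(supers) == 2
        for name in supers:
            base = "::".join(name.split("::")[2:])
            assert db.members(base) < db.members(name)

    def test_signal_overlap_at_least_80pct(self):
        mods = self._modules()
        symbols = gene_symbols(100)
        db = generate_genesets(100, mods, n_null_sets=5, n_supersets=0, seed=1)
        for m, name in zip(mods, [n for n in db.names()
                                  if n.startswith("signal::")]):
            planted = set(symbols[m.gene_indices])
            ratio = len(db.members(name) & planted) / len(planted)
            assert ratio >= 0.8

    def test_risk_loci_flags(self):
        mods = self._modules()
        loci = generate_risk_loci(mods, n_in_module=3, n_outside=2, seed=0,
                                  n_genes=100)
        assert len(loci) == 5
        assert loci["in_module"].sum() == 3
        assert loci["gene"].is_unique
        none_in = generate_risk_loci(mods, 0, 4, seed=0, n_genes=100)
        assert not none_in["in_module"].any()

    def test_risk_loci_request_too_large(self):
        with pytest.raises(ValueError, match="exceeds available"):
            generate_risk_loci(self._modules(), n_in_module=100, n_outside=0,
                               seed=0, n_genes=100)


class TestPlantedRankData:
    @pytest.mark.parametrize("rank", [1, 2, 3])
    def test_shapes_and_classes(self, rank):
        X, y = generate_planted_rank_data(100, 30, rank, seed=0)
        assert X.shape == (100, 30)
        assert set(np.unique(y)) == {-1, 1}
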