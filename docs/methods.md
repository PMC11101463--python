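# Methods

## Model and estimation

Each cell-type gets an independent PLS-DA classifier of cell transcriptomes
against donor diagnosis. The estimator is the classic NIPALS/power-method
sequence for a single-column outcome. Numerical conventions:

- `standardize()` centers and scales columns with the population (1/n)
  standard deviation; the spec example `[1,3] → [−1,+1]` fixes this
  convention. The PLS core consumes already-standardized data and performs
  no internal rescaling, so its outputs are directly comparable to a
  reference NIPALS run with scaling disabled on the same matrix (verified
  to 1e-6 in the tests).
- Loadings are normalized as `l = Xᵀt/(tᵀt)` (the NIPALS convention). This
  differs from the unnormalized `Xᵀt` by a positive per-component scalar
  only, so directions, rankings and every downstream statistic are
  unchanged.
- `u` is initialized from the outcome vector rather than randomly: for a
  one-column outcome the iteration reaches its fixed point after a single
  pass regardless of the start, and the deterministic start removes an
  irrelevant source of run-to-run variation. A seeded random start remains
  available (`random_init=True`) and reaches the same fixed point.
- Components are oriented so the y-weight `c` is positive (positive scores
  point toward disease). This removes the reflection non-identifiability
  within one fit; bootstrap replicates are additionally cosine-aligned to
  the full-data loadings.
- Convergence: tol 1e-6 on the weight update, max 500 iterations
  (non-convergence warns and keeps the last iterate). A vanishing score or
  weight norm means the requested component count exceeds the effective
  rank and raises.
- Prediction coefficients use the standard rotation construction
  `R = W (LᵀW)⁻¹`, `coef = R c`; predictions are linear scores on the
  standardized-label scale, not calibrated probabilities. Class calls
  threshold at 0 with exact ties assigned to the control class.

## Preprocessing

Fixed order: library-size normalization of every cell to 10,000 counts
followed by natural-log log1p; one global seeded shuffle of the cell order;
per cell-type: subset, drop genes detected in fewer than `ceil(0.001·n)`
cells of that type (the "1 in 1000" rule read as an inclusive ≥1-per-1000
threshold; boundary configurable), subsample the majority diagnosis class
to balance, and standardize. Standardization parameters are estimated
inside each training portion only and applied unchanged to held-out cells;
genes that become constant after balancing are dropped and recorded, since
their standardization is undefined. Class balancing happens once before
cross-validation, not per fold.

## Model selection

Nested stratified 5×5-fold CV over cells (not subjects; a cell-level split
mirrors the analysis this package reimplements — predictions for a cell can
therefore borrow information from sibling cells of the same donor, and a
`--split-by subject` variant would be the conservative alternative). The
component grid is 1–8. The inner scan fits one model at the largest grid
value per inner fold and evaluates truncations: sequentially extracted
components are nested, so the truncated coefficients equal a refit (tested
to 1e-10). Grid ties break to the smallest value; the final per-cell-type
count is the mode over outer folds, smallest on ties. Reported AUROC is
the mean ± sd across the five outer folds; AUROC itself is the tie-aware
Mann–Whitney statistic.

## Bootstrap modules

B resamples of cells with replacement, stratified by diagnosis class so
every refit sees the balance the model was trained under; the component
count is fixed at the full-data CV choice. Genes constant within a resample
get an exact-zero loading for that iteration. After cosine sign alignment
(per component, per iteration; ties unflipped), a gene is silenced when its
empirical 5/95% interval (linear-interpolation quantiles) contains zero
inclusively or any iteration produced an exact zero; retained genes carry
the median aligned loading. Default B=1000; the acceptance script uses
B=200 for runtime.

A property of this rule worth knowing: the bootstrap interval of a gene
re-centers on that gene's *sample* loading, not on zero. In a cohort where
the fitted direction is stable, a pure-noise gene whose sample correlation
with the component happens to sit ~1.6 standard errors from zero keeps a
CI excluding zero, so null genes are retained at roughly the nominal
two-sided exclusion rate (~10%) — and somewhat above it, because the
fitted component partially absorbs each gene's own noise. The retained set
therefore has high recall of truly shifted genes but only modest set-level
precision when true module genes are a small fraction of the transcriptome;
the |loading| ranking concentrates the planted genes at the top regardless,
which is what the downstream preranked enrichment consumes. The tests
measure both views.

## Enrichment

Preranked GSEA on the median bootstrap loadings of each component, silenced
genes excluded, descending scores with ties broken by gene symbol. Weighted
running sum with exponent 1 (configurable): hit increments proportional to
|score|, normalized over the set's hits; miss decrement `1/(N−n_set)`; ES
is the extreme of the running sum (evaluated in closed form at the hit
boundaries; exact ties between the positive and negative extreme resolve
positive, with a 1e-12 tolerance so exact rational ties are deterministic
under float round-off). The null is `n_perm` random same-size gene subsets
(shared across sets of equal size), the preranked standard since no
phenotype labels exist at this stage. NES divides ES by the mean |null ES|
of the matching sign; p is the sign-matched empirical tail with +1
smoothing; q follows the GSEA procedure on the pooled sign-normalized null,
clipped to [0,1]. Calibration (uniform null p) and agreement with an
independent implementation (rank correlation of ES) are tested rather than
bit-equality, since FDR variants differ across tool versions. Filtering:
strict q < 0.05, then greedy redundancy removal in descending |NES| (ties
by name) dropping any set whose overlap ratio — shared genes over the
smaller set — exceeds 0.9 against a kept set. Multiple GMT files are
enriched separately and combined. Keyword profiling matches case-insensitive
substrings, with a trailing `*` meaning token-prefix match.

## Pseudo-progression

Out-of-sample continuous predictions (validation folds only) are grouped by
subject within each cell-type and summarized by the median; missing
(subject × cell-type) cells are imputed with the cell-type's cross-subject
mean and flagged. Rows (cell-types) are centered across subjects but not
variance-scaled — all rows already live on the common standardized-
prediction scale, and centering alone makes the first principal component
meaningful. Subjects are projected on PC1 (SVD), the sign is fixed so
disease-labelled subjects score higher on average, and ranks ascend from
most control-like. Validation is Spearman (mid-rank ties) against all five
markers: Braak-like and CERAD-like ordinals, cognition, tangles, amyloid.

## Coordination

For every top gene set of a module (top 50 by |NES| by default; ranking by
|Spearman with the pseudo-progression| is available, surfacing rather than
resolving the two published variants), a single-component PLS-DA restricted
to the set's genes is fitted on the same balanced cells as the main model,
and the per-subject mean of its continuous predictions is that subject's
activity. The activity models are fitted in-sample by default — a known
optimism source (in-sample activity correlates with diagnosis at roughly
√(n_set_genes/n_subjects) even for noise sets); `cv_folds` switches to
out-of-sample activity. Coordination between two modules of different
cell-types is the median |Pearson| over all pairs of their activity
columns; within-cell-type pairs are excluded from the matrix.

One emergent behaviour of the generator matters here: library-size
normalization couples every gene of a cell-type to whatever severity-driven
modules that cell-type hosts (shifted modules change the cell totals, so
all normalized values co-vary with severity). A module driven by an
independent subject factor therefore only behaves independently if planted
in a cell-type without severity-driven modules; the coordination contrast
test is constructed that way.

## Risk mapping and DE comparison

Risk loci are an input gene list. Enriched (FDR-filtered, de-duplicated)
sets are first reduced to leaves — sets that are not strict supersets of
another enriched set in the same module; equal member sets both survive —
and each locus is counted per module by the number of leaf sets containing
it; loci absent from the retained expression genes are flagged "not
captured". Differential expression uses the Wilcoxon rank-sum test on the
log-normalized expression (exact for small tie-free samples, normal
approximation with tie correction otherwise), log2 fold-change of class
means with pseudocount 1e-9, and Benjamini–Hochberg adjustment. Module-DE
agreement reports Spearman (primary) and Pearson correlations between
loadings (silenced genes at zero) and fold-changes, plus intersections of
the top-10 genes by |loading| with the top-10 by adjusted p and by
|fold-change|.

## Synthetic cohort

Defaults emulate a 48-subject, half-case cohort with 6 cell-types, 30
cells per subject per type and 2,000 genes — a desk-scale stand-in for a
~70k-cell, ~18k-gene study. Latent severity: controls |N(0, 0.2²)|, cases
1 + |N(0, 0.5²)| — disjoint classes with a within-case gradient that
pseudo-progression must recover. Markers are monotone in severity
(cognition decreasing, the rest increasing) with Gaussian noise (sd 0.3)
on the latent scale; Braak (0–6) and CERAD (1–4) arise by quantile binning
of a noisy latent, matching their semi-quantitative nature. Counts are
negative binomial (dispersion 10, i.e. variance m + m²/10) with log-normal
library sizes (sd 0.3) and log-normal baseline means (5% of genes
near-zero to exercise the detection filter). Planted modules shift module
genes by `direction · 1.5 · severity` on the log scale (70% up-regulated);
two disjoint 50-gene modules per cell-type by default. Because both default
modules of a cell-type follow the same severity, the class-discriminative
signal is genuinely rank one and the CV correctly selects one component —
distinct per-module subject factors (`ModuleSpec.subject_factor`) create
higher-rank structure when needed. The gene-set DB carries one signal set
per module (90% overlap plus padding), random null sets, and supersets of
signal sets to exercise redundancy and leaf filters; names encode the
ground truth. What the generator does not emulate: doublets, ambient RNA,
batch effects, cell-type misassignment, gene–gene correlation beyond the
planted modules — so passing tests certify the statistical machinery, not
robustness to those artifacts.

The rank-planted fixture for model selection places r orthonormal gene-
space directions at factor scales (4, 2, 1) with i.i.d. standard-normal
cell factors and labels the sign of the equally-weighted factor sum; the
factors enter the label equally but sit in the data at distinct variances,
so sequential extraction needs exactly r components to reach the optimal
predictor, and the scale separation keeps the r-th component's incremental
AUROC detectable at n=400 cells.

## Problem sizes and determinism

The default pipeline (B=200 bootstrap) runs in ~3 minutes on one CPU; the
test suite uses smaller instances per test (stated in each test) chosen so
the whole suite completes in minutes. All randomness flows through
explicit per-stage seeds; reruns are byte-identical, which the suite
checks by hashing the result bundle.

## Known limitations

- Cell-level CV splits allow donor-level information sharing (see above).
- The CI zeroing rule's set-level precision is intrinsically limited (see
  bootstrap section); interpret retained sets via their ranking.
- PLS confidences are uncalibrated linear scores; "confidence" is ordinal.
- In-sample activity scores are optimistic; use `cv_folds` when absolute
  null behaviour matters.
- The GSEA FDR q matches the classic procedure's behaviour, not any one
  tool version bit-for-bit.
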