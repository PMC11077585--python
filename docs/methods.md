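# Methods

This note documents the models, procedures and numerical choices behind
`bonequant`, in the spirit of a statistical-software methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Scope and data model

`bonequant` post-processes label-free quantification tables produced by
peptide search engines for bone (and other collagen-rich) proteomes.  It
consumes DIA-NN `report.tsv` and MaxQuant `evidence.txt` files, never raw
spectra: identification and FDR control are the engines' responsibility,
and protein quantities are precursor sums (no MaxLFQ re-implementation).

The central container is the `QuantMatrix`: features × samples abundances
with `NaN` as the explicit missing marker, at one of three feature levels —
`protein` (leading accession of the protein group), `peptide_sequence`
(stripped sequence, pooling charges and modification states) and
`modified_sequence` (stripped sequence plus the multiset of
deamidation/oxidation events).  Three conventions matter throughout:

* **Zero is missing.** Blank or zero intensities are absence of evidence,
  not measured zeros; they become missing cells and are candidates for
  imputation.  The log2 transform therefore never sees zeros.
* **Engine neutrality.** Both engine dialects map onto one modification
  vocabulary (deamidation N/Q, oxidation M, N-terminal acetylation,
  carbamidomethyl C, other).  The modified-sequence feature key counts
  deamidation/oxidation events but ignores site positions and non-analyte
  modifications (fixed carbamidomethyl, default N-terminal acetylation):
  DIA-NN writes UniMod:4 tokens into its modified sequences while MaxQuant
  omits fixed modifications, and engines may localize positional isomers
  differently, so only class counts are portable across engines.  Site
  positions remain available on each `PrecursorRecord`.
* **Razor assignment.** A precursor mapping to several protein groups
  counts only toward the first listed group, logged.

## Missingness cutoff calibration

Features with too much missing data are excluded rather than imputed.  The
acceptable cutoff is calibrated by mask-and-score: remove a fraction of the
*observed* cells completely at random (30%–50% in 5% steps by default),
re-impute, and score root-mean-squared error and Pearson correlation
between true and imputed values over the masked cells only, on the log2
scale (so RMSE is scale-free).  Masking preserves at least one observation
per feature, the count of masked cells is exactly `round(fraction ×
n_observed)`, and unmasked cells are bit-identical before and after a
calibration run.

The selection rule — the largest masking fraction whose mean Pearson r
over repeats stays at or above `r_min` (default 0.7), falling back to the
smallest fraction with a warning — is an explicit, configurable policy:
some rule is required for reproducibility, and a correlation floor directly
encodes "imputation is still trustworthy at this much missingness".
Defaults: 5 repeats per fraction; per-run seeds derive from
`SeedSequence(seed, fraction_index, repeat)`.

Exclusion rules differ by level, deliberately:

* proteins with missingness above the cutoff are dropped;
* a peptide is analyzed only if **every** one of its modified/unmodified
  sequence forms is at or below the cutoff.  An occupancy ratio computed
  from a partial set of forms is biased, so peptide exclusion is
  all-or-nothing.  Retained sets are nested across decreasing cutoffs.

## Imputation

The primary imputer is MissForest (Stekhoven & Bühlmann's iterative
random-forest scheme), oriented with features as responses and samples as
observations (features outnumber samples in this data shape):

1. initialize missing cells with feature means;
2. visit features in ascending missingness order; for each, fit a
   random-forest regressor of that feature on all others using the samples
   where it is observed, and re-predict its missing cells;
3. after each sweep compute Δ = Σ(X_new − X_old)² / Σ X_new² over imputed
   cells; stop at the first increase of Δ and return the matrix from the
   last Δ-decreasing sweep, or stop at `max_iterations` (default 10).

Forest hyperparameters follow the R `randomForest` regression defaults the
reference implementation inherits: 100 trees, `mtry = √p`, node size 5.
Every forest seed derives from `(seed, feature index, sweep)`, so the whole
imputation is reproducible; a transposed orientation is available by
passing the transposed matrix.

**Convergence tolerance.** In addition to the Δ-increase rule, the sweep
loop declares convergence when a sweep improves Δ by less than `rel_tol`
(default 5%) in relative terms.  On the default problem size the Δ trace
collapses by orders of magnitude over the first two sweeps and then
plateaus, with subsequent sweeps changing imputed cells at the ~10⁻⁶
relative level while each costs as much as a full refit of every forest;
the tolerance cuts that tail without measurably changing the imputation.
Set `rel_tol=0` to recover the strict increase-only rule.

Comparator imputers (scored on identical masks in the paired benchmark):
feature-space k-nearest-neighbour averaging (k = 5, NaN-aware Euclidean
distances over mutually observed samples), feature-mean substitution, and
a left-censoring surrogate (feature minimum − 1 log2 unit).  All imputers
leave observed cells bit-exactly untouched; scoring reports RMSE and
Pearson r over masked cells, with Pearson undefined (NaN, warned) under
zero variance.

## PTM occupancy ratios

For one peptide sequence in one sample, the occupancy of a modification
class is

    ratio = Σ abundance(forms carrying ≥1 modification of the class)
            ───────────────────────────────────────────────────────
            Σ abundance(all forms of the sequence)

computed from raw (pre-log) abundances.  Choices embedded in this
definition:

* a form carrying both a deamidation and an oxidation counts in the
  numerator of both classes — this keeps each class's conservation law
  (modified + complement = total) exact;
* multiple sites on one form count once: occupancy is form-level, not
  site-level;
* a cell whose total abundance is unobserved is missing, never 0; a cell
  with an observed total but no observed modified form is 0;
* ratios use observed abundances only; imputation, if requested, applies
  to the ratio table afterwards, not to the form abundances that feed it;
* a deamidation row exists for every retained sequence containing N or Q,
  an oxidation row for every sequence containing M; N-terminal acetylation
  and carbamidomethyl never form rows (search-engine bookkeeping, not
  degradation markers).

Group summaries are unweighted means over defined cells, reported in
percent.  Ratios are invariant to rescaling all abundances of a sample.

## Normalization, standardization, comparison

Abundance matrices are log2-transformed.  Per-sample z-scoring (subtract
the sample's observed-cell mean, divide by its sample standard deviation,
n−1 denominator) is applied only when arms from different analytical runs
or acquisition modes are compared; arms from one run share a scale and are
compared on log2 values directly.

Arm comparison is feature-by-feature on donor-paired values with the
Wilcoxon signed-rank test:

* pairs with a missing member are removed; zero differences are dropped
  (classic Wilcoxon; Pratt's method available);
* **exact branch** (n ≤ 12 usable pairs): the null distribution of
  W⁺ = Σ ranks of positive differences is enumerated over all 2ⁿ sign
  assignments with the observed (possibly tied) ranks; the two-sided
  p-value is P(|W⁺ − μ| ≥ |w − μ|) with μ = Σranks/2 — the distribution is
  symmetric about μ even under ties;
* **normal branch** (n > 12): z = (|W⁺ − μ| − ½)/σ with σ² = Σrᵢ²/4, which
  is the tie-corrected variance when midranks are used, and a 0.5
  continuity correction;
* fewer than 3 usable pairs: the feature is recorded as untested.

Significance is reported at raw p < α (default 0.05); Benjamini–Hochberg
adjustment is available behind a flag but off by default, matching common
reporting practice for these designs.  Direction is the sign of the median
paired difference.  "Shared features" are the intersection of the two
arms' post-filter feature sets.  PTM occupancy is compared both
per-peptide (each (sequence, class) row as a feature) and pooled (all
(sequence, donor) paired cells of one class in one test); both views are
reported because they answer different questions.

Multivariate views: PCA on centered data with samples as observations
(variance explained sums to 100% when all components are kept), and
Euclidean average-linkage hierarchical clustering with inputs pre-sorted
by id for deterministic tie-breaking.  Proteome coverage is
operationalized as the count of observed proteins per sample of the
pre-imputation matrix — a declared surrogate, labeled as such in the
output — and tested with the same paired machinery.

## Synthetic data generator

The generator defines the study conditions under which every claim in the
test suite is evaluated.  It emulates, per dataset:

* **Design.** 30 donors by default, each contributing one run per workflow
  arm (replicate sets A/B): 60 runs, donor-paired across arms.
* **Abundance.** Two log2-normal protein classes: a small high-abundance
  class (10% of 150 proteins; log2 mean 24, sd 1.5) standing for the
  collagens and other structural proteins that dominate bone extracts, and
  a low-abundance class (log2 mean 17.5, sd 1.8).  Under these defaults
  the high class carries well over half the total intensity.  Each protein
  has 2–6 peptides with fixed per-peptide ionization offsets (sd 0.8).
* **Variance components.**  A donor-level global shift (sd 1.0) shared by
  both of a donor's runs, a per-protein×donor biological effect (sd 0.3),
  a per-run technical loading shift (sd 0.15) and residual noise (sd 0.3).
  The donor shift plays two roles at once: it produces the strong
  inter-feature correlation (~0.8 under defaults) that label-free data
  show and that feature-based imputation exploits, and it cancels exactly
  in within-donor paired contrasts, so paired tests keep their power.
* **Effects.** A configurable set of differential proteins receives a
  log2 fold-change in the second arm.
* **PTMs.** Peptides carry a deamidation site (N or Q, probability 0.6)
  and/or an oxidation site (M, probability 0.35); per-peptide occupancies
  are uniform on [0.2, 0.8], and each peptide's total abundance is
  partitioned *exactly* across its modified/unmodified forms (assuming
  independent deamidation and oxidation), so realized abundance-weighted
  occupancy equals the configured truth before masking.  An optional
  occupancy drift emulates protocol-induced deamidation differences.
* **Missingness.** An MCAR floor (default 2%) plus a logistic
  missing-not-at-random component whose probability rises as latent log2
  abundance falls (slope 1.0 per log2 unit), with the intercept calibrated
  by bisection so the marginal missing fraction hits the configured target
  (default 18%, per-arm overrides available; targets above 95% are
  rejected as infeasible).  The unit of missingness is configurable:
  per precursor-form cell (default) or per protein×run cell (all forms of
  a protein vanish together — the right unit when emulating the
  protein-matrix missingness percentages that studies report).  Setting
  the MCAR rate and slope to zero yields complete data for clean oracle
  tests.

Datasets are emitted as syntactically valid DIA-NN `report.tsv` or
MaxQuant `evidence.txt` files (modification notation in each engine's
dialect, fixed carbamidomethyl annotated only in the DIA-NN dialect, as
the engines themselves behave), alongside the design table and the full
ground truth.  Parsing an emitted report reproduces the ground-truth
observed matrices cell-for-cell, and the two dialects parse to identical
matrices.

Not emulated — and therefore not demonstrated by passing tests:
chromatographic or spectral artifacts, retention-time or m/z structure,
interference/co-isolation, engine scoring errors, richer dynamic-range
structure than two abundance classes, and correlated missingness beyond
the abundance-driven mechanism.  Conclusions about real data rest on the
method's behavior under these idealized conditions.

## Problem sizes and runtime choices

Defaults were chosen so a full validation runs on one CPU in minutes: the
imputation recovery check uses the default 150×60 matrix (5 seeds in the
test suite, 3 in the acceptance script); cutoff calibration examples run
on a 30-protein × 16-run matrix (25 mask-impute-score runs with 100-tree
forests); the power study uses 15 donor pairs × 150 proteins × 10 seeds.
All sizes are configuration, not limits; every routine accepts larger
inputs.

## Known limitations

* Protein quantities are precursor sums; MaxLFQ-style normalization is out
  of scope, so between-sample loading differences reach the log2 matrices
  (the paired design absorbs them).
* The kNN imputer warns and reduces k only on the global feature count; it
  does not warn per-cell when fewer than k donors carry a value.
* The coverage statistic is a surrogate definition (observed protein
  count per sample).
* The exact signed-rank branch enumerates 2ⁿ assignments and is limited to
  n ≤ 12 by design; beyond that the tie-corrected normal approximation is
  used.
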