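# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical conventions and the open design choices of `ctcstrat`.

## Cohort model and endpoints

A cohort is a per-cell feature table (one row per sorted cell: patient id,
cell class ∈ {eCTC, CD45pos, other}, 34 image features) plus a per-patient
clinical table (overall survival in months, event indicator, bone
metastasis status).  Class labels come from upstream marker gating and are
taken as input; the package does not re-derive them.

Overall survival is dichotomized at a horizon (default 30 months, the
cohort median of the reference study): a patient observed or censored
beyond the horizon is a long survivor; a patient who died at or before it
is a short survivor; a patient **censored at or before the horizon is
indeterminate** — their class is unknowable — and is excluded from
classification targets while remaining available for Kaplan–Meier
estimation.  The reference analysis did not state how such patients were
handled; exclusion is the only choice that avoids fabricating a label.

## Aggregation

Per patient and cell class, every feature is summarized by mean, sample
SD (n−1 denominator), and the 25th/50th/75th percentiles with linear
interpolation between order statistics (h = (n−1)p) — the dominant
spreadsheet/NumPy convention; the source analysis does not specify one.
A patient with no cells of a class receives missing markers (NaN), never
an exception; one cell leaves the SD missing.  Count features are added:
total cells, absolute eCTC / CD45pos counts, the CD45pos fraction of all
cells, and the eCTC fraction of **CTC-candidate (non-CD45pos) cells**
(denominator configurable to total cells).

A note on arithmetic: 34 features × 5 statistics give 170 aggregate
columns per class (plus counts).  The reference text says "34 parameters
for each patient", which conflicts with its own 34 × 5 enumeration; the
package implements the full 170 + counts, which is what the named
features of the published rankings require.

Missing values downstream are imputed with the **training-fold median**
inside every cross-validation step (never using the held-out patient),
except in the naive Bayes and information-gain paths, where missingness
is a category of its own.

## Information-gain ranking

Features are discretized into k = 4 equal-frequency bins — edges at the
(1/k, …, (k−1)/k)-quantiles, a value falling in the lowest bin whose upper
edge is ≥ the value, tied mass collapsing duplicate edges — and scored by

    IG = H(y) − Σ_b (n_b / n) · H(y | bin b)    [bits].

Ties are broken lexicographically so the ranking is deterministic.  The
same 4-bin scheme serves both the ranking and the naive Bayes model; the
source describes only one discretization, and reusing it is the most
parsimonious reading.

Ranking is computed **once on the full cohort**, before model screening,
mirroring the original (unnested) design.  This leaks target information
into the candidate pool; the consequence is quantified below.

## Single-variable analysis

For one feature, candidate cutoffs are midpoints between consecutive
sorted distinct values, scanned in both orientations (high-predicts-
positive and low-predicts-positive); the maximal Youden index
J = sensitivity + specificity − 1 wins, ties preferring the smallest
cutoff, then the high orientation.  Orientation is learned per fold.
Out-of-sample labels come from leave-one-out: the cutoff is re-fit on the
other n−1 patients for every prediction.  Contingency metrics (PPV, NPV,
sensitivity, specificity, accuracy) are exact ratios; a zero denominator
yields NaN and is flagged, never silently 0.

## Categorical naive Bayes

The classifier the pipeline is built around is a from-scratch categorical
naive Bayes: per feature, k equal-frequency bins (edges fit on training
rows only, by default) plus a dedicated missing category; conditionals
Laplace-smoothed,

    P(bin | class) = (count + α) / (n_class + α · n_categories),  α = 1,

priors equal to class frequencies, posteriors computed in log space and
normalized, exact ties resolving to the negative class.  α = 1 is
necessary at this scale: with ~44 training patients and 4 bins, zero-count
cells are certain and unsmoothed products would vanish.  Out-of-range
values at prediction time clamp to the extreme bins.

Two discretization scopes are implemented: `fold` (default; edges re-fit
inside every training fold, leak-free) and `cohort` (edges fit once on the
full matrix, the likely original behavior).  Both are tested; the default
is the conservative one.

Comparator families — L2 logistic regression (standardized inputs),
CART-style decision tree (Gini), random forest (bootstrap + √p feature
subsampling, seeded per subset × fold via a stable hash) — use
scikit-learn with conventional defaults, on the **continuous** features;
only naive Bayes consumes discretized data.

## Power-set screening

All 2¹⁰ − 1 = 1023 non-empty subsets of the top-10 features are evaluated
per family under leave-one-out cross-validation; imputation,
discretization and fitting all happen inside each fold.  The best model
maximizes LOO accuracy, ties broken by parsimony (fewer features), then by
subset name order.

For naive Bayes the screen uses an exact algebraic shortcut: the per-fold,
per-feature bin edges and smoothed log-conditionals do not depend on the
subset, so they are precomputed once per (fold, feature) and every
subset's posterior is a sum over its features.  The fast path is
bit-identical to the generic fold loop (verified by test) and makes the
1023-subset screen cost little more than one LOO run.

### Selection optimism

The headline accuracy is a maximum over 1023 subsets of features that were
themselves selected from ~175 candidates on the same cohort.  On null
cohorts (no planted effect, n = 50) this two-stage selection alone lifts
the best LOO accuracy ≈ 0.2–0.3 above the majority-class baseline.  The
acceptance suite therefore checks null cohorts against a matched
permutation reference (same pipeline on permuted targets): genuine absence
of signal must produce the same optimism as pure noise, within 0.06 on the
mean over 20 seeds (≈ 4 standard errors).  An optional outer-validation
split is available for honest error estimates but is off by default to
mirror the original design.

## Survival analysis

Kaplan–Meier product-limit curves step only at observed event times;
events precede censorings at tied times (the standard convention; censored
subjects at a tied time remain at risk).  The median is the smallest time
with S(t) ≤ 0.5, undefined when never reached.  The two-group log-rank
statistic is (Σ(O − E))²/ΣV with hypergeometric variance terms, referred
to χ²(1).  Curves are computed on the **LOO-predicted strata** to measure
out-of-sample stratification — an unusual design inherited from the
reference workflow; true-label stratification is available by passing the
actual classes as the group vector.  Both estimators are cross-checked
against lifelines in the test suite.

## Synthetic cohort generator

The generator supplies the study conditions every test runs under.
Defaults: 45 patients; negative-binomial cells per patient (mean
2598/45 ≈ 57.7, shape 2); per-patient class propensities Dirichlet around
the reference mix (13.2 % eCTC, 32.6 % CD45pos, 54.2 % other,
concentration 4 — low enough that some patients have zero eCTC, as in the
reference tallies); bone-metastasis prevalence 0.667; log-normal survival
with median 30 months and log-SD 0.9; independent Uniform(0, c) censoring
with c solved so the expected censored fraction is 0.2 (independence keeps
the KM median unbiased).

Features are right-skewed with patient-level random effects:
membrane irregularity z = 1 − circularity is log-normal (leukocytes
rounder than tumor cells), truncated so circularity ∈ (0, 1]; diameter is
log-normal per class (eCTC ≈ 16 µm > other ≈ 12 µm > CD45pos ≈ 10 µm);
perimeter = π·diameter/√circularity × noise; intensities are gamma with a
class × channel expression matrix (eCTC high FITC, CD45pos high APC, all
high DAPI); background-subtracted intensity is a Beta(8,2) fraction of the
mean, guaranteeing bgsub ≤ mean.  None of these distributional parameters
are published for real DEPArray exports; they are fixed, documented
choices.

Effects are planted at the **patient level** (the analysis operates on
per-patient aggregates): short survivors' brightfield-circularity latent
mean shifts by d standardized units (higher circularity ⇒ poor survival),
BM-positive patients' brightfield log-diameter likewise (bigger cells ⇒
bone metastasis); default d = 2.  Because one latent drives all five
aggregate statistics of its feature, and cell size physically drives both
diameter and perimeter, recovery is asserted at the family level
(circularity_brightfield_* for OS; diameter/perimeter_brightfield_* for
BM) — the sibling statistics are exchangeable carriers of one signal and
a single-statistic claim would not be identifiable.

What the generator does **not** model: optics and segmentation noise,
cross-channel correlation of morphology, marker-gating errors,
informative censoring, or any cell-level outcome dependence.  Passing
tests therefore demonstrate that the pipeline recovers patient-level
distributional shifts of the stated size under realistic skew,
missingness and censoring — not that such shifts exist in real cohorts,
nor that real effect sizes match the planted ones.

## Problem sizes and determinism

Unit tests run on 8–20-patient cohorts; recovery and calibration suites
use 45–60 patients × ~20 seeds and 500 log-rank null simulations — the
scale at which the checked properties are statistically meaningful while
the full suite stays fast.  All randomness flows from explicit integer
seeds (`numpy.random.default_rng`); the same configuration and seed
reproduce every artifact byte for byte (reports contain no timestamps).

## Known limitations

* Headline accuracies are optimistically biased by design (see Selection
  optimism); they are comparable to the reference workflow, not to a
  validated clinical classifier.
* Patients censored before the horizon are dropped from classification,
  shrinking n and potentially biasing the case mix when censoring is
  heavy.
* The equal-frequency binning collapses under heavy ties; a feature with
  fewer than k distinct values yields fewer bins (handled, with warnings
  for constants).
* The combined (eCTC + CD45pos) matrix unions two class-specific column
  sets; patients missing one class carry a block of missing values that
  the naive Bayes missing category absorbs but the comparators impute.
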