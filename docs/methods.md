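# Methods

This note documents the statistical procedures implemented in
`claimseg`, the assumptions behind them, the choices made where the
design was genuinely open, and what the synthetic test bed does and
does not demonstrate.

## Cohort definition

The study population consists of patients with a *validated* type 2
diabetes diagnosis and at least one appearance in the outpatient data,
anchored at the first emergency-department visit of the index year
(2016). "Two years prior" means the eight calendar quarters strictly
before the index quarter; "one year prior" the four quarters strictly
before it. The index quarter itself never counts — billing within it
is not care *prior to* the visit.

Validation applies four conditions in order, recording the first that
holds: (1) a confirmed / condition-after diabetes code in at least two
distinct lookback quarters; (2) one such quarter plus a diabetes code
among the index-year ED diagnoses; (3) one diabetes code (outpatient
or ED) plus at least one insulin (ATC A10A) or oral antidiabetic
(A10B) prescription in the lookback; (4) diabetes as main hospital
diagnosis after the ED visit. Because the conditions are ordered,
condition 2 effectively means *exactly* one qualifying outpatient
quarter. Quarters need not be consecutive, and diagnosis and
prescription need not share a quarter.

The diabetes-*type* allocation algorithm of the source analysis is not
publicly documented, so the package ships a reconstruction built from
the stated ingredients, exposed as a plain, overridable rule: type 1
iff E10 without any E11 under insulin-only therapy, or type-1 DMP
enrolment without type-2 enrolment; otherwise type 2 iff E11 coded, an
OAD prescribed or type-2 DMP enrolment; E12–E14-only coders under
insulin-only therapy are "other"; the remainder "unclear". Only type 2
enters the cohort. Users applying the package to real data should
review this rule against their own documentation standard.

ICD matching is prefix-based on dot-stripped codes ("E11" matches
"E11.2"). Outpatient diagnoses count only with qualifier "confirmed"
or "condition after"; ED and hospital diagnoses are accepted as coded.

## Indicators

All utilisation indicators count *distinct calendar quarters* with at
least one qualifying event in the 4-quarter lookback, categorised
0 / 1–2 / 3–4. Quarter granularity is not a modelling preference but a
property of German statutory-health-insurance billing: flat rates per
quarter make within-quarter contact counts meaningless. An indicator
is 0 ("not performed") as soon as the patient appears at least once in
the outpatient data; patients absent from the outpatient tables
entirely get missing utilisation indicators. The medication indicator
is missing — never 0 — for patients of a region that transmitted no
prescription data.

Complication groups are read from the 4th digit of E10–E14 codes:
.0/.1 metabolic, .2 kidney, .3 eye, .4/.5 neuro-vascular, .7 multiple;
.6/.8/.9 name no organ complication and map to no group. This default
map is configurable, since the source analysis also used further
diabetes-specific codes that are not publicly listed.

Ages derive from birth year only (claims carry no birth dates); the
mean age over index-year visits is rounded half-up before banding,
giving deterministic boundary behaviour. The Charlson comorbidity
index uses the Quan ICD-10 mapping with the original weights and the
standard hierarchies (complicated diabetes over uncomplicated,
moderate/severe liver disease over mild, metastatic tumour over other
malignancy), computed over the same 4-quarter window as the other
indicators — the source analysis does not state its window, so one
window is used consistently here.

Billing codes for HbA1c, microalbuminuria, creatinine and fundus
examinations are opaque configurable sets with synthetic placeholder
defaults; real German EBM numbers are regionally versioned and carry
no scientific content for the method.

## Imputation

Missing categories are filled by iterative forest imputation
(missForest-style): mode initialisation, then sweeps over variables in
order of increasing missingness, each variable regressed on all others
with a 100-tree random-forest classifier fitted on its observed rows.
Sweeping stops when the fraction of imputed cells that changed *rises*
relative to the previous sweep (the previous sweep's values are kept),
or after ten sweeps — the ten-sweep figure is treated as a cap, not a
fixed count. Per-sweep forest seeds derive deterministically from the
master seed. Single imputation only; no pooling across multiple
imputations is attempted, matching the single-imputation design of the
source analysis.

## Latent class model

A K-class mixture of independent multinomials. EM runs from random
responsibility initialisations (restart r seeded with master + r), in
log space on a one-hot encoding, with an M-step probability floor of
1e-10 (then renormalisation) to guard against log-domain underflow on
empty cells. Convergence: relative log-likelihood change below 1e-8,
capped at 500 iterations; the best of the restarts by final
log-likelihood is kept, ties to the lower restart index. Likelihood
monotonicity is asserted in the tests on every fit.

Fit statistics: p = (K−1) + K·Σ_j (C_j−1) free parameters;
BIC = −2ℓ + p ln n; entropy EN = −Σ τ ln τ; scaled relative entropy
E = 1 − EN/(n ln K) (defined as 1 for K = 1); ICL = BIC + 2·EN.

For reporting, classes are ordered by a disease-stage score — the mean
expected category code of the medication and complication indicators —
ascending, so class 1 is the earliest-stage class, matching the
early / progressing / progressed narrative. Stability comparisons
never rely on this ordering; they match classes explicitly via optimal
assignment on the confusion matrix.

The per-indicator discriminatory-power score is the class-weighted
Kullback–Leibler divergence of each class-conditional distribution
from the mixture marginal, Σ_k π_k KL(θ_kj ‖ θ̄_j). The source
analysis's exact definition is not public; this default is documented
as the package's own choice (zero for a non-discriminating indicator,
invariant to class relabelling).

## Model selection

The local-independence screen computes Spearman rank correlations on
the ordinal category codes (for binary sex this is the phi-type
association) and flags pairs with |r| ≥ 0.50. Within a flagged pair
the package drops the variable with the *smaller* mean absolute
correlation to the remaining indicators: of two collinear
measurements, the one sharing less structure with the rest of the set
carries mostly idiosyncratic noise and is the redundant copy. (The
alternative caret-style rule — dropping the *larger*-mean-correlation
member — would discard the cleaner measurement whenever one variable
is a noisy copy of another, e.g. it would drop HbA1c rather than the
redundant creatinine indicator in the planted-collinearity scenario.)

Selection fits K = 1..10 on a seeded 70 % training split and collects
BIC, ICL, entropy and the average silhouette width. The ASW uses the
simple-matching distance d(i,i′) = (1/J)·#{j : x_ij ≠ x_i′j}; mean
distances to clusters are computed exactly from cluster-conditional
category frequencies in O(nJ) per cluster, so no subsampling is needed
at cohort scale (a seeded row subsample caps the averaging above
10,000 rows); singleton-cluster members score 0 by convention. The BIC
elbow is the interior K maximising the second difference
BIC(K−1) − 2·BIC(K) + BIC(K+1), ties to the smaller K, with a warning
on a kink-free (linear) sequence.

The decision rule formalises "under consideration of the BIC elbow,
maximum ASW and minimum ICL": the three criterion winners are the
candidates; the smallest K endorsed by at least two criteria is
chosen, else the ASW winner; a candidate violating the constraints
(every class ≥ 5 % of the sample, every class-average MAP posterior
≥ 0.80) is skipped in favour of the next candidate by ASW rank, and
total failure is reported explicitly rather than silently resolved.
The full rule trace is recorded in the selection report.

Partition stability: bootstrap resamples are refit from fresh restarts
and compared with the reference MAP partition on the resampled rows
(pair-counting adjusted Rand index and co-assignment Jaccard index,
both label-invariant; classes additionally matched by maximum
agreement for diagnostics). Hold-out confirmation classifies the
validation split with the training model (E-step only), refits K
fresh on the validation data, compares the two partitions and checks
the 0.80 posterior floor. Whether the source analysis's stability
values came from bootstrap resampling or the split refit is not
stated; both procedures are provided.

## Profiling and regression

Profiling uses hard MAP assignment, as class-wise patient tables
imply; outcome rates are per-patient (recurrent ED use = more than one
visit in the index year; admission = at least one admitted visit).
Odds ratios come from maximum-likelihood logistic regression
(Newton/IRLS, tolerance 1e-10) with Wald 95 % intervals from the
observed information; with a single categorical predictor the fitted
OR equals the contingency-table cross-product ratio, which the tests
assert to 1e-8 over random tables. Wald (not profile-likelihood)
intervals are used because they reproduce the published intervals from
the published counts, which is the verification basis available here.
Separation (a class with constant outcome) raises an error naming the
class. The ED-site outlier filter excludes sites whose mean
diagnoses-per-visit exceeds the cross-site mean by more than three
cross-site standard deviations (an absolute threshold can be supplied
instead); top-10 diagnosis tables use dot-stripped, three-character
codes with lexicographic tie-breaks, counting repeat visits
repeatedly.

## The synthetic test bed

The generator plants a three-class mixture whose class weights
(0.365 / 0.261 / 0.374) equal the published class shares and whose
outcome log-odds equal the published univariate odds ratios (admission
1.27 / 1.38, recurrent visits 1.03 / 1.17 versus class 1) on the
published class-1 baseline rates. The item-response preset follows the
published class narrative — class 1 early stage / high utilisation,
class 2 progressing / low utilisation, class 3 progressed / high
utilisation — and was calibrated once, at design time, to two
requirements the test bed must satisfy simultaneously: classes
separated well enough for reliable recovery (Bayes-classifier adjusted
Rand index ≈ 0.96 against the planted labels), while no indicator pair
other than the planted one approaches the 0.50 collinearity threshold
(maximum other pairwise |r| ≈ 0.45). These two goals trade off
directly, because between-class separation itself induces marginal
correlation among indicators; the preset resolves the tension by
spreading separation across indicators with deliberately different
class-contrast patterns and by using rare-category "tails", which add
likelihood separation with little effect on rank correlations. The
creatinine indicator copies HbA1c with probability 0.5, yielding a
rank correlation of ≈ 0.63, the planted local-independence violation
that the screen must detect. The preset is a plausible stand-in, not
ground truth about any real population.

The claims layer is a constrained inverse of the indicator coding:
category-consistent event placements are drawn uniformly (1–2 or 3–4
distinct lookback quarters), complication groups are planted via E11
4th digits, medication via A10A/A10B prescriptions, and laboratory /
fundus billing rows carry the "other" specialty group so they cannot
disturb the three physician-contact indicators. Every cohort patient
carries confirmed E11 codes in two distinct validation-window
quarters; three distractor archetypes (type-1-only with insulin and
T1DMP; single-quarter E11 coders without corroboration; patients
without any diabetes code) exercise each rejection path. One region,
sized to hold ≈ 20.4 % of patients, is marked non-transmitting and its
prescriptions removed. Comorbidity diagnoses for the Charlson index
and ED / hospital diagnosis codes are drawn from small per-class
pools patterned on the published top-10 tables.

What passing tests show — and what they do not: exact round-trips,
cohort precision/recall of 1, parameter recovery and K = 3 selection
demonstrate the *implementation* is correct under known ground truth.
They do not show that real claims data satisfy local independence,
that real classes are as well separated, or that the reconstruction of
the non-public allocation algorithm matches the original. Real data
also carry features the generator omits: realistic ICD frequency
spectra, coding-practice heterogeneity between providers, age-class
confounding of outcomes (the generator draws outcomes from class alone
by default, so age-adjusted and univariate odds ratios coincide in
expectation), and DMP under-recording.

## Problem sizes and defaults

Defaults were chosen for desk-scale reproducibility: simulated cohorts
of 10,000 patients (plus 500 distractors) for pipeline runs, n = 5,000
for recovery checks, 20 EM restarts for single fits, 5–10 restarts
within the selection grid, 10–20 bootstrap resamples, and the full
K = 1..10 grid. The published study's cohort (40,561 patients) runs
through the same code path unchanged; only wall-clock time differs.
All randomness flows from a single master seed through fixed offsets,
so every reported number is exactly reproducible.
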