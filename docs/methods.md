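# Methods

This note documents the models and procedures implemented in `metkin`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data tests do and do not demonstrate about real cohorts.

## Setting

The package analyses serial CT measurements of individual metastases in
patients with advanced melanoma, before and during treatment with BRAF
inhibitors (BRAFi).  Each lesion is measured as three orthogonal diameters
(two axial, one from a coronal reconstruction) and converted to an ellipsoid
volume `V = (π/6)·d1·d2·d3`.  Three scan anchors structure a patient's
timeline: BBL (the scan before baseline), BL (the last scan before treatment
start), and IR (the first scan on treatment).  An untreated historical cohort
with two scans per patient provides the reference for the spontaneous course.
Time is measured in months (1 month = 30.44 days when converting dates); the
unit choice is internal and all rates scale consistently with it.

## Kinetics indices

For a volume pair `(V1, V2)` observed `Δt` months apart:

* exponential growth rate `aExp = (ln V2 − ln V1)/Δt` (1/month),
* linear slope `aLin = (V2 − V1)/Δt` (cm³/month),
* relative volume change `RVC = (V2 − V1)/V1` (unitless).

Natural logarithms are used throughout; this is forced by the identity
between the lethal-burden score and the inverse crossing time of the
exponential trajectory (below), which only holds with base *e*.

Each index is computed *globally* (on the summed volume of the measurable
lesions) and as a *mean* over per-lesion values; the sample standard
deviation and the range of the per-lesion values quantify inter-metastasis
heterogeneity.  The global exponential rate is not the mean of the
per-lesion rates — the gap between them is itself driven by heterogeneity.

**Missing lesions.**  A lesion can be unmeasurable at one endpoint of a
window (below the 1 cm detection limit).  The default ("floor") policy
excludes such lesions from the per-lesion exponential rate (whose log is
unbounded as volume → 0) but keeps them in RVC and the linear slope by
imputing the volume of a 0.5 cm sphere (≈0.065 cm³) at the missing endpoint:
a sub-threshold lesion has small but nonzero volume, so RVC is bounded below
by about −1 and above by the growth implied by surfacing at the limit.  The
strict alternative ("exclude") drops such lesions from all per-lesion
indices.  Both are implemented; the choice is logged with every profile.

**Single-lesion patients** have no measurable heterogeneity; their spread
fields are emitted as absent (`None`), never as 0, and are excluded from
regressions.  Conflating "no heterogeneity" with "cannot measure
heterogeneity" would bias heterogeneity effects toward the null.

**Post-discontinuation comparison.**  For patients with at least two scans
after stopping therapy, the exponential rates from the two scans bracketing
treatment start are compared with those from the first two post-stop scans.
Each summary (global rate, mean rate, range of rates) is classified
decreased/stable/increased with a symmetric "stable" band of ±5% of the
pre-treatment magnitude (configurable); the ternary classification needs
such a band because an exact tie has measure zero.

## Lethal-burden risk score

The untreated disease is modelled as exponential growth of total burden,
`V(t) = V_BL·exp(aExp_global·t)`, with death when `V(t)` first reaches a
critical burden `V_lethal`.  The prognostic score is the inverse of that
predicted time,

    LB = aExp_global / (ln V_lethal − ln V_BL)    [1/month].

`LB` is 0 for static disease and negative for shrinking disease (the
threshold is never reached); such patients are retained — the score remains
a valid ordering of predicted risk.  Patients whose baseline burden already
meets the candidate threshold get a clipped log-gap (0.05) so their score is
finite and extreme rather than undefined; they are counted in the
calibration trace (`n_flagged`).

**Threshold calibration.**  `V_lethal` is chosen by grid search (default: 60
geometric points on 100–10,000 cm³) against observed overall survival in the
untreated cohort.  Each candidate is scored by a Cox fit of survival on the
LB score under that candidate.  Two criteria are available:

* **concordance** (default): Harrell's C of the fit;
* **partial likelihood**: the maximised Cox partial log-likelihood.

Concordance is the default as a deliberate design choice.  On simulated
cohorts with a known threshold (no measurement noise, no detection
censoring, death exactly at the crossing), concordance recovers the true
threshold within one grid step consistently, whereas the partial likelihood
is maximised at thresholds 2–3× too high: the death hazard is a monotone but
strongly non-log-linear function of LB, and the partial likelihood rewards
thresholds that *straighten* that relationship rather than the one that
generated the deaths.  Ties in the criterion break toward the smaller
threshold, and the full criterion trace over the grid is always returned and
persisted, so the flatness of the criterion around the optimum can be
inspected rather than assumed.

No growth model richer than the exponential is fitted: the score must be
computable from exactly two volume measurements per patient.

## Response classification (RECIST-1.1 proxy)

When no formal RECIST read exists, target lesions are chosen at baseline as
the largest lesions by volume, at most five in total and two per organ
(ties broken by lesion id, making selection order-independent).  Progression
at an assessment is called when any of:

* the sum of target *longest diameters* (the maximum of the three recorded
  diameters) grows ≥20% from its nadir with an absolute increase ≥0.5 cm —
  the standard RECIST 1.1 thresholds, with nadir the smallest sum from
  baseline up to (not including) the assessment;
* a new lesion appears, i.e. first becomes measurable after baseline;
* any non-target lesion at least doubles its baseline volume (treated as
  unequivocal progression).

A volume-based target sum is available behind a flag (`use_volume_sum`,
applied on the cube-root scale so the 20% rule keeps its meaning for
self-similar growth); the diameter sum is the default for fidelity to the
standard.  Lymph-node short-axis special-casing and CR/PR/SD adjudication
are out of scope — only the PD/non-PD distinction feeds the survival models.

**Mixed response** labels a first assessment where at least one lesion
shrinks by ≥30% while another grows by ≥20% (or a clearly shrinking lesion
coexists with a new lesion).  The ±30/+20 thresholds mirror the per-lesion
PR/PD conventions and are configurable; a single lesion is "uniform" by
convention.

## Survival inference

Overall survival is measured from treatment start with **delayed entry** at
the first on-treatment evaluation: a patient contributes to no risk set
before the time at which the cohort's eligibility criteria could have been
assessed.  All fits use the Cox partial likelihood with Efron tie handling
(lifelines `CoxPHFitter` with `entry_col`), Wald 95% intervals for hazard
ratios, and likelihood-ratio tests for model selection.  A continuous
covariate whose positive values span at least two orders of magnitude is
log-transformed before entry; scores that can be non-positive (like LB) are
exempt from the rule.  Functional form is checked graphically by martingale
residuals against the covariate with a lowess smooth.

A constant (zero-variance) covariate is reported with coefficient 0 and
hazard ratio 1 rather than breaking the fit; the null partial likelihood in
that case is computed directly from risk-set counts.

**Covariate screening** mirrors the analysis plan: each candidate is fitted
alone and scored by its likelihood-ratio p-value; among pairs with
|Spearman ρ| > 0.8 only the more significant survives (this is what removes
the SD-based spread measures in favour of ranges, and collapses the highly
correlated response criteria); the survivors plus the anchor covariate
(RECIST PD) enter one joint model.

**Multistate models.**  Two state structures capture dynamic disease status:

* brain model: on-study → brain-mets, on-study → death-other,
  brain-mets → death-brain, brain-mets → death-other;
* RECIST model: on-study → RECIST-PD, on-study → death, RECIST-PD → death.

Patient histories are expanded into stacked counting-process rows (one row
per reachable transition, clock-forward, Markov) and fitted as a single Cox
model stratified by transition, so each transition keeps its own baseline
hazard; covariates act through covariate-by-transition interaction columns,
and the transition set each covariate acts on is configuration, not
hard-coded.  Transitions with too few events (default threshold 5 in the
pipeline) carry no covariate effects — with one or two events a
transition-specific effect is pure separation risk.  A patient already in
the intermediate state at entry contributes no on-study rows.  Baseline-
hazard proportionality across transitions can be tested by fitting the
shared-baseline variant (transition dummies instead of strata) and running a
Schoenfeld-residual test on the dummies; because that residual machinery
does not support delayed entry, the proportionality *test* ignores entry
times (the effect estimates themselves never do) — a documented limitation.
Note that the PD indicator must not enter the RECIST-structure model as a
covariate: it defines the intermediate state there and is perfectly
separated.

## Relative-risk survival tree

The tree implements the LeBlanc–Crowley full-likelihood relative-risk
method (the approach behind rpart's exponential method).  Follow-up is first
rescaled by the cohort Nelson–Aalen cumulative hazard, giving each subject
an expected event count `e_i = H(t_i) − H(t_entry,i)` under the root
baseline (delayed entry subtracts the pre-entry expectation — an extension
over the reference implementation, which ignores entry).  Death counts over
exposures are then a Poisson problem: splits maximise the deviance reduction
under maximum-likelihood node rates, growth stops at `minsplit = 20`,
`minbucket = 7`, depth 10, or when the best gain falls below `cp = 0.01` of
the root deviance (the reference defaults).  Node relative risks are
observed/expected ratios with the rates shrunk toward the root by a gamma
prior with coefficient of variation 1, matching the reference; leaf event
counts therefore sum exactly to the cohort's death count while leaf rates
are stabilised.

Pruning follows cost-complexity cross-validation: the weakest-link subtree
sequence is scored by held-out Poisson deviance over seeded k-fold splits
(trees are regrown per fold, including the fold's own hazard transform), and
the subtree minimising the cross-validated deviance — optionally the
smallest within one standard error — is returned.  Fold assignment is
seeded, so pruning is deterministic given (data, seed).  On covariates
independent of the hazard the pruned tree collapses to the root in most
replicates under the minimum-deviance rule and essentially always under the
1-SE rule.  Routing sends values equal to the threshold left; a missing
split covariate raises an error (no surrogate splits).

An agreement test against R's rpart (method "exp", same controls) on a
common fixture shows identical first splits and leaf relative risks within
2%; rpart serves only as an independent oracle there.

## Synthetic cohorts

The simulator generates the statistical structure the analysis assumes, so
every stage can be exercised and parameter recovery can be verified without
external data:

* lesions per patient: `1 + Poisson(4)` truncated at 20, spread over five
  organ labels (brain weighted 0.15);
* baseline lesion volumes log-normal with median 1.5 cm³ and log-SD 1.1 —
  roughly 1–3 cm lesions with occasional large masses and a fraction below
  the 1 cm detection limit (these surface later and are the model for "new"
  lesions);
* per-lesion pre-treatment exponential rates drawn around a patient mean
  (population mean 0.35/month ≈ a two-month doubling time, between-patient
  SD 0.25, within-patient SD 0.15 — the within-patient spread is what the
  heterogeneity indices measure);
* a lesion-specific multiplicative treatment effect (mean −1.0, SD 0.8), so
  a typical lesion flips to shrinkage while the spread encodes heterogeneous
  primary resistance; responding lesions revert to regrowth after an
  exponential resistance delay (hazard 0.08/month), and 35% of patients
  discontinue at a uniform time in 4–10 months, after which lesions rebound
  at their pre-treatment rate times a lesion-specific factor (SD 0.4) —
  producing the post-discontinuation pattern of similar average speed but
  wider spread;
* death when total (true) burden first crosses `V_lethal = 1200 cm³` on a
  0.01-month grid; the death is attributed to brain disease when brain
  lesions alone exceed half the burden at death (a simulator convention, not
  a mechanistic claim); survivors are censored at 24 months;
* scans at −3 and −0.5 months and on a fixed on-treatment schedule;
  diameters carry 5% log-normal measurement noise and a lesion is recorded
  only if a measured diameter reaches 1 cm.

The published study gives no distributional facts about inter-lesion rate
spread; the values above are assumptions chosen to be clinically plausible,
not estimates, and are all configurable.  Because death is *deterministic*
given the growth curves (exact threshold crossing), the simulated link
between kinetics and survival is far stronger than in real data — simulated
per-SD hazard ratios for the risk score are an order of magnitude larger
than anything observable clinically.  Passing recovery tests therefore shows
the estimators are correct under the model's assumptions; it does not show
the assumptions hold in patients, nor how the scores perform under
real-world outcome noise.

## Numerical choices and degenerate inputs

* Emitted measurement tables round diameters and volumes to 1e-6; identical
  seeds give byte-identical CSVs.
* Rates require strictly positive volumes and intervals; callers apply the
  floor policy before computing logs.
* Calibration grid points where the Cox fit fails (extreme thresholds) score
  −∞ in the trace rather than aborting the search.
* The Wald coverage of the Cox fitter (true HR 2, n = 500, 200 replicates)
  is checked to be ≥90% for nominal 95% intervals.
* Tree deviance terms with zero events contribute 0; exposures are floored
  at 1e-300 inside logs only to avoid −inf on empty children.

## Problem sizes in the tests

Test and acceptance runs use cohorts of 40–100 patients, Markov simulations
of 400–600 subjects, 200-replicate coverage runs at n = 500, and 300-subject
tree fixtures.  These sizes were chosen so every Monte-Carlo assertion has
comfortable margins while the whole suite stays fast to iterate on.

## Known limitations

* The proportionality-of-baselines test ignores delayed entry (see above).
* The RECIST proxy selects targets by volume and measures longest recorded
  diameters; a radiologist's RECIST read can differ (plane restrictions,
  node rules).
* The multistate model is Markov clock-forward; no time-varying coefficients
  or frailty terms.
* No surrogate splits in the tree; subjects with missing split covariates
  must be handled upstream.
* Calibration identifiability degrades when the criterion is flat near the
  optimum (heavily censored or very noisy cohorts); inspect the trace.
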