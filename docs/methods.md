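# Methods

This note documents the models and procedures the package implements, the
defaults it ships, what the synthetic generator does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Code-pattern semantics

Claims phenotypes are written in the compact notation used in published
code lists. The parser assigns each expression exactly one kind from its
syntax; no caller-side disambiguation exists.

| kind | example | matches |
|---|---|---|
| exact | `733.42`, `29914` | string equality after normalization |
| wildcard | `295.xx`, `307.8x` | same category; decimal starts with the fixed digits (none for `.xx`/`.x`) |
| decimal range | `278.00-278.03` | same category; decimal compared as a fixed-width integer |
| category range | `401.xx-405.xx` | category numerically inside the inclusive range |
| bare category | `820` | the category and every 4th/5th-digit subdivision |

Choices worth stating:

* **Fixed-width decimal comparison.** `278.00-278.03` does not match
  `278.8`: one- and two-digit decimals are distinct ICD-9 codes, and the
  shipped metabolic set in fact lists `278.8` separately from the range.
* **Bare categories capture subdivisions.** The hip-fracture exclusion
  (`820`, `821`) is intended to remove any hip fracture, so `820.21`
  matches. An exclusion screen that missed subdivisions would silently
  admit fracture patients.
* **V-codes are case-insensitive** and stored upper-case; the shipped lists
  mix `v15.52` and `V15.82` as printed.
* **Two sleep-disorder entries, `227.4` and `320.20`, sit oddly** among the
  327-series parasomnia and sleep-related-breathing codes and are plausibly
  typos for 327.4x/327.20. They are implemented verbatim; the
  `builtin_registry(overrides=...)` hook lets a study substitute corrected
  lists without code changes. Similarly, `714.0` appears in both the
  exclusion screen and the systemic-arthropathy comorbidity set; both
  placements are kept.
* Therapeutic-class codes are exact 6-character strings; CPT codes are
  exact 5-character strings; wildcard/range notation is ICD-9-only.

## Repository model and validation

Eight tables linked on `person_id`: persons, enrollment spans, direct-care
inpatient and outpatient encounters, purchased institutional stays,
purchased claim lines, pharmacy fills, ancillary procedures. Event tables
are stored as `<table>_FY<year>.csv` partitioned by US federal fiscal year
(Oct 1–Sep 30, keyed on the event date); all dates are ISO calendar dates —
the pipeline operates at day resolution throughout. List-valued cells
(diagnosis codes) are semicolon-joined. Enrollment spans are normalized on
load by merging overlapping and abutting spans.

Validation mirrors warehouse error-file practice: records with a blank
encounter/claim identifier, no diagnosis code, or (for every encounter
table except direct-care outpatient) no procedure code are routed to an
error report, as are direct-care records with a zero visit count
(`visit_count` defaults to 1). Direct-care outpatient records are exempt
from the procedure-code requirement because professional encounters
legitimately lack a CPT. Conservation holds per table: rows in = rows clean
+ rows in error. Records dated within 90 days before the query date are
flagged `immature` — claims lag and monthly cost reconciliation make recent
records unreliable — and retained by default (`--drop-immature` drops
them), since generated data is always mature but the rule must be
exercisable.

## Cohort selection

* Index = the person's **first** qualifying procedure; later qualifying
  procedures are downstream utilization, not new index events. Same-day
  ties break to the smallest code string so results are independent of row
  order.
* Age bounds are inclusive at both ends, in completed years at the index
  date (calendar arithmetic, leap-day safe).
* The exclusion window is **closed at the index date**: a competing
  diagnosis recorded on the surgery day itself indicates the procedure
  targeted that condition. Codes strictly after the index never exclude —
  they may be sequelae of the surgery.
* The 12/24-month windows are fixed day counts (365/730) for
  reproducibility across calendar conventions; both are configurable.
  `gap_tolerance_days` defaults to 0 (the strict reading of continuous
  enrollment); any uncovered run longer than the tolerance fails the
  filter.
* All diagnosis-bearing events are scanned for exclusions, whatever their
  source table; pharmacy fills carry no diagnoses and cannot exclude.

The final membership is invariant to the order the three filters are
applied in (a tested property); only the attrition counts depend on the
order, which is fixed as index → age → exclusion → eligibility.

## Derived variables

* **Comorbidity flags** default to a 12-month pre-index look-back, aligned
  with the eligibility look-back; the window is configurable because no
  canonical flag window exists. Each of the eight sets is evaluated
  independently; the PTSD code 309.81 is covered by `309.xx` inside the
  mental-health set.
* **Visit counting**: direct-care encounters count one each; purchased
  claim lines deduplicate to visits by distinct (person, service date,
  provider), since one clinical visit can generate several lines or
  claims.
* **Costs**: direct care contributes the sum of the 14 full-cost
  subcomponents (FCCLNSAL … FCSUP); purchased care contributes the paid
  amount; pharmacy and ancillary records sit outside the encounter cost
  roll-up. A missing subcomponent is treated as 0 with a logged warning
  (cost fields have near-zero missingness in practice); an unknown
  subcomponent name is rejected at entry. Hip-relatedness uses
  **any-position** diagnosis matching; the shipped hip-related set (the
  exclusion-table hip universe plus joint-pain codes 719.45/719.95) is a
  package default, not a published list, and should be replaced per study.
* **Opioid use**: fills whose therapeutic class is 280808 or 280812;
  `continued_use` = any flagged fill more than 90 days post-index, a
  package-defined operationalization of continued post-surgical use.

## Synthetic generator

The generator emulates the *structural* features the pipeline assumes —
linkage, fiscal-year partitioning, multi-line purchased claims, coded
diagnoses/procedures/prescriptions, full-cost decomposition, enrollment
gaps — not clinical realism. Defaults: 500 persons over a five-fiscal-year
window (2008-10-01 … 2013-09-30), 20% surgery prevalence, comorbidity
prevalences from 4% (systemic arthropathies) to 25% (tobacco use), 3
visits/person-year, 40% of visits purchased with 1–4 claim lines, other
health insurance at 3% (the rate reported for the 18–50 demographic), 50%
post-surgical opioid prescribing. No distributional facts about the real
cohort are published; these defaults are package-chosen and documented as
such.

Mechanics that make the planted truth exactly recoverable:

* Ages at index are uniform 16–55 so the 18–50 filter is exercised on both
  sides; 25% of age-eligible surgical candidates are deliberately sabotaged
  (enrollment gap inside the surveillance window, or a pre-index exclusion
  diagnosis), with the reason recorded — the attrition table has a ground
  truth. A configurable fraction of cohort members also receives a
  *post*-index exclusion diagnosis, which must not remove them.
* Comorbidity-carrying encounters are drawn **from** the person's Poisson
  visit budget (dates moved into the look-back for candidates, diagnosis
  drawn uniformly from the set's expansion) rather than added on top, so a
  flag changes costs only through the planted effect, not through extra
  visits.
* Cost components are gamma distributed (shape 2) — non-negative and
  right-skewed, the stylized shape of healthcare costs — and every encounter
  cost of a person is scaled by exp(Σ planted per-comorbidity effects).
  Because this is a pure scale factor on total encounter cost, a log-scale
  regression of cost on flags identifies the planted weights exactly in
  expectation (default planted effects 0.10–0.50).
* Background diagnoses come from a small benign lexicon verified at
  generation time to match neither the exclusion screen nor any comorbidity
  set.

What passing tests therefore show: the pipeline recovers what was planted
under the stated structure. What they do not show: robustness to coding
error, upcoding, care-seeking correlated with comorbidity, regional
practice variation, or any other behavior of real claims.

Missingness injection supports MCAR (i.i.d. Bernoulli per cell), MAR
(logistic in a fully observed driver), and NMAR (logistic in the target's
own values); the logistic intercept is solved numerically so the expected
missing fraction equals the requested rate, with the slope (default 1, on
the standardized driver) controlling mechanism strength.

## Missing-data workflow

* **EM** for the multivariate-normal mean and ML covariance under ignorable
  missingness groups rows by missingness pattern and uses the conditional
  sweep in both E-step and observed-data log-likelihood; the log-likelihood
  is non-decreasing by construction (tested), convergence is declared below
  a 1e-6 likelihood increase, and a singular within-iteration covariance is
  ridge-regularized with a logged epsilon. Complete data converges in one
  step to the closed form.
* **Little's MCAR test** uses the EM estimates; all patterns with at least
  one row and one observed variable enter the statistic (rows missing every
  variable are excluded with a warning). Complete data reports d² = 0,
  df = 0, p = 1. Monte-Carlo calibration (tested): type-I error within
  [0.025, 0.080] at nominal 5% for n = 200, p = 4, 20% missingness; power
  above 0.5 against a logistic MAR mechanism with slope 2 at n = 500.
* **Chained equations**: cells initialize from random draws of each
  column's observed marginal; each incomplete column is re-imputed in turn
  from a Bayesian linear regression on all other columns (posterior draws
  of β and σ², ridge 1e-8 on the normal equations), for 10 cycles by
  default; m = 10 independent chains by seed offsets. Continuous columns
  use predictive-mean matching with 5 donors (robust to non-normality,
  imputes only observed values); `norm` stochastic-regression draws are
  available; columns whose observed values are all 0/1 use logistic draws.
  The defaults (m, cycles, PMM) are package choices — standard practice,
  not published values.
* **Pooling** follows Rubin's rules; the point estimate is the mean across
  imputations, so "average of the estimated coefficients" and Rubin pooling
  coincide for the bias comparison.
* **Relative bias** is ((B_full − B_missing)/B_full) × 100 per coefficient.
  The printed form of this formula is operator-ambiguous as typeset;
  the implemented reading is the only one that yields a percentage
  difference. Bias is computed for the covariate coefficients — the
  intercept of a centered design is near zero and its relative bias is
  noise — and coefficients with |B_full| < 1e-8 are reported ungradable
  rather than divided by. Grading applies to the absolute value (the sign
  convention is unstated in the source grading scheme) over contiguous
  half-open bands with upper bounds {5, 10, 20, 30}; boundary values fall
  to the lower band, matching the printed "0% to 5% = negligible". The
  published one-decimal band gaps (5 vs 5.1) are closed continuously.
* The sensitivity fit is linear on the configured outcome, with a
  `log_outcome` switch for skewed cost outcomes; the regression family of
  the original analyses is not stated.

## Risk adjustment

OLS of log1p(outcome) on comorbidity-flag indicators (identity scale
available for visit counts); fitted coefficients are the weights, and a
person's score is the linear predictor, mapped back through expm1 on the
log scale. Pairwise interactions ("conditions in combination") are off by
default — with 8 flags the full interaction set would be 28 extra terms —
and limited to pairs when enabled. Flags without variation raise an
unidentifiability error rather than silently dropping. The mechanism is
applied cross-sectionally within the surveillance window; prospective-year
scoring (prior-year diagnoses predicting next-year cost, as in
hierarchical-condition-category systems) is a deliberate simplification
and out of scope, as are proprietary coefficient tables.

## Pipeline and reproducibility

A single global seed fans out to per-stage seeds by SHA-256 of
`"{seed}:{stage}"` (taken mod 2³¹), so stages cannot perturb one another's
random streams; two runs with the same config and seed are byte-identical
(tested). The manifest records a hash of the scientific configuration
(excluding the output location), per-stage status, and record counts.

## Problem sizes used in the checks

The shipped verification suite uses: 20 seeds × (n = 1000, 4 covariates,
m = 10) for the imputation-bias bound; 500 MCAR + 200 MAR replicates for
test calibration; 200 random repositories of ≤50 persons for cohort oracle
equivalence; and repositories of 500/2000/8000 persons for risk-weight
recovery. These sizes give stable Monte-Carlo behavior at the tested
tolerances while keeping a full run in the low minutes on one CPU.

## Known limitations

* Little's test assumes joint normality; non-normal joint models and
  multilevel imputation are out of scope, and no NMAR *correction* is
  offered (NMAR appears only as a stress mechanism).
* The generator plants no propensity structure: comparison-group
  construction and matching are out of scope.
* Pain scores are generated but deliberately unanalyzed (inconsistently
  captured in the emulated source); claim adjudication, update cycles, and
  ICD-10/CPT crosswalks are not modeled.
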