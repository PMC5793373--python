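# claimsforge

Tools for turning multi-source administrative healthcare claims into
longitudinal musculoskeletal-outcome variables — with a synthetic-data
generator standing in for the real (non-distributable) claims warehouse.

The package targets health-services researchers who build surgical cohorts
from claims: it emulates the structure of a military-health-system data
repository (direct-care inpatient and outpatient files, purchased-care
institutional and claim-line files, pharmacy fills, ancillary procedures,
and enrollment spans, all linked on a person identifier and partitioned by
fiscal year) and implements the analysis workflow end to end:

* **Code-set phenotyping** — ICD-9/CPT pattern notation (`295.xx`
  wildcards, `278.00-278.03` decimal ranges, `401.xx-405.xx` category
  ranges, bare categories) with a built-in registry: the four hip-arthroscopy
  inclusion CPT codes (29914, 29915, 29916, 29862), the competing-condition
  exclusion diagnoses, eight comorbidity definitions, and the opiate
  therapeutic classes (280808, 280812).
* **Cohort construction** — index event = first qualifying procedure; then
  age 18–50 at index (completed years, inclusive), no exclusion diagnosis on
  or before the index date, and continuous enrollment for 12 months before
  through 24 months after surgery, with per-filter attrition counts.
* **Variable derivation** — comorbidity flags over the look-back window,
  visit counts with purchased-claim-line deduplication, total versus
  hip-related costs (direct care from the 14 full-cost subcomponents,
  purchased care at paid amount), opioid fills/days' supply, days to first
  rehabilitation/imaging/injection/fill.
* **Missing-data workflow** — Little's MCAR test via an EM fit of the
  multivariate-normal mean and covariance,

      d² = Σⱼ nⱼ (ȳ₍obs,j₎ − μ̂₍obs,j₎)ᵀ Σ̂₍obs,j₎⁻¹ (ȳ₍obs,j₎ − μ̂₍obs,j₎),
      df = Σⱼ pⱼ − p ;

  chained-equations multiple imputation (predictive-mean matching by
  default) pooled by Rubin's rules; and a sensitivity analysis grading the
  per-coefficient relative bias ((B_full − B_missing)/B_full) × 100% into
  severity bands (≤5 negligible, ≤10 minimal, ≤20 moderate, ≤30 heavy,
  >30 severe).
* **Risk adjustment** — regression-based comorbidity weights (OLS on
  log1p cost by default, optionally with pairwise flag interactions) and a
  deterministic per-person risk score.

Every generated repository carries a planted ground truth (cohort
membership, index dates, comorbidity flags, log-scale cost effects), so the
whole pipeline is testable against a known answer.

## Worked example

```bash
cat > run.yaml <<'YAML'
out_dir: demo
seed: 7
generator: {n_persons: 800}
missingness:
  - {mechanism: MCAR, rate: 0.1, target_columns: [visits_total]}
YAML
forge run --config run.yaml
```

The run writes the repository, `truth.json`, `cohort.csv`,
`attrition.csv`, `variables.csv`, `bias.json`, `risk.json`, and a manifest.
The attrition table for this seed:

```
stage,retained,removed
index event identified,177,0
age in range,153,24
no prior exclusion diagnosis,126,27
continuously eligible,109,17
```

177 persons have a qualifying arthroscopy code; 24 are outside 18–50 at
index, 27 carry a competing diagnosis on or before the index date, 17 have
an enrollment gap inside the 36-month surveillance window — leaving a
109-person cohort, which matches the generator's planted truth exactly.
`variables.csv` then holds one row per member (eight comorbidity flags,
visit counts, total and hip-related cost, opioid use, timing), e.g.

```
person_id,index_date,index_cpt,...,visits_total,total_cost,hip_related_cost,...
P000009,2011-01-17,29916,...,11,2218.83,192.68,...
```

and `risk.json` the fitted per-comorbidity log-cost weights with per-person
scores. Library use mirrors the CLI:

```python
from claimsforge.synthetic_claims import GeneratorConfig, generate
from claimsforge.cohort_builder import build_cohort

bundle, truth = generate(GeneratorConfig(n_persons=800, seed=7))
members, attrition = build_cohort(bundle)
assert {m.person_id for m in members} == truth.true_cohort
```

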