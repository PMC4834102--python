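# pipscreen

Screening of longitudinal prescription-dispensing records against explicit
prescribing-appropriateness criteria, with polypharmacy measurement,
prevalence estimation and logistic-regression determinants — plus a
synthetic dispensing-data generator so the whole pipeline is testable
without any real claims data.

## What it does

* **Vocabulary** (`pipscreen.vocabulary`) — drug classes defined by code
  prefixes in two coding dialects (hierarchical ATC codes and dotted BNF
  section codes), a maintenance-dose threshold table, and a declarative
  rule set, all loaded from one YAML config
  (`src/pipscreen/data/default_config.yaml`; fully user-overridable).
* **Cohort** (`pipscreen.cohort`) — eligibility at ages 45–64 (completed
  years at study start), censoring at the month before the 65th birthday
  (switchable), and a 3-month lead-in tagged separately from the
  observation phase.
* **Exposure** (`pipscreen.exposure`) — continuous-use episodes chained
  from dispensings (gap tolerance 63 days, 28-day coverage per dispensing,
  both configurable) with mean daily doses, and per-calendar-month class
  occupancy.
* **Criteria engine** (`pipscreen.criteria`) — five structural rule
  categories: duration, dose + duration, same-month co-prescription,
  first-line (new-user) and same-month duplication. Produces per-patient
  flags, the any-PIP outcome and PIP-count categories (0 / 1 / 2 / 3+).
  Eleven rules ship by default (long-term benzodiazepines, Z-drugs and
  NSAIDs; supra-maintenance PPIs; strong opioids without a laxative;
  first-line first-generation antihistamines and TCAs; duplicate opioids,
  benzodiazepines, NSAIDs and stimulant laxatives).
* **Polypharmacy** (`pipscreen.polypharmacy`) — number of distinct
  medication classes (5-character ATC / BNF section) dispensed ≥3 times in
  the observation year; polypharmacy = ≥4 classes.
* **Statistics** (`pipscreen.stats`) — percent prevalence with Wald 95%
  CIs (Wilson behind a flag), rounded half-up to one decimal; unadjusted
  and adjusted logistic-regression odds ratios via statsmodels.
* **Simulator** (`pipscreen.simulate`) — seeded generator emitting a
  registry, an event stream and a ground-truth table, with plantable
  criterion-positive and boundary-exact criterion-negative patterns;
  with zero background dispensing the engine recovers the planted labels
  with sensitivity = specificity = 1 by construction.

## CLI

```sh
# end-to-end: simulate -> screen -> analyze -> report (+ manifest)
pipscreen run --n-patients 2000 --seed 7 --out-dir out \
    --planted-rate benzo_gt_4w=0.1 --planted-rate opioid_no_laxative=0.05 \
    --background-rate statins=0.2 --polypharmacy-target 0.2

# or stage by stage
pipscreen simulate --n-patients 2000 --seed 7 --out-dir out
pipscreen screen --registry out/registry.csv --events out/events.csv --out-dir out
pipscreen analyze --analysis-table out/analysis_table.csv --out-dir out
```

All inputs/outputs are plain CSV with ISO-8601 dates. `screen` accepts
`--coding-system {ATC,BNF}`, `--include-birthday-month`,
`--duplication-in-any-pip` and `--no-require-any-dispensing`;
`analyze` accepts `--ci-method {wald,wilson}`.

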