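# hrucost

Harmonization and micro-costing of **self-reported healthcare resource
utilization (HRU)** across multi-study substance-use-disorder (SUD)
research.

Comparative-effectiveness studies in SUD/HIV research collect HRU — ED
visits, hospitalizations, outpatient encounters, treatment visits,
problem days, substance spending — with instruments that differ in recall
period (past 30 days, 6 months, 12 months, lifetime) and in question
structure (a single count, or a frequency question paired with a
per-event duration question). Before these data can enter an economic
evaluation they must be audited for missingness, normalized to a common
timeframe, and converted to dollars. `hrucost` implements that pipeline
for health economists and data coordinators, with a built-in catalog
modeled on the baseline instruments of three NIDA Seek, Test, Treat, and
Retain (STTR) studies (PACTo *n*=409, RETAIN *n*=360, BRIGHT 2 *n*=99)
and 2017-USD unit costs (monetary conversion factors, MCFs) from MEPS,
the SAMHSA ADSS cost study, the Medicare physician fee schedule, and
pooled problem-day values.

## The method

For a measure with recall period of *M* months (*M* ∈ {1, 6, 12}) and a
valid count *x*, the per-30-day rate is *x*/*M* — averaging real
observations down rather than extrapolating short recall up. Compound
measures are built **per participant, then averaged**:

- frequency × duration (hospital and residential stays):
  *u_i* = (*x_i*/*M*) · mean(min(*d_ij*, 30)), with each reported
  per-event length *d_ij* capped at 30 days;
- providers × visits-per-provider (outpatient encounters):
  *u_i* = (*x_i*/*M*) · *v_i*.

Mean cost per participant per 30 days is then mean(*u_i*) × MCF for unit-
costed measures, and the reported dollar mean for substance spending (no
MCF). Healthcare-sector cells are summed (before any rounding) into a
per-study TOTAL; societal cells (problem days, spending) are reported but
not totaled.

Before harmonization, every response is classified under a four-category
missingness taxonomy — `absent_blank`, `absent_code` (don't know /
refuse / N/A), `out_of_range` (e.g. 50 ED visits in a 30-day window), and
`incompatible_compound` (zero events but positive per-event duration, or
the reverse) — and removed by **per-measure case deletion**: a
participant invalid on one measure still contributes to all others.

A synthetic-data module generates multi-study survey tables with the
statistical structure this pipeline assumes (zero-inflated negative-
binomial counts, lognormal durations and spending, truncated per-event
recording, all four missingness mechanisms injected with known
probabilities and a truth log), so the full pipeline is testable without
any restricted data.

## Worked example

Feed the degenerate fixture — every participant answering exactly at the
published per-30-day study means — through the whole pipeline:

```python
import hrucost as h
from hrucost.costing import cost_table_frame

catalog = h.default_catalog()
tables = h.constant_mean_fixture(catalog)          # three wide response tables
responses = [r for df in tables.values() for r in h.read_responses(df, catalog)]
classifications = h.classify_all(responses, catalog)
kept, deleted = h.apply_case_deletion(responses, classifications)
utils = h.harmonize_responses(kept, catalog)
summaries = h.summarize_utilization(utils, catalog)
table = h.build_cost_table(summaries, catalog)
frame = cost_table_frame(table, catalog)
print(frame[["measure_id", "unit_cost", "cost_PACTO", "cost_RETAIN", "cost_BRIGHT2"]]
      .head(12).to_string(index=False))
```

prints

```
                 measure_id unit_cost cost_PACTO cost_RETAIN cost_BRIGHT2
                  ed_visits       989        $68         $98         $106
           hospitalizations      4255      $1664       $3157        $1332
     hospital_clinic_visits      1128        $45         $10          $18
    community_clinic_visits      1128        $51         $10          $19
           physician_visits      1128      $4.51       $2.26        $2.26
            mh_visits_psych        85      $2.47       $1.45        $2.47
          mh_visits_medmgmt        44      $0.92       $0.48        $0.88
      residential_treatment       126        $87         $65          $43
        sud_provider_visits       153      $9.49       $1.07        $5.97
sud_provider_visits_medmgmt        44      $1.36       $1.45        $1.63
                      TOTAL                $1934       $3347        $1531
          money_spent_drugs                 $657        $200
```

Each cell is the mean 30-day cost per participant in 2017 USD: e.g.
hospitalization days (0.391 per 30 days in PACTo) × $4255 per inpatient
night = $1664. The TOTAL row sums the ten healthcare-sector cells before
rounding — inpatient days dominate every study. Cells of $10 and above
are reported in whole dollars, smaller cells in cents; a blank cell means
the study did not ask the measure (BRIGHT 2 collected no spending data).

The same stages are available from a shell:

```sh
hrucost simulate --seed 42 --out out/sim        # synthetic tables + truth log
hrucost run --input out/sim --out out/results   # audit, utilization, costs
```

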