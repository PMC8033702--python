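# Methods

## Scope and model

`hrucost` converts heterogeneous self-reported healthcare resource
utilization (HRU) from multi-study baseline surveys into comparable
per-30-day quantities and 2017-USD costs. The pipeline is baseline-only:
it neither models follow-up waves nor longitudinal cost trajectories,
and it performs no inference beyond descriptive means and sample
standard deviations. Cross-study pooling stops at harmonized tables;
integrative analysis of the pooled data is out of scope, as are multiple
imputation (the pipeline implements per-measure case deletion and emits
the audit an imputation model would need), cost-effectiveness ratios,
and criminal-activity costing.

A *measure* is monetizable only if it counts units of service over a
specific recall period. Lifetime counts and binary indicators ("ever
prescribed medication for AUD") are carried in the catalog and audited,
but excluded from harmonization and costing — there is no defensible way
to put a dollar value on "times treated, lifetime".

## Recall normalization

Counts over a recall of *M* months are divided by *M* (1, 6 or 12) to
give a per-30-day rate. The divisor is **months, not days**: a 6-month
recall divides by 6 regardless of whether it is stored as 182 days. The
alternative — multiplying 30-day answers up to 12 months — relies on the
same constant-rate assumption while inventing data points, so averaging
down is the conservative choice. Both directions assume utilization is
stationary over the recall window; the package makes no seasonality
adjustment.

## Compound measures

Frequency×duration measures (hospitalizations, residential/detox stays)
combine an event count with up to `max_recorded_events` (default 5)
per-event durations:

```
u_i = (count_i / M) × mean_j( min(duration_ij, 30) )
```

Choices that matter:

- **Per-event 30-day cap.** Each reported event length is capped at 30
  days *before* averaging, so one 200-day stay cannot contribute more
  days than the window contains. The cap applies only to day-denominated
  event lengths, not to visits-per-provider counts.
- **Mean of products, not product of means.** Each participant's value
  is compounded first and the study mean is taken over those products.
  With skewed, correlated components the two orders differ materially;
  the per-participant order is the one that corresponds to each person's
  actual utilization. A regression test pins this with a two-participant
  example where the orders disagree (3.5 vs 4.5).
- **Truncated recording.** When the count exceeds the number of recorded
  events (instruments capture only the most recent five), the recorded
  durations stand in for all events — the only information available.
  This biases the duration factor toward recent stays for heavy
  utilizers; with the observed event counts the effect is negligible.
- Provider measures compound as (providers/M) × visits-per-provider.

Summaries report the combined value over all contributors, and component
rows (frequency; days-per-event both raw and capped; visits-per-
provider) with the per-event rows conditioned on participants with at
least one event, since "days per hospitalization" is undefined for the
never-hospitalized. Whether published per-event summaries were capped
before or after averaging is not documented; reporting both columns
sidesteps the ambiguity.

## Missingness taxonomy

Each response is classified into exactly one of:

| category | meaning |
|---|---|
| `absent_blank` | a required field left blank |
| `absent_code` | don't know / refuse / N/A, or an unparseable token |
| `out_of_range` | value outside the valid range (e.g. 50 problem days in a 30-day window) |
| `incompatible_compound` | one component of a pair positive, the other zero |

Precedence when problems co-occur is **absence > out_of_range >
incompatible**: the compound rule is only evaluable on present, in-range
values. Three boundary rules:

- zero count with no recorded events is a *valid* true zero (and, for
  provider pairs, a blank visits-per-provider after a zero count is read
  as a structured skip, i.e. also a valid zero);
- a positive count with *no* recorded durations at all is
  `incompatible_compound` (a contradiction between the paired
  questions), whereas a positive count with *some* durations blank is
  `absent_blank`;
- a literal 0 inside a duration slot is routed to the compound rule,
  never to the range rule, even though the per-event valid range floors
  at 1 day.

Valid ranges default to [0, recall-days] for counts (so 50 ED visits is
out of range in a 30-day window but plausible over 6 months), [1, 365]
for per-event days, [0, 10⁶] for dollars; all overridable per measure.
Sentinel codes default to `DK`, `REF`, `NA_` and may be strings or
negative integers. Unknown non-numeric tokens are classified
`absent_code` (recorded verbatim) rather than raising: classification
never fails on data content, only `read_responses` raises, and only on
structural faults (unknown measures, a measure a study never asked,
duplicated rows).

Case deletion is per participant×measure, never listwise. Audit
percentages are reported to one decimal. A measure on which every
participant was deleted surfaces as an empty (n=0, NaN) summary and
poisons its study's cost TOTAL with NaN rather than silently
understating it.

## Costing

Mean per-30-day utilization × unit cost (monetary conversion factor,
MCF), per measure and study. The shipped MCFs are 2017 USD: $989 per ED
visit and $4255 per inpatient night and $1128 per outpatient visit
(MEPS); $126 per residential-treatment day, $153 and $44 per treatment-
provider visit (ADSS); $85 (CPT 90834) and $44 (CPT 99212) per mental-
health visit (Medicare fee schedule); $19 per problem day. Substance
spending is already in dollars and passes through with no MCF. An
`inflation_factor` hook (default 1.0) rescales any MCF for users whose
unit costs are in another price year; mixing price years without factors
warns.

Internal arithmetic is never rounded. At serialization, cells ≥ $10 are
reported in whole dollars and smaller cells in cents, matching the mixed
precision convention of published cost tables; TOTALs are computed from
unrounded cells and rounded last. Healthcare-sector cells are totaled
per study; societal cells (problem days, spending) are reported
untotaled by default (`total_societal=True` enables one) because the two
perspectives are not additive. Measures a study did not ask yield blank
cells — absent, never $0.

## Synthetic data

The generator emulates what the pipeline consumes, not a disease
process. Per study×measure: a Bernoulli(`p_any`) zero-inflation gate; a
shifted negative-binomial positive count (dispersion 0.8; 2.0 for the
window-bounded problem-day counts) — right-skewed and overdispersed,
matching the SD ≫ mean pattern of published summaries; lognormal
per-event days (σ_log = 0.9, rounded to whole days, floor 1) and
lognormal spending (σ_log = 1.2); per-event recording truncated at five.
Default parameters are calibrated so spec-implied harmonized means land
at the published three-study values (`expected_mean_30d` gives the
analytic moment — exact for single counts, dollars and provider pairs,
a continuous approximation for capped rounded durations). Measures are
generated independently: real HRU measures are correlated (a
hospitalization predicts outpatient follow-up), so passing tests show
the pipeline's arithmetic and audit are correct, not that any
covariance structure survives harmonization.

Missingness is injected per response with known per-category
probabilities (defaults 1% blank, 1% code, 0.5% out-of-range, 1%
incompatible-pair — study-level totals inside the published 0–7.5%
band), and each corruption is written to a truth log so recovery tests
compare audit output against recorded truth rather than re-deriving it.
Corruptions are constructed to classify as injected (e.g. out-of-range
corruption of a frequency/duration pair targets a duration when events
exist, keeping the count evaluable so the absence rule cannot fire
first).

Two fixtures: a stochastic three-study dataset (n = 409/360/99), and a
degenerate fixture in which every participant's responses harmonize
exactly to the published per-30-day means (one event of size mean×M per
compound measure, all below the cap). The degenerate fixture is the
vehicle for reproducing published cost cells to the dollar, since the
participant-level data behind the published summaries are not public.

## Numerical and reporting conventions

- Sample (n−1) standard deviations; SD is NaN for n<2.
- Utilization summaries serialize to 3 decimals; audit percentages to 1.
- Bit-reproducibility: all randomness flows from `numpy`
  `default_rng([seed, stream])` with fixed stream offsets per study and
  for injection; identical (spec, seed) gives byte-identical CSV.
- Floating-point checks in tests use 1e-9 absolute tolerance for
  algebraic identities (mean/cost commutation, brute-force equivalence)
  and 3-standard-error bands for stochastic recovery.

## Known limitations

- Harmonized rates assume constant utilization across the recall window;
  recall bias over 6–12 months is not modeled.
- Unit costs are national averages in 2017 USD; no geographic or payer
  adjustment, and the inflation hook is a flat factor, not an index.
- The generator's independence across measures and its parametric
  families are conveniences, not estimates of the restricted source
  data; only its marginal moments are calibrated.
- Exact reproduction of published *stochastic* quantities
  (study missingness profiles, participant-level cost distributions) is
  not possible from printed summaries and is not attempted.
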