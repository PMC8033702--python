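"""Synthetic multi-study survey data with the structure the pipeline assumes.

The generator emulates baseline self-report data from the three STTR
demonstration studies: zero-inflated utilization counts (a Bernoulli "any
use" gate times an overdispersed positive count), right-skewed per-event
durations and spending (lognormal), per-event recording truncated at the
instrument's limit, and all four missingness mechanisms injected with
known probabilities and a first-class truth log.  Measures are drawn
independently of each other — real utilization measures are correlated;
the simplification is deliberate and documented.

Two fixtures are provided:

* :func:`three_study_fixture` — stochastic tables whose harmonized means
  land near the published per-30-day study means;
* :func:`constant_mean_fixture` — a degenerate table in which every
  participant's responses harmonize *exactly* to the published mean, so
  downstream cost cells reproduce the published cost table to the dollar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import LIFETIME, RECALL_MONTHS, Catalog, StudyConfig, default_catalog
from .harmonize import DURATION_CAP_DAYS
from .ingest import DEFAULT_SENTINELS

__all__ = [
    "REFERENCE_MEANS",
    "REFERENCE_COMPONENTS",
    "MeasureParams",
    "MissingnessRates",
    "SynthSpec",
    "default_synth_spec",
    "expected_mean_30d",
    "generate_study",
    "generate_all",
    "inject_missingness",
    "three_study_fixture",
    "constant_mean_fixture",
]


class SynthError(ValueError):
    """Synthesis spec does not cover what a study asks."""


# ---------------------------------------------------------------------------
# Published per-30-day baseline means (2017 USD for spending), used both to
# calibrate the stochastic generator and to build the exact constant fixture.
# ---------------------------------------------------------------------------

#: study_id -> measure_id -> published mean utilization per 30 days.
REFERENCE_MEANS: dict[str, dict[str, float]] = {
    "PACTO": {
        "ed_visits": 0.069, "hospitalizations": 0.391, "residential_treatment": 0.692,
        "hospital_clinic_visits": 0.040, "community_clinic_visits": 0.045,
        "physician_visits": 0.004, "mh_visits_psych": 0.029, "mh_visits_medmgmt": 0.021,
        "sud_provider_visits": 0.062, "sud_provider_visits_medmgmt": 0.031,
        "days_alcohol_problems": 0.785, "days_drug_problems": 8.405,
        "money_spent_alcohol": 22.0, "money_spent_drugs": 657.0,
    },
    "RETAIN": {
        "ed_visits": 0.099, "hospitalizations": 0.742, "residential_treatment": 0.516,
        "hospital_clinic_visits": 0.009, "community_clinic_visits": 0.009,
        "physician_visits": 0.002, "mh_visits_psych": 0.017, "mh_visits_medmgmt": 0.011,
        "sud_provider_visits": 0.007, "sud_provider_visits_medmgmt": 0.033,
        "days_alcohol_problems": 1.591, "days_drug_problems": 4.542,
        "money_spent_alcohol": 68.0, "money_spent_drugs": 200.0,
    },
    "BRIGHT2": {
        "ed_visits": 0.107, "hospitalizations": 0.313, "residential_treatment": 0.341,
        "hospital_clinic_visits": 0.016, "community_clinic_visits": 0.017,
        "physician_visits": 0.002, "mh_visits_psych": 0.029, "mh_visits_medmgmt": 0.020,
        "sud_provider_visits": 0.039, "sud_provider_visits_medmgmt": 0.037,
    },
}

#: study_id -> measure_id -> (event frequency per 30d, days or visits per event).
REFERENCE_COMPONENTS: dict[str, dict[str, tuple[float, float]]] = {
    "PACTO": {
        "hospitalizations": (0.044, 8.837), "residential_treatment": (0.077, 10.206),
        "hospital_clinic_visits": (0.073, 0.532), "community_clinic_visits": (0.049, 1.030),
        "physician_visits": (0.006, 0.575), "mh_visits_psych": (0.056, 0.433),
        "mh_visits_medmgmt": (0.056, 0.400), "sud_provider_visits": (0.060, 0.894),
        "sud_provider_visits_medmgmt": (0.060, 0.810),
    },
    "RETAIN": {
        "hospitalizations": (0.129, 8.110), "residential_treatment": (0.039, 18.714),
        "hospital_clinic_visits": (0.029, 0.297), "community_clinic_visits": (0.035, 0.269),
        "physician_visits": (0.004, 0.555), "mh_visits_psych": (0.023, 1.091),
        "mh_visits_medmgmt": (0.023, 0.396), "sud_provider_visits": (0.009, 0.555),
        "sud_provider_visits_medmgmt": (0.009, 2.137),
    },
    "BRIGHT2": {
        "hospitalizations": (0.055, 5.712), "residential_treatment": (0.013, 25.688),
        "hospital_clinic_visits": (0.031, 0.511), "community_clinic_visits": (0.028, 0.600),
        "physician_visits": (0.003, 0.616), "mh_visits_psych": (0.049, 0.604),
        "mh_visits_medmgmt": (0.049, 0.508), "sud_provider_visits": (0.038, 1.045),
        "sud_provider_visits_medmgmt": (0.038, 1.148),
    },
}


@dataclass(frozen=True)
class MeasureParams:
    """Generative parameters for one study×measure.

    ``p_any`` is the zero-inflation gate.  Positive counts over the recall
    period are ``1 + NegativeBinomial`` with mean ``pos_count_mean`` and
    dispersion ``count_dispersion`` (smaller = more overdispersed).
    ``event_mean`` is the mean per-event quantity: days per event
    (lognormal, rounded to whole days, floor 1) for frequency×duration
    measures, visits per provider (lognormal) for provider measures, and
    dollars for spending measures.
    """

    p_any: float
    pos_count_mean: float = 1.5
    count_dispersion: float = 0.8
    event_mean: float = 0.0
    event_sdlog: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_any <= 1.0):
            raise SynthError(f"p_any must be in [0,1], got {self.p_any}")
        if self.pos_count_mean < 1.0:
            raise SynthError("pos_count_mean is conditional on any use; must be >= 1")


@dataclass(frozen=True)
class MissingnessRates:
    """Per-response injection probabilities for the four mechanisms."""

    p_blank: float = 0.0
    p_code: float = 0.0
    p_out_of_range: float = 0.0
    p_incompatible: float = 0.0

    def __post_init__(self) -> None:
        probs = (self.p_blank, self.p_code, self.p_out_of_range, self.p_incompatible)
        if any(p < 0 or p > 1 for p in probs) or sum(probs) > 1.0 + 1e-12:
            raise SynthError(f"injection probabilities invalid: {probs}")


@dataclass(frozen=True)
class SynthSpec:
    """Full generative specification: per study×measure parameters,
    missingness rates (per measure, with a global default), and the seed
    that makes output bit-reproducible."""

    params: dict[tuple[str, str], MeasureParams]
    missingness: MissingnessRates = MissingnessRates()
    missingness_overrides: dict[tuple[str, str], MissingnessRates] = field(
        default_factory=dict
    )
    seed: int = 0

    def rates_for(self, study_id: str, measure_id: str) -> MissingnessRates:
        return self.missingness_overrides.get((study_id, measure_id), self.missingness)


def default_synth_spec(
    catalog: Catalog | None = None,
    *,
    seed: int = 0,
    missingness: MissingnessRates | None = None,
) -> SynthSpec:
    """Generator parameters calibrated to the published study means.

    For measures without a published mean (items that were never costed),
    modest utilization is assumed; missingness defaults inject roughly
    2.5% per single measure and 3.5% per compound measure, inside the
    published 0–7.5% range.
    """
    catalog = catalog or default_catalog()
    if missingness is None:
        missingness = MissingnessRates(
            p_blank=0.01, p_code=0.01, p_out_of_range=0.005, p_incompatible=0.01
        )
    params: dict[tuple[str, str], MeasureParams] = {}
    for study in catalog.studies:
        ref = REFERENCE_MEANS.get(study.study_id, {})
        comp = REFERENCE_COMPONENTS.get(study.study_id, {})
        for mid, rd in study.recall_days.items():
            m = catalog.measure(mid)
            months = 1 if rd == LIFETIME else RECALL_MONTHS[rd]
            if m.structure == "binary":
                params[(study.study_id, mid)] = MeasureParams(p_any=0.15)
                continue
            if m.structure == "dollars":
                total = ref.get(mid, 50.0)
                p_any = 0.5
                params[(study.study_id, mid)] = MeasureParams(
                    p_any=p_any, event_mean=total / p_any, event_sdlog=1.2
                )
                continue
            if m.is_compound:
                freq, per_event = comp.get(mid, (0.05, 3.0))
                total_count = freq * months
                p_any = min(0.3, max(0.01, total_count / 1.5))
                params[(study.study_id, mid)] = MeasureParams(
                    p_any=p_any,
                    pos_count_mean=max(1.0, total_count / p_any),
                    event_mean=max(per_event, 0.25),
                    event_sdlog=0.9 if m.structure == "frequency_duration" else 0.6,
                )
                continue
            # single_count (incl. problem days and lifetime items); reference
            # means are per 30 days, counts are per recall period
            total = ref[mid] * months if mid in ref else 0.3 * months
            p_any = min(0.7 if m.domain == "problem_days" else 0.35,
                        max(0.01, total / 1.5))
            params[(study.study_id, mid)] = MeasureParams(
                p_any=p_any,
                pos_count_mean=max(1.0, total / p_any),
                # problem-day counts are bounded by the recall window; less
                # overdispersion keeps the clipped mean near its target
                count_dispersion=2.0 if m.domain == "problem_days" else 0.8,
            )
    return SynthSpec(params=params, missingness=missingness, seed=seed)


# ---------------------------------------------------------------------------
# Analytic moments (oracles for parameter-recovery tests)
# ---------------------------------------------------------------------------

def _norm_cdf(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


def _lognormal_capped_mean(mean: float, sdlog: float, cap: float) -> float:
    """E[min(X, cap)] for lognormal X with E[X]=mean (continuous approximation)."""
    mu = math.log(mean) - sdlog**2 / 2.0
    a = (math.log(cap) - mu) / sdlog
    return mean * _norm_cdf(a - sdlog) + cap * (1.0 - _norm_cdf(a))


def expected_mean_30d(
    p: MeasureParams, structure: str, recall_months: int
) -> float:
    """Spec-implied per-30-day mean of the harmonized value.

    Exact for single_count, dollars and provider_visits; for
    frequency×duration measures the duration factor uses the continuous
    lognormal capped mean, a close approximation to the rounded
    whole-day draws actually generated.
    """
    freq = p.p_any * p.pos_count_mean / recall_months
    if structure == "single_count":
        return freq
    if structure == "dollars":
        return p.p_any * p.event_mean / recall_months
    if structure == "provider_visits":
        return freq * p.event_mean
    if structure == "frequency_duration":
        return freq * _lognormal_capped_mean(p.event_mean, p.event_sdlog, DURATION_CAP_DAYS)
    raise SynthError(f"no harmonized mean for structure {structure!r}")


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _wide_columns(study: StudyConfig, catalog: Catalog) -> list[str]:
    cols = ["participant_id", "study_id"]
    for mid in study.recall_days:
        m = catalog.measure(mid)
        cols.append(mid)
        if m.structure == "frequency_duration":
            cols += [f"{mid}__dur{i}" for i in range(1, study.max_recorded_events + 1)]
        elif m.structure == "provider_visits":
            cols.append(f"{mid}__per")
    return cols


def _draw_positive_count(rng: np.random.Generator, p: MeasureParams) -> int:
    extra_mean = p.pos_count_mean - 1.0
    if extra_mean <= 0:
        return 1
    k = p.count_dispersion
    return 1 + int(rng.negative_binomial(k, k / (k + extra_mean)))


def _draw_duration(rng: np.random.Generator, p: MeasureParams) -> int:
    mu = math.log(p.event_mean) - p.event_sdlog**2 / 2.0
    d = rng.lognormal(mu, p.event_sdlog)
    return int(min(365, max(1, round(d))))


def generate_study(
    spec: SynthSpec, study: StudyConfig, catalog: Catalog
) -> pd.DataFrame:
    """Clean (pre-missingness) wide response table for one study.

    Bit-reproducible given (spec, seed); every value is within its valid
    range, so the whole table classifies as valid.
    """
    for mid in study.recall_days:
        if (study.study_id, mid) not in spec.params:
            raise SynthError(
                f"spec has no parameters for measure {mid!r} in study {study.study_id!r}"
            )
    study_index = [s.study_id for s in catalog.studies].index(study.study_id)
    rng = np.random.default_rng([spec.seed, study_index])
    cols = _wide_columns(study, catalog)
    rows = []
    for i in range(study.n_participants):
        row: dict[str, object] = {
            "participant_id": f"{study.study_id}-{i + 1:04d}",
            "study_id": study.study_id,
        }
        for mid, rd in study.recall_days.items():
            m = catalog.measure(mid)
            p = spec.params[(study.study_id, mid)]
            any_use = rng.random() < p.p_any
            if m.structure == "binary":
                row[mid] = int(any_use)
                continue
            if m.structure == "dollars":
                lo, hi = m.count_range_for(rd)
                if any_use:
                    mu = math.log(p.event_mean) - p.event_sdlog**2 / 2.0
                    row[mid] = round(min(hi, rng.lognormal(mu, p.event_sdlog)), 2)
                else:
                    row[mid] = 0.0
                continue
            lo, hi = m.count_range_for(rd)
            count = min(int(hi), _draw_positive_count(rng, p)) if any_use else 0
            row[mid] = count
            if m.structure == "frequency_duration":
                n_rec = min(count, study.max_recorded_events)
                for j in range(1, study.max_recorded_events + 1):
                    row[f"{mid}__dur{j}"] = _draw_duration(rng, p) if j <= n_rec else ""
            elif m.structure == "provider_visits":
                row[f"{mid}__per"] = (
                    round(max(0.25, rng.lognormal(
                        math.log(p.event_mean) - p.event_sdlog**2 / 2.0, p.event_sdlog
                    )), 2)
                    if count > 0
                    else 0.0
                )
        rows.append(row)
    return pd.DataFrame(rows, columns=cols)


def generate_all(spec: SynthSpec, catalog: Catalog) -> dict[str, pd.DataFrame]:
    return {s.study_id: generate_study(spec, s, catalog) for s in catalog.studies}


# ---------------------------------------------------------------------------
# Missingness injection
# ---------------------------------------------------------------------------

def inject_missingness(
    table: pd.DataFrame, spec: SynthSpec, catalog: Catalog
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Corrupt a clean wide table with known mechanisms; return a truth log.

    Per response the four mechanisms fire with the spec's probabilities
    (compound incompatibility only applies to compound measures).  The
    truth log records every corruption (participant, study, measure,
    category) so recovery tests never re-derive what was injected.
    """
    out = table.copy().astype(object)
    log_rows = []
    rng = np.random.default_rng([spec.seed, 10_000])
    for idx, row in table.iterrows():
        study = catalog.study(str(row["study_id"]))
        for mid in study.recall_days:
            if mid not in table.columns:
                continue
            m = catalog.measure(mid)
            r = spec.rates_for(study.study_id, mid)
            u = rng.random()
            thresholds = np.cumsum([r.p_blank, r.p_code, r.p_out_of_range, r.p_incompatible])
            if u >= thresholds[-1]:
                continue
            category = None
            if u < thresholds[0]:
                category = "absent_blank"
                out.at[idx, mid] = ""
                if m.structure == "frequency_duration":
                    for j in range(1, study.max_recorded_events + 1):
                        out.at[idx, f"{mid}__dur{j}"] = ""
                elif m.structure == "provider_visits":
                    out.at[idx, f"{mid}__per"] = ""
            elif u < thresholds[1]:
                category = "absent_code"
                out.at[idx, mid] = DEFAULT_SENTINELS[int(rng.integers(len(DEFAULT_SENTINELS)))]
            elif u < thresholds[2]:
                category = "out_of_range"
                count = float(row[mid]) if str(row[mid]) != "" else 0.0
                offset = int(rng.integers(1, 11))
                if m.structure == "frequency_duration" and count >= 1:
                    # corrupt a recorded duration, keeping the count evaluable
                    _, dhi = m.duration_range
                    out.at[idx, f"{mid}__dur1"] = dhi + offset
                else:
                    _, hi = m.count_range_for(study.recall_days[mid])
                    out.at[idx, mid] = hi + offset
            else:
                if not m.is_compound:
                    continue  # mechanism not applicable; response left valid
                category = "incompatible_compound"
                count = float(row[mid]) if str(row[mid]) != "" else 0.0
                if m.structure == "frequency_duration":
                    if count >= 1:
                        for j in range(1, min(int(count), study.max_recorded_events) + 1):
                            out.at[idx, f"{mid}__dur{j}"] = 0
                    else:
                        out.at[idx, mid] = 0
                        out.at[idx, f"{mid}__dur1"] = int(rng.integers(1, 11))
                else:
                    if count >= 1:
                        out.at[idx, f"{mid}__per"] = 0.0
                    else:
                        out.at[idx, mid] = 0
                        out.at[idx, f"{mid}__per"] = float(rng.integers(1, 6))
            log_rows.append(
                {
                    "participant_id": row["participant_id"],
                    "study_id": study.study_id,
                    "measure_id": mid,
                    "category": category,
                }
            )
    log = pd.DataFrame.from_records(
        log_rows, columns=["participant_id", "study_id", "measure_id", "category"]
    )
    return out, log


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

def three_study_fixture(
    seed: int = 0, catalog: Catalog | None = None, *, with_missingness: bool = True
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame]]:
    """Stochastic three-study dataset calibrated to the published means.

    Returns (tables, truth_logs), keyed by study id.
    """
    catalog = catalog or default_catalog()
    spec = default_synth_spec(catalog, seed=seed)
    tables: dict[str, pd.DataFrame] = {}
    logs: dict[str, pd.DataFrame] = {}
    for study in catalog.studies:
        clean = generate_study(spec, study, catalog)
        if with_missingness:
            tables[study.study_id], logs[study.study_id] = inject_missingness(
                clean, spec, catalog
            )
        else:
            tables[study.study_id] = clean
            logs[study.study_id] = pd.DataFrame(
                columns=["participant_id", "study_id", "measure_id", "category"]
            )
    return tables, logs


def constant_mean_fixture(catalog: Catalog | None = None) -> dict[str, pd.DataFrame]:
    """Degenerate fixture: every participant reproduces the published mean.

    Raw responses are constructed so the harmonized per-30-day value of
    every participant equals the published study mean exactly (compound
    measures use one event whose size is ``mean × months``, all below the
    30-day cap), making the downstream cost table reproduce the published
    cells deterministically.  Measures without a published mean are filled
    with valid constants (zeros; 2 for lifetime items).
    """
    catalog = catalog or default_catalog()
    tables: dict[str, pd.DataFrame] = {}
    for study in catalog.studies:
        ref = REFERENCE_MEANS.get(study.study_id, {})
        row: dict[str, object] = {"study_id": study.study_id}
        for mid, rd in study.recall_days.items():
            m = catalog.measure(mid)
            months = None if rd == LIFETIME else RECALL_MONTHS[rd]
            mean = ref.get(mid)
            if m.structure == "binary":
                row[mid] = 0
            elif rd == LIFETIME:
                row[mid] = 2
            elif m.structure == "dollars":
                row[mid] = mean if mean is not None else 0.0
            elif m.structure == "frequency_duration":
                per_event = 0.0 if mean is None else mean * months
                if per_event > DURATION_CAP_DAYS:
                    raise SynthError(
                        f"cannot build exact fixture for {mid!r}: "
                        f"per-event size {per_event:g} exceeds the 30-day cap"
                    )
                row[mid] = 0 if per_event == 0 else 1
                for j in range(1, study.max_recorded_events + 1):
                    row[f"{mid}__dur{j}"] = per_event if (j == 1 and per_event > 0) else ""
            elif m.structure == "provider_visits":
                per = 0.0 if mean is None else mean * months
                row[mid] = 0 if per == 0 else 1
                row[f"{mid}__per"] = per
            else:  # single_count
                row[mid] = 0.0 if mean is None else mean * months
        rows = []
        for i in range(study.n_participants):
            r = dict(row)
            r["participant_id"] = f"{study.study_id}-{i + 1:04d}"
            rows.append(r)
        tables[study.study_id] = pd.DataFrame(rows, columns=_wide_columns(study, catalog))
    return tables
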