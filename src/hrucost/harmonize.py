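"""Normalization of valid responses to per-30-day utilization quantities.

Recall periods are harmonized by *dividing by the number of months the
recall represents* (1, 6 or 12) — averaging real data points down rather
than extrapolating 30-day answers up, which only adds invented points
under the same constant-rate assumption.

Compound measures are built per participant, then averaged (the
mean-of-products).  For frequency×duration measures each reported
per-event length is capped at 30 days before averaging, so a single long
hospitalization cannot contribute more than a month of days to a 30-day
window:

    value = (count / months) × mean(min(duration_i, 30))

For provider×visits measures: value = (providers / months) × visits per
provider.  Lifetime measures cannot be normalized and raise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import LIFETIME, Catalog
from .ingest import RawResponse

__all__ = [
    "DURATION_CAP_DAYS",
    "HarmonizeError",
    "Utilization30d",
    "UtilizationSummary",
    "normalize_to_30day",
    "cap_event_durations",
    "combine_frequency_duration",
    "combine_provider_visits",
    "harmonize_responses",
    "summarize_utilization",
    "utilization_frame",
    "summary_frame",
]

#: Maximum days a single reported event can contribute.
DURATION_CAP_DAYS = 30.0


class HarmonizeError(ValueError):
    """Attempt to normalize something that has no per-30-day meaning."""


@dataclass(frozen=True)
class Utilization30d:
    """One participant's harmonized quantity for one measure, per 30 days.

    For compound measures ``freq_per_30d`` and ``mean_capped_duration``
    hold the two factors (``value = freq_per_30d × mean_capped_duration``);
    for provider measures ``mean_capped_duration`` carries the
    visits-per-provider factor, uncapped.  ``mean_raw_duration`` keeps the
    pre-cap average event length for the conditional component summaries.
    """

    participant_id: str
    study_id: str
    measure_id: str
    value: float
    freq_per_30d: float | None = None
    mean_capped_duration: float | None = None
    mean_raw_duration: float | None = None
    n_events: int = 0


@dataclass(frozen=True)
class UtilizationSummary:
    """Per study×measure mean and sample SD after case deletion.

    ``component`` distinguishes the combined quantity from its factors:
    ``combined``, ``frequency`` (events per 30 days), ``duration`` /
    ``duration_capped`` (days per event, over participants with >= 1
    event), ``secondary`` (visits per provider, over participants with
    >= 1 provider).  ``sd`` is NaN when fewer than two participants
    contribute.
    """

    study_id: str
    measure_id: str
    component: str
    n: int
    mean: float
    sd: float


def normalize_to_30day(count: float, recall_months: int) -> float:
    """Per-recall-period count -> per-30-day rate (divide by months)."""
    if recall_months == LIFETIME or recall_months is None:
        raise HarmonizeError("measure cannot be normalized: lifetime recall")
    if recall_months not in (1, 6, 12):
        raise HarmonizeError(f"unsupported recall_months {recall_months!r}")
    return count / recall_months


def cap_event_durations(durations, cap: float = DURATION_CAP_DAYS) -> list[float]:
    """Elementwise min(duration, cap); length preserved."""
    return [min(float(d), cap) for d in durations]


def combine_frequency_duration(
    count: float, durations, recall_months: int
) -> tuple[float, float, float]:
    """(value, freq_per_30d, mean_capped_duration) for one participant.

    ``mean_capped_duration`` is the arithmetic mean of the capped recorded
    durations (0 when no events).  When the count exceeds the number of
    recorded events (instrument truncation), the recorded events stand in
    for all of them.
    """
    freq = normalize_to_30day(count, recall_months)
    if count > 0 and len(durations) == 0:
        raise HarmonizeError(
            "positive event count with no durations reached harmonization; "
            "such responses must be removed by case deletion"
        )
    capped = cap_event_durations(durations)
    mean_capped = float(np.mean(capped)) if capped else 0.0
    return freq * mean_capped, freq, mean_capped


def combine_provider_visits(
    n_providers: float, visits_per_provider: float, recall_months: int
) -> tuple[float, float, float]:
    """(value, providers_per_30d, visits_per_provider) for one participant."""
    freq = normalize_to_30day(n_providers, recall_months)
    return freq * visits_per_provider, freq, visits_per_provider


def harmonize_responses(
    valid_responses: list[RawResponse], catalog: Catalog
) -> list[Utilization30d]:
    """Harmonize case-deleted responses to per-30-day quantities.

    Binary measures and lifetime-recall measures carry no per-30-day
    meaning and are skipped; everything else yields one record per
    participant×measure.
    """
    out: list[Utilization30d] = []
    for r in valid_responses:
        m = catalog.measure(r.measure_id)
        s = catalog.study(r.study_id)
        if m.structure == "binary" or s.recall_days[r.measure_id] == LIFETIME:
            continue
        months = s.recall_months(r.measure_id)
        count = float(r.count_value)
        if m.structure == "frequency_duration":
            durations = [float(d) for d in r.event_durations if d is not None]
            value, freq, mean_capped = combine_frequency_duration(count, durations, months)
            out.append(
                Utilization30d(
                    r.participant_id, r.study_id, r.measure_id, value,
                    freq_per_30d=freq, mean_capped_duration=mean_capped,
                    mean_raw_duration=float(np.mean(durations)) if durations else 0.0,
                    n_events=len(durations) if count > 0 else 0,
                )
            )
        elif m.structure == "provider_visits":
            sec = float(r.secondary_count) if r.secondary_count is not None else 0.0
            value, freq, per = combine_provider_visits(count, sec, months)
            out.append(
                Utilization30d(
                    r.participant_id, r.study_id, r.measure_id, value,
                    freq_per_30d=freq, mean_capped_duration=per,
                    mean_raw_duration=per,
                    n_events=int(count > 0),
                )
            )
        else:  # single_count, dollars
            out.append(
                Utilization30d(
                    r.participant_id, r.study_id, r.measure_id,
                    normalize_to_30day(count, months),
                )
            )
    return out


def _mean_sd(values: list[float]) -> tuple[float, float]:
    n = len(values)
    mean = float(np.mean(values)) if n else math.nan
    sd = float(np.std(values, ddof=1)) if n > 1 else math.nan
    if n == 1:
        sd = math.nan  # undefined, flagged as NaN
    return mean, sd


def summarize_utilization(
    utilizations: list[Utilization30d], catalog: Catalog
) -> list[UtilizationSummary]:
    """Per study×measure summaries (mean, sample SD over contributors).

    Combined values are summarized over every contributing participant.
    Component rows for compound measures — event frequency per 30 days,
    and days-per-event both as reported and capped at 30 — condition the
    duration rows on participants with at least one event, mirroring how
    "days per hospitalization" is only defined for people who were
    hospitalized.
    """
    groups: dict[tuple[str, str], list[Utilization30d]] = {}
    for u in utilizations:
        groups.setdefault((u.study_id, u.measure_id), []).append(u)

    # A measure every participant was deleted on still appears, as an empty
    # (n=0, NaN) row — empty is not zero utilization.
    for study_id in {u.study_id for u in utilizations}:
        s = catalog.study(study_id)
        for mid, rd in s.recall_days.items():
            m = catalog.measure(mid)
            if m.structure == "binary" or rd == LIFETIME:
                continue
            groups.setdefault((study_id, mid), [])

    out: list[UtilizationSummary] = []
    study_order = {s.study_id: i for i, s in enumerate(catalog.studies)}
    measure_order = {m.measure_id: i for i, m in enumerate(catalog.measures)}
    for (study_id, measure_id), us in sorted(
        groups.items(),
        key=lambda kv: (study_order.get(kv[0][0], 99), measure_order.get(kv[0][1], 999)),
    ):
        m = catalog.measure(measure_id)
        mean, sd = _mean_sd([u.value for u in us])
        out.append(UtilizationSummary(study_id, measure_id, "combined", len(us), mean, sd))
        if m.is_compound:
            freqs = [u.freq_per_30d for u in us]
            fmean, fsd = _mean_sd(freqs)
            out.append(
                UtilizationSummary(study_id, measure_id, "frequency", len(us), fmean, fsd)
            )
            with_events = [u for u in us if u.n_events > 0]
            if m.structure == "frequency_duration":
                for comp, attr in (
                    ("duration", "mean_raw_duration"),
                    ("duration_capped", "mean_capped_duration"),
                ):
                    dmean, dsd = _mean_sd([getattr(u, attr) for u in with_events])
                    out.append(
                        UtilizationSummary(
                            study_id, measure_id, comp, len(with_events), dmean, dsd
                        )
                    )
            else:
                smean, ssd = _mean_sd([u.mean_capped_duration for u in with_events])
                out.append(
                    UtilizationSummary(
                        study_id, measure_id, "secondary", len(with_events), smean, ssd
                    )
                )
    return out


def utilization_frame(utilizations: list[Utilization30d]) -> pd.DataFrame:
    """Long participant-level table of harmonized values."""
    return pd.DataFrame.from_records(
        [
            {
                "participant_id": u.participant_id,
                "study_id": u.study_id,
                "measure_id": u.measure_id,
                "value_per_30d": u.value,
                "freq_per_30d": u.freq_per_30d,
                "mean_capped_duration": u.mean_capped_duration,
                "mean_raw_duration": u.mean_raw_duration,
                "n_events": u.n_events,
            }
            for u in utilizations
        ],
        columns=[
            "participant_id", "study_id", "measure_id", "value_per_30d",
            "freq_per_30d", "mean_capped_duration", "mean_raw_duration", "n_events",
        ],
    )


def summary_frame(summaries: list[UtilizationSummary]) -> pd.DataFrame:
    """Summary table (means/SDs reported to 3 decimals at serialization)."""
    return pd.DataFrame.from_records(
        [
            {
                "study_id": s.study_id,
                "measure_id": s.measure_id,
                "component": s.component,
                "n": s.n,
                "mean": round(s.mean, 3) if not math.isnan(s.mean) else math.nan,
                "sd": round(s.sd, 3) if not math.isnan(s.sd) else math.nan,
            }
            for s in summaries
        ],
        columns=["study_id", "measure_id", "component", "n", "mean", "sd"],
    )
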