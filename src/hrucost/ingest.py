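"""Reading raw survey tables and auditing missing responses.

Missing data fall into four mutually exclusive categories:

* ``absent_blank``   — a required field was left blank;
* ``absent_code``    — a non-response code ("I don't know", "Refuse to
  respond", "N/A") or an unparseable token;
* ``out_of_range``   — a value outside the measure's valid range (e.g. 50
  ED visits in a 30-day recall);
* ``incompatible_compound`` — for frequency/duration or provider/visit
  pairs, one component positive while the paired component is zero (e.g.
  zero hospitalizations yet 2 days per hospitalization).

Precedence when several problems co-occur is absence > out_of_range >
incompatible_compound: the compound rule is only evaluable on values that
are actually present and in range.  Classification is pure and never raises
on data content; structural problems (unknown measures, duplicated rows)
raise at read time instead.

Case deletion is per participant×measure: a participant invalid on one
measure still contributes to every other measure.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import Catalog, MeasureDefinition, StudyConfig

__all__ = [
    "DEFAULT_SENTINELS",
    "CATEGORIES",
    "IngestError",
    "RawResponse",
    "MissingClassification",
    "read_responses",
    "classify_response",
    "classify_all",
    "audit_missingness",
    "apply_case_deletion",
]

#: Default non-response codes: don't know / refuse / not applicable.
DEFAULT_SENTINELS = ("DK", "REF", "NA_")

#: Missingness categories in audit column order.
CATEGORIES = ("absent_blank", "absent_code", "out_of_range", "incompatible_compound")

BLANK = None  # internal marker for a blank cell


class IngestError(ValueError):
    """Structural problem in an input table (not a data-content problem)."""


@dataclass(frozen=True)
class RawResponse:
    """One participant's raw answer(s) to one measure.

    Each field holds a parsed number, a sentinel-code string, or ``None``
    for blank.  ``event_durations`` exists only for frequency_duration
    measures (days per event, up to ``max_recorded_events``);
    ``secondary_count`` only for provider_visits measures (visits per
    provider).
    """

    participant_id: str
    study_id: str
    measure_id: str
    count_value: float | str | None = None
    event_durations: tuple[float | str | None, ...] = ()
    secondary_count: float | str | None = None


@dataclass(frozen=True)
class MissingClassification:
    """Validity verdict for one response."""

    status: str  # "valid" | "missing"
    category: str  # one of CATEGORIES, or "none" when valid
    detail: str = ""

    def __post_init__(self) -> None:
        assert (self.status == "valid") == (self.category == "none")


_VALID = MissingClassification("valid", "none")


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _numeric_sentinels(sentinels: tuple[str, ...]) -> dict[float, str]:
    out = {}
    for s in sentinels:
        try:
            out[float(s)] = str(s)
        except (TypeError, ValueError):
            pass
    return out


def _parse_cell(value, sentinels: tuple[str, ...]):
    """Blank -> None; numeric -> float; sentinel/other token -> stripped string.

    Sentinels may be strings ("DK") or negative integers (-99); numeric
    sentinels are returned as their code string, never as a value.
    """
    numeric = _numeric_sentinels(sentinels)
    if value is None:
        return BLANK
    if isinstance(value, float) and math.isnan(value):
        return BLANK
    if isinstance(value, (int, float, np.integer, np.floating)):
        v = float(value)
        return numeric.get(v, v)
    s = str(value).strip()
    if s == "":
        return BLANK
    try:
        v = float(s)
    except ValueError:
        return s  # sentinel code or unparseable token; classified as absent_code
    return numeric.get(v, v)


def _duration_columns(measure_id: str, k: int) -> list[str]:
    return [f"{measure_id}__dur{i}" for i in range(1, k + 1)]


def _strip_trailing_blanks(values: list) -> tuple:
    while values and values[-1] is BLANK:
        values.pop()
    return tuple(values)


def read_responses(
    table_source,
    catalog: Catalog,
    *,
    layout: str = "wide",
    sentinels: tuple[str, ...] = DEFAULT_SENTINELS,
) -> list[RawResponse]:
    """Read a raw response table into :class:`RawResponse` records.

    ``table_source`` is a DataFrame, a path, or a file-like object holding
    CSV.  Two layouts are supported:

    * ``wide`` — one row per participant with columns ``participant_id``,
      ``study_id``, then ``<measure_id>`` for the (primary) count,
      ``<measure_id>__dur1 .. __dur<k>`` for per-event durations and
      ``<measure_id>__per`` for visits-per-provider.  A measure column
      missing entirely yields blank responses for that measure.
    * ``long`` — columns ``participant_id, study_id, measure_id, field,
      value`` with ``field`` in ``count``, ``duration_<i>``, ``secondary``.

    One record is produced per participant×measure *asked by that study*
    (catalog-driven); measures a study did not ask are absent, not missing.
    Columns/rows for measures the study did not ask raise
    "measure not in study"; unknown measure ids and duplicated
    participant×measure×field cells raise with the offending rows listed.
    """
    if isinstance(table_source, pd.DataFrame):
        df = table_source.copy()
    else:
        df = pd.read_csv(table_source, dtype=str, keep_default_na=False)
    if layout == "wide":
        return _read_wide(df, catalog, sentinels)
    if layout == "long":
        return _read_long(df, catalog, sentinels)
    raise IngestError(f"unknown layout {layout!r} (expected 'wide' or 'long')")


def _check_base_columns(df: pd.DataFrame, required: list[str]) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise IngestError(f"input table lacks required columns: {missing}")


def _known_wide_columns(catalog: Catalog, max_events: int) -> dict[str, tuple[str, str]]:
    """column name -> (measure_id, role)."""
    cols: dict[str, tuple[str, str]] = {}
    for m in catalog.measures:
        cols[m.measure_id] = (m.measure_id, "count")
        if m.structure == "frequency_duration":
            for i, c in enumerate(_duration_columns(m.measure_id, max_events), start=1):
                cols[c] = (m.measure_id, f"duration_{i}")
        elif m.structure == "provider_visits":
            cols[f"{m.measure_id}__per"] = (m.measure_id, "secondary")
    return cols


def _read_wide(df: pd.DataFrame, catalog: Catalog, sentinels) -> list[RawResponse]:
    _check_base_columns(df, ["participant_id", "study_id"])
    max_events = max((s.max_recorded_events for s in catalog.studies), default=5)
    known = _known_wide_columns(catalog, max_events)
    unknown = [
        c for c in df.columns
        if c not in ("participant_id", "study_id") and c not in known
    ]
    if unknown:
        raise IngestError(f"unknown measure columns: {unknown}")

    dup = df.duplicated(subset=["participant_id", "study_id"])
    if dup.any():
        raise IngestError(
            f"duplicated participant rows: {df.loc[dup, 'participant_id'].tolist()}"
        )

    # A column for a measure some study did not ask must be blank in that
    # study's rows ("a blank cell confers the measure was not asked").
    responses: list[RawResponse] = []
    for study_id, block in df.groupby("study_id", sort=False):
        study = catalog.study(study_id)
        for c in df.columns:
            if c in ("participant_id", "study_id"):
                continue
            mid = known[c][0]
            if not study.asks(mid):
                bad = block[c].map(lambda v: _parse_cell(v, sentinels)) if c in block else None
                if bad is not None and any(v is not BLANK for v in bad):
                    rows = block.loc[[v is not BLANK for v in bad], "participant_id"].tolist()
                    raise IngestError(
                        f"measure {mid!r} not in study {study_id!r} "
                        f"(non-blank values for participants {rows})"
                    )
        for _, row in block.iterrows():
            pid = str(row["participant_id"])
            for mid in study.recall_days:
                m = catalog.measure(mid)
                count = _parse_cell(row.get(mid), sentinels)
                durations: tuple = ()
                secondary = None
                if m.structure == "frequency_duration":
                    vals = [
                        _parse_cell(row.get(c), sentinels)
                        for c in _duration_columns(mid, study.max_recorded_events)
                    ]
                    durations = _strip_trailing_blanks(vals)
                elif m.structure == "provider_visits":
                    secondary = _parse_cell(row.get(f"{mid}__per"), sentinels)
                responses.append(
                    RawResponse(pid, study_id, mid, count, durations, secondary)
                )
    return responses


def _read_long(df: pd.DataFrame, catalog: Catalog, sentinels) -> list[RawResponse]:
    _check_base_columns(df, ["participant_id", "study_id", "measure_id", "field", "value"])
    unknown = sorted(
        set(df["measure_id"]) - {m.measure_id for m in catalog.measures}
    )
    if unknown:
        rows = df.index[df["measure_id"].isin(unknown)].tolist()
        raise IngestError(f"unknown measure_id {unknown} (rows {rows})")
    keycols = ["participant_id", "study_id", "measure_id", "field"]
    dup = df.duplicated(subset=keycols)
    if dup.any():
        raise IngestError(
            "duplicated participant×measure×field rows: "
            f"{df.loc[dup, keycols].to_dict('records')}"
        )

    cells: dict[tuple[str, str], dict[str, dict[str, object]]] = {}
    for _, row in df.iterrows():
        study = catalog.study(str(row["study_id"]))
        mid = str(row["measure_id"])
        if not study.asks(mid):
            raise IngestError(
                f"measure {mid!r} not in study {study.study_id!r} "
                f"(participant {row['participant_id']!r})"
            )
        key = (str(row["participant_id"]), study.study_id)
        cells.setdefault(key, {}).setdefault(mid, {})[str(row["field"])] = _parse_cell(
            row["value"], sentinels
        )

    responses: list[RawResponse] = []
    for (pid, study_id), by_measure in cells.items():
        study = catalog.study(study_id)
        for mid in study.recall_days:
            m = catalog.measure(mid)
            fields = by_measure.get(mid, {})
            count = fields.get("count", BLANK)
            durations: tuple = ()
            secondary = None
            if m.structure == "frequency_duration":
                vals = [
                    fields.get(f"duration_{i}", BLANK)
                    for i in range(1, study.max_recorded_events + 1)
                ]
                durations = _strip_trailing_blanks(vals)
            elif m.structure == "provider_visits":
                secondary = fields.get("secondary", BLANK)
            responses.append(RawResponse(pid, study_id, mid, count, durations, secondary))
    return responses


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _missing(category: str, detail: str) -> MissingClassification:
    return MissingClassification("missing", category, detail)


def _cell_problem(value, rng, what: str):
    """Absence/range verdict for a single cell, or None if the cell is fine."""
    if value is BLANK:
        return _missing("absent_blank", f"{what} left blank")
    if isinstance(value, str):
        return _missing("absent_code", f"{what} answered {value!r}")
    lo, hi = rng
    if not (lo <= value <= hi):
        return _missing("out_of_range", f"{what}={value:g} outside [{lo:g}, {hi:g}]")
    return None


def classify_response(
    r: RawResponse, m: MeasureDefinition, s: StudyConfig
) -> MissingClassification:
    """Classify one raw response as valid or missing (pure, deterministic).

    For compound structures the checks run in fixed precedence: absence of
    any required component, then range violations on any component, then
    the compound-incompatibility rule.  A zero count with no recorded
    events is a true (valid) zero.  A count exceeding the number of
    recorded events is valid when the instrument truncates recording (only
    the ``max_recorded_events`` most recent events are captured); a
    positive count with *no* recorded events is contradictory.
    """
    recall = s.recall_days[r.measure_id]
    count_rng = m.count_range_for(recall)

    problem = _cell_problem(r.count_value, count_rng, "count")
    if m.structure in ("single_count", "dollars", "binary"):
        return problem or _VALID

    if m.structure == "frequency_duration":
        # Absence (blank or code) on any component dominates (precedence 1).
        if problem is not None and problem.category in ("absent_blank", "absent_code"):
            return problem
        nonblank = [d for d in r.event_durations if d is not BLANK]
        if problem is not None:
            # Count present but out of range; duration codes still rank first.
            for d in nonblank:
                if isinstance(d, str):
                    return _missing("absent_code", f"duration answered {d!r}")
            return problem
        count = r.count_value
        # One duration per event up to the recording limit ("up to five most
        # recent"); a larger count than recorded events is truncation, not
        # missingness.  Slots beyond that limit are unused and may be blank,
        # but non-blank extras still participate in code/range/compound checks.
        expected = min(int(math.ceil(count)), s.max_recorded_events) if count > 0 else 0
        slots = list(r.event_durations[:expected])
        slots += [BLANK] * (expected - len(slots))
        extras = [d for d in r.event_durations[expected:] if d is not BLANK]
        if count > 0 and not nonblank:
            # Events reported yet no durations recorded at all: a
            # contradiction between the paired questions, not a blank.
            return _missing(
                "incompatible_compound", f"{count:g} events but no durations recorded"
            )
        for i, d in enumerate(slots, start=1):
            if d is BLANK:
                return _missing("absent_blank", f"duration {i} left blank")
        for d in slots + extras:
            if isinstance(d, str):
                return _missing("absent_code", f"duration answered {d!r}")
        # Range violations (precedence 2).  A literal zero duration is left
        # to the compound rule below, which is the rule that names it.
        lo, hi = m.duration_range
        for d in slots + extras:
            if d < 0 or (d != 0 and not (lo <= d <= hi)):
                return _missing(
                    "out_of_range", f"duration {d:g} outside [{lo:g}, {hi:g}]"
                )
        # Compound incompatibility (precedence 3), symmetric.
        positives = [d for d in slots + extras if d > 0]
        if count == 0 and positives:
            return _missing(
                "incompatible_compound",
                f"zero events but positive duration(s) {positives}",
            )
        if count > 0 and all(d == 0 for d in slots + extras):
            return _missing(
                "incompatible_compound", f"{count:g} events but all durations zero"
            )
        return _VALID

    if m.structure == "provider_visits":
        sec_problem = None
        count = r.count_value if isinstance(r.count_value, float) else None
        if r.secondary_count is BLANK:
            # A blank visits-per-provider after a zero gate question is a
            # structured skip, i.e. a valid zero; blank after a positive
            # count is a missing component.
            if problem is None and count == 0:
                sec_problem = None
            else:
                sec_problem = _missing("absent_blank", "visits per provider left blank")
        else:
            sec_problem = _cell_problem(
                r.secondary_count, count_rng, "visits per provider"
            )
            if (
                sec_problem is not None
                and sec_problem.category == "out_of_range"
                and r.secondary_count == 0
            ):
                sec_problem = None  # zero handled by the compound rule
        for cat in ("absent_blank", "absent_code"):
            for p in (problem, sec_problem):
                if p is not None and p.category == cat:
                    return p
        for p in (problem, sec_problem):
            if p is not None:
                return p
        sec = r.secondary_count if isinstance(r.secondary_count, float) else 0.0
        if (count == 0) != (sec == 0):
            return _missing(
                "incompatible_compound",
                f"{count:g} providers but {sec:g} visits per provider",
            )
        return _VALID

    raise AssertionError(f"unhandled structure {m.structure!r}")


def classify_all(
    responses: list[RawResponse], catalog: Catalog
) -> dict[RawResponse, MissingClassification]:
    """Classify every response; order-independent by construction."""
    return {
        r: classify_response(r, catalog.measure(r.measure_id), catalog.study(r.study_id))
        for r in responses
    }


# ---------------------------------------------------------------------------
# Audit and case deletion
# ---------------------------------------------------------------------------

def audit_missingness(
    responses: list[RawResponse],
    catalog: Catalog,
    classifications: dict[RawResponse, MissingClassification] | None = None,
) -> pd.DataFrame:
    """Per study×measure missingness audit.

    Columns: ``study_id, measure_id, n_asked, n_valid, n_absent_blank,
    n_absent_code, n_out_of_range, n_incompatible, pct_missing`` with
    ``pct_missing = 100 × n_missing / n_asked`` rounded to one decimal.
    """
    if classifications is None:
        classifications = classify_all(responses, catalog)
    rows: dict[tuple[str, str], dict[str, int]] = {}
    for r in responses:
        c = classifications[r]
        key = (r.study_id, r.measure_id)
        counts = rows.setdefault(key, {"n_asked": 0, "n_valid": 0, **{k: 0 for k in CATEGORIES}})
        counts["n_asked"] += 1
        if c.status == "valid":
            counts["n_valid"] += 1
        else:
            counts[c.category] += 1
    records = []
    study_order = {s.study_id: i for i, s in enumerate(catalog.studies)}
    measure_order = {m.measure_id: i for i, m in enumerate(catalog.measures)}
    for (study_id, measure_id), c in sorted(
        rows.items(),
        key=lambda kv: (study_order.get(kv[0][0], 99), measure_order.get(kv[0][1], 999)),
    ):
        n_missing = c["n_asked"] - c["n_valid"]
        records.append(
            {
                "study_id": study_id,
                "measure_id": measure_id,
                "n_asked": c["n_asked"],
                "n_valid": c["n_valid"],
                "n_absent_blank": c["absent_blank"],
                "n_absent_code": c["absent_code"],
                "n_out_of_range": c["out_of_range"],
                "n_incompatible": c["incompatible_compound"],
                "pct_missing": round(100.0 * n_missing / c["n_asked"], 1),
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "study_id", "measure_id", "n_asked", "n_valid", "n_absent_blank",
            "n_absent_code", "n_out_of_range", "n_incompatible", "pct_missing",
        ],
    )


def audit_summary_text(audit: pd.DataFrame) -> str:
    """Human-readable one-line-per-cell summary of the audit table."""
    lines = ["Missingness audit (per study × measure):"]
    for _, row in audit.iterrows():
        lines.append(
            f"  {row.study_id:<10s} {row.measure_id:<28s} "
            f"asked={row.n_asked:<5d} missing={row.n_asked - row.n_valid:<4d} "
            f"({row.pct_missing:.1f}%)"
        )
    return "\n".join(lines)


def apply_case_deletion(
    responses: list[RawResponse],
    classifications: dict[RawResponse, MissingClassification],
) -> tuple[list[RawResponse], pd.DataFrame]:
    """Drop missing responses per participant×measure (never listwise).

    Returns the valid responses (input order preserved) and a deletion log
    with one row per removed response (participant_id, study_id,
    measure_id, category, detail).
    """
    kept: list[RawResponse] = []
    log_rows = []
    for r in responses:
        c = classifications[r]
        if c.status == "valid":
            kept.append(r)
        else:
            log_rows.append(
                {
                    "participant_id": r.participant_id,
                    "study_id": r.study_id,
                    "measure_id": r.measure_id,
                    "category": c.category,
                    "detail": c.detail,
                }
            )
    log = pd.DataFrame.from_records(
        log_rows,
        columns=["participant_id", "study_id", "measure_id", "category", "detail"],
    )
    return kept, log
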