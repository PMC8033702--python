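"""Monetization of harmonized utilization (2017 USD, per participant per 30 days).

Each costable measure's mean per-30-day utilization is multiplied by its
monetary conversion factor (MCF) — a per-unit cost from MEPS, the SAMHSA
ADSS cost study, the Medicare physician fee schedule, or pooled
problem-day values.  Substance-spending measures are already in dollars
and pass through unchanged.  Cells are aggregated into a cost table with
one healthcare-sector TOTAL per study; societal-perspective cells are
reported but not totaled by default.

Internal arithmetic is never rounded.  Report formatting rounds cells of
$10 and above to whole dollars and smaller cells to cents, and TOTALs are
computed from unrounded cells before rounding.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import Catalog, McfEntry
from .harmonize import Utilization30d, UtilizationSummary

__all__ = [
    "CostingError",
    "CostCell",
    "CostTable",
    "cost_measure",
    "cost_problem_days",
    "passthrough_spending",
    "build_cost_table",
    "per_participant_costs",
    "report_dollars",
    "format_dollars",
    "cost_table_frame",
]


class CostingError(ValueError):
    """A costable measure cannot be monetized as requested."""


@dataclass(frozen=True)
class CostCell:
    """Mean 30-day cost for one study×measure (unrounded USD)."""

    study_id: str
    measure_id: str
    perspective: str
    unit_cost: float  # NaN for dollar-denominated (pass-through) measures
    mean_cost: float
    n: int
    source: str = "Self-report"
    code: str | None = None


@dataclass(frozen=True)
class CostTable:
    """All cells plus per-study healthcare-sector totals (unrounded)."""

    cells: tuple[CostCell, ...]
    totals: dict[str, float]  # study_id -> healthcare-sector TOTAL
    price_year: int
    societal_totals: dict[str, float] | None = None


# ---------------------------------------------------------------------------
# Rounding — the single report-formatting implementation
# ---------------------------------------------------------------------------

def report_dollars(x: float) -> float:
    """Report precision: whole dollars at >= $10, cents below (NaN passes)."""
    if math.isnan(x):
        return x
    if abs(x) >= 10:
        return float(round(x))
    return round(x, 2)


def format_dollars(x: float) -> str:
    if math.isnan(x):
        return ""
    r = report_dollars(x)
    return f"${r:.0f}" if abs(x) >= 10 else f"${r:.2f}"


# ---------------------------------------------------------------------------
# Cell-level operations
# ---------------------------------------------------------------------------

def cost_measure(
    mean_utilization: float, mcf: McfEntry, inflation_factor: float = 1.0
) -> float:
    """mean utilization × unit cost (× optional inflation factor), unrounded."""
    if mean_utilization < 0:
        raise CostingError("mean utilization must be nonnegative")
    return mean_utilization * mcf.unit_cost * inflation_factor


#: Problem-day measures are costed exactly like any other MCF measure; the
#: alias names the operation as health economists speak of it.
cost_problem_days = cost_measure


def passthrough_spending(mean_dollars: float) -> float:
    """Spending is reported in dollars already; no MCF is applied."""
    return mean_dollars


# ---------------------------------------------------------------------------
# Table assembly
# ---------------------------------------------------------------------------

def build_cost_table(
    summaries: list[UtilizationSummary],
    catalog: Catalog,
    *,
    inflation_factors: dict[str, float] | None = None,
    total_societal: bool = False,
) -> CostTable:
    """One cost cell per study×costable measure, plus healthcare-sector TOTALs.

    Measures a study did not ask are simply absent (blank), never $0.  A
    missing summary for an asked costable measure is an error; an empty
    (n=0) summary yields an empty (NaN) cell and poisons that study's
    TOTAL rather than silently understating it.
    """
    inflation_factors = inflation_factors or {}
    if len(catalog.price_years) > 1 and not inflation_factors:
        warnings.warn(
            f"MCFs mix price years {sorted(catalog.price_years)} without "
            "inflation factors; costs are not on a single price basis",
            stacklevel=2,
        )
    by_key = {
        (s.study_id, s.measure_id): s for s in summaries if s.component == "combined"
    }
    cells: list[CostCell] = []
    study_ids = sorted(
        {s.study_id for s in summaries},
        key=lambda sid: [st.study_id for st in catalog.studies].index(sid),
    )
    for study_id in study_ids:
        study = catalog.study(study_id)
        for m in catalog.measures:
            if not m.costable or not study.asks(m.measure_id):
                continue
            summ = by_key.get((study_id, m.measure_id))
            if summ is None:
                raise CostingError(
                    f"no utilization summary for costable measure "
                    f"{m.measure_id!r} in study {study_id!r}"
                )
            if m.structure == "dollars":
                mean_cost = passthrough_spending(summ.mean)
                unit_cost, source, code = math.nan, "Self-report", None
            else:
                mcf = catalog.mcf(m.measure_id)
                if mcf is None:
                    raise CostingError(f"no MCF for costable measure {m.measure_id!r}")
                mean_cost = cost_measure(
                    summ.mean if not math.isnan(summ.mean) else math.nan,
                    mcf,
                    inflation_factors.get(m.measure_id, 1.0),
                ) if not math.isnan(summ.mean) else math.nan
                unit_cost, source, code = mcf.unit_cost, mcf.source, mcf.code
            cells.append(
                CostCell(
                    study_id, m.measure_id, m.perspective, unit_cost,
                    mean_cost, summ.n, source, code,
                )
            )

    def _total(persp: str) -> dict[str, float]:
        out = {}
        for sid in study_ids:
            vals = [c.mean_cost for c in cells if c.study_id == sid and c.perspective == persp]
            if vals:
                out[sid] = float(np.sum(vals))  # NaN cells poison the total
        return out

    return CostTable(
        cells=tuple(cells),
        totals=_total("healthcare_sector"),
        price_year=max(catalog.price_years) if catalog.price_years else 0,
        societal_totals=_total("societal") if total_societal else None,
    )


def per_participant_costs(
    utilizations: list[Utilization30d],
    catalog: Catalog,
    *,
    inflation_factors: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Participant-level 30-day costs for every costable measure.

    Zero-cost rows are kept and flagged (``zero_cost``) so reports and
    strip plots can count non-utilizers separately instead of plotting a
    pile of points at $0.
    """
    inflation_factors = inflation_factors or {}
    rows = []
    for u in utilizations:
        m = catalog.measure(u.measure_id)
        if not m.costable:
            continue
        if m.structure == "dollars":
            cost = u.value
            unit_cost = math.nan
        else:
            mcf = catalog.mcf(u.measure_id)
            if mcf is None:
                raise CostingError(f"no MCF for costable measure {u.measure_id!r}")
            cost = cost_measure(u.value, mcf, inflation_factors.get(u.measure_id, 1.0))
            unit_cost = mcf.unit_cost
        rows.append(
            {
                "participant_id": u.participant_id,
                "study_id": u.study_id,
                "measure_id": u.measure_id,
                "perspective": m.perspective,
                "utilization_per_30d": u.value,
                "unit_cost": unit_cost,
                "cost_per_30d": cost,
                "zero_cost": cost == 0.0,
            }
        )
    return pd.DataFrame.from_records(
        rows,
        columns=[
            "participant_id", "study_id", "measure_id", "perspective",
            "utilization_per_30d", "unit_cost", "cost_per_30d", "zero_cost",
        ],
    )


def cost_table_frame(table: CostTable, catalog: Catalog) -> pd.DataFrame:
    """Serialized cost table: one measure per row, one cost column per study.

    Cells are rounded here and only here; a blank cell means the study did
    not ask the measure.  TOTAL rows come from unrounded sums.
    """
    study_ids = sorted(
        {c.study_id for c in table.cells},
        key=lambda sid: [st.study_id for st in catalog.studies].index(sid),
    )
    by_measure: dict[str, dict[str, CostCell]] = {}
    for c in table.cells:
        by_measure.setdefault(c.measure_id, {})[c.study_id] = c

    rows = []
    for persp in ("healthcare_sector", "societal"):
        for m in catalog.measures:
            if m.measure_id not in by_measure or m.perspective != persp:
                continue
            cells = by_measure[m.measure_id]
            any_cell = next(iter(cells.values()))
            row = {
                "perspective": persp,
                "measure_id": m.measure_id,
                "label": m.label,
                "mcf_source": any_cell.source,
                "mcf_code": any_cell.code or "",
                "unit_cost": "" if math.isnan(any_cell.unit_cost) else f"{any_cell.unit_cost:g}",
            }
            for sid in study_ids:
                cell = cells.get(sid)
                row[f"cost_{sid}"] = "" if cell is None else format_dollars(cell.mean_cost)
            rows.append(row)
        if persp == "healthcare_sector":
            row = {
                "perspective": persp, "measure_id": "TOTAL", "label": "TOTAL",
                "mcf_source": "", "mcf_code": "", "unit_cost": "",
            }
            for sid in study_ids:
                row[f"cost_{sid}"] = (
                    format_dollars(table.totals[sid]) if sid in table.totals else ""
                )
            rows.append(row)
        elif table.societal_totals is not None:
            row = {
                "perspective": persp, "measure_id": "TOTAL", "label": "TOTAL",
                "mcf_source": "", "mcf_code": "", "unit_cost": "",
            }
            for sid in study_ids:
                row[f"cost_{sid}"] = (
                    format_dollars(table.societal_totals[sid])
                    if sid in table.societal_totals
                    else ""
                )
            rows.append(row)
    return pd.DataFrame.from_records(rows)
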