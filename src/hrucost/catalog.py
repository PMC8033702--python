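"""Declarative catalog of survey measures, studies, and monetary conversion factors.

A *measure* is one self-reported healthcare-resource-utilization (HRU)
question (or question pair) — e.g. hospital-based emergency department
visits in the past 6 months.  A *study* maps each measure it asked to a
recall period.  A *monetary conversion factor* (MCF) is the per-unit 2017
USD cost applied to a harmonized utilization quantity.

The built-in :func:`default_catalog` encodes the baseline instruments of
three NIDA Seek, Test, Treat, and Retain (STTR) demonstration studies
(PACTo, RETAIN, BRIGHT 2) together with published unit costs drawn from the
Medical Expenditure Panel Survey, the SAMHSA Alcohol and Drug Services
Study, the Medicare physician fee schedule, and pooled problem-day values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import yaml

__all__ = [
    "LIFETIME",
    "RECALL_MONTHS",
    "ConfigError",
    "MeasureDefinition",
    "StudyConfig",
    "McfEntry",
    "Catalog",
    "default_catalog",
    "load_catalog",
    "dump_catalog",
]

#: Sentinel recall period for lifetime questions (cannot be normalized or costed).
LIFETIME = "lifetime"

#: Recall period in days -> number of months represented.  Normalization
#: divides by months (1, 6 or 12), not by days; the day counts are metadata.
RECALL_MONTHS = {30: 1, 182: 6, 365: 12}

DOMAINS = frozenset(
    {"general_medical", "sud_treatment", "medications", "spending", "problem_days"}
)
PERSPECTIVES = frozenset({"healthcare_sector", "societal", "none"})
STRUCTURES = frozenset(
    {"single_count", "frequency_duration", "provider_visits", "dollars", "binary"}
)
#: Structures that can be monetized.  Binary and lifetime measures cannot.
COSTABLE_STRUCTURES = frozenset(
    {"single_count", "frequency_duration", "provider_visits", "dollars"}
)


class ConfigError(ValueError):
    """Catalog/configuration schema or referential-integrity violation."""


@dataclass(frozen=True)
class MeasureDefinition:
    """One survey measure.

    ``count_range`` is the inclusive valid range for the per-recall-period
    count (``None`` → derived per study as ``[0, recall_days]``);
    ``duration_range`` is the inclusive valid range for per-event durations
    of frequency×duration measures.
    """

    measure_id: str
    label: str
    domain: str
    perspective: str
    structure: str
    unit: str
    costable: bool
    count_range: tuple[float, float] | None = None
    duration_range: tuple[float, float] = (1.0, 365.0)

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ConfigError(f"measure {self.measure_id!r}: unknown domain {self.domain!r}")
        if self.perspective not in PERSPECTIVES:
            raise ConfigError(
                f"measure {self.measure_id!r}: unknown perspective {self.perspective!r}"
            )
        if self.structure not in STRUCTURES:
            raise ConfigError(
                f"measure {self.measure_id!r}: unknown structure {self.structure!r}"
            )
        if self.costable and self.structure not in COSTABLE_STRUCTURES:
            raise ConfigError(
                f"measure {self.measure_id!r}: structure {self.structure!r} cannot be costable"
            )
        for name, rng in (("count_range", self.count_range), ("duration_range", self.duration_range)):
            if rng is None:
                continue
            lo, hi = rng
            if lo < 0 or hi < lo:
                raise ConfigError(f"measure {self.measure_id!r}: invalid {name} {rng!r}")

    @property
    def is_compound(self) -> bool:
        return self.structure in ("frequency_duration", "provider_visits")

    def count_range_for(self, recall_days: int | str) -> tuple[float, float]:
        """Valid count range under a study's recall period."""
        if self.count_range is not None:
            return self.count_range
        if self.structure == "dollars":
            return (0.0, 1_000_000.0)
        if self.structure == "binary":
            return (0.0, 1.0)
        if recall_days == LIFETIME:
            return (0.0, 10_000.0)
        return (0.0, float(recall_days))


@dataclass(frozen=True)
class StudyConfig:
    """One study: which measures it asked and over what recall period.

    ``recall_days`` maps measure_id -> 30 | 182 | 365 | ``LIFETIME``; a
    measure absent from the map was not asked in that study (a blank cell),
    which is different from a missing response.
    """

    study_id: str
    recall_days: dict[str, int | str]
    n_participants: int
    max_recorded_events: int = 5

    def __post_init__(self) -> None:
        if self.max_recorded_events < 1:
            raise ConfigError(f"study {self.study_id!r}: max_recorded_events must be >= 1")
        if self.n_participants < 1:
            raise ConfigError(f"study {self.study_id!r}: n_participants must be >= 1")
        for mid, rd in self.recall_days.items():
            if rd != LIFETIME and rd not in RECALL_MONTHS:
                raise ConfigError(
                    f"study {self.study_id!r}, measure {mid!r}: "
                    f"recall_days must be one of {sorted(RECALL_MONTHS)} or {LIFETIME!r}, got {rd!r}"
                )

    def asks(self, measure_id: str) -> bool:
        return measure_id in self.recall_days

    def recall_months(self, measure_id: str) -> int:
        """Months represented by the recall period (normalization divisor)."""
        rd = self.recall_days[measure_id]
        if rd == LIFETIME:
            raise ConfigError(
                f"measure {measure_id!r} has lifetime recall in study {self.study_id!r} "
                "and cannot be normalized"
            )
        return RECALL_MONTHS[rd]


@dataclass(frozen=True)
class McfEntry:
    """Monetary conversion factor: USD per unit of one measure."""

    measure_id: str
    unit_cost: float
    price_year: int
    source: str
    code: str | None = None

    def __post_init__(self) -> None:
        if self.unit_cost < 0 or not math.isfinite(self.unit_cost):
            raise ConfigError(f"mcf {self.measure_id!r}: unit_cost must be >= 0")


@dataclass
class Catalog:
    """Validated triple of measures, studies and MCFs with lookup helpers."""

    measures: list[MeasureDefinition]
    studies: list[StudyConfig]
    mcfs: list[McfEntry]
    _measure_index: dict[str, MeasureDefinition] = field(
        init=False, repr=False, compare=False, default_factory=dict
    )
    _study_index: dict[str, StudyConfig] = field(
        init=False, repr=False, compare=False, default_factory=dict
    )
    _mcf_index: dict[str, McfEntry] = field(
        init=False, repr=False, compare=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        self.validate()

    def __iter__(self):
        # Allows ``measures, studies, mcfs = catalog``.
        return iter((self.measures, self.studies, self.mcfs))

    def measure(self, measure_id: str) -> MeasureDefinition:
        return self._measure_index[measure_id]

    def study(self, study_id: str) -> StudyConfig:
        return self._study_index[study_id]

    def mcf(self, measure_id: str) -> McfEntry | None:
        return self._mcf_index.get(measure_id)

    def validate(self) -> None:
        if not self.measures:
            raise ConfigError("no measures defined")
        self._measure_index = {}
        for m in self.measures:
            if m.measure_id in self._measure_index:
                raise ConfigError(f"duplicate measure_id {m.measure_id!r}")
            self._measure_index[m.measure_id] = m
        self._study_index = {}
        for s in self.studies:
            if s.study_id in self._study_index:
                raise ConfigError(f"duplicate study_id {s.study_id!r}")
            self._study_index[s.study_id] = s
            for mid, rd in s.recall_days.items():
                if mid not in self._measure_index:
                    raise ConfigError(
                        f"study {s.study_id!r} references unknown measure_id {mid!r}"
                    )
                if rd == LIFETIME and self._measure_index[mid].costable:
                    raise ConfigError(
                        f"costable measure {mid!r} has lifetime recall in study {s.study_id!r}"
                    )
        self._mcf_index = {}
        for e in self.mcfs:
            if e.measure_id not in self._measure_index:
                raise ConfigError(f"mcf references unknown measure_id {e.measure_id!r}")
            if e.measure_id in self._mcf_index:
                raise ConfigError(f"duplicate mcf for measure_id {e.measure_id!r}")
            m = self._measure_index[e.measure_id]
            if not m.costable:
                raise ConfigError(f"mcf given for non-costable measure {e.measure_id!r}")
            if m.structure == "dollars":
                raise ConfigError(
                    f"mcf given for dollar-denominated measure {e.measure_id!r} "
                    "(spending is passed through without conversion)"
                )
            self._mcf_index[e.measure_id] = e
        # Every costable non-dollars measure actually asked somewhere needs a unit cost.
        asked = {mid for s in self.studies for mid in s.recall_days}
        for m in self.measures:
            if (
                m.costable
                and m.structure != "dollars"
                and m.measure_id in asked
                and m.measure_id not in self._mcf_index
            ):
                raise ConfigError(f"no mcf defined for costable measure {m.measure_id!r}")

    @property
    def price_years(self) -> set[int]:
        return {e.price_year for e in self.mcfs}


# ---------------------------------------------------------------------------
# Built-in default catalog: three STTR studies, 2017 USD unit costs
# ---------------------------------------------------------------------------

_MEPS = "Medical Expenditure Panel Survey"
_ADSS = "ADSS cost study (SAMHSA 1997)"
_PFS = "Medicare physician fee schedule"
_PROBLEM_DAY = "McCollister, Yang (pooled problem-day values)"

# (measure_id, label, domain, perspective, structure, unit, costable)
_DEFAULT_MEASURES = [
    ("ed_visits", "Emergency department visits (hospital-based)",
     "general_medical", "healthcare_sector", "single_count", "visits", True),
    ("hospitalizations", "Hospitalizations",
     "general_medical", "healthcare_sector", "frequency_duration", "days", True),
    ("hospital_clinic_visits", "Hospital clinic / outpatient department visits",
     "general_medical", "healthcare_sector", "provider_visits", "visits", True),
    ("community_clinic_visits", "Community clinic / neighborhood health center visits",
     "general_medical", "healthcare_sector", "provider_visits", "visits", True),
    ("physician_visits", "Physician visits",
     "general_medical", "healthcare_sector", "provider_visits", "visits", True),
    ("mh_visits_psych", "Mental healthcare provider visits (psychological / emotional issues)",
     "general_medical", "healthcare_sector", "provider_visits", "visits", True),
    ("mh_visits_medmgmt", "Mental healthcare provider visits (medication management)",
     "general_medical", "healthcare_sector", "provider_visits", "visits", True),
    ("dental_visits", "Dental care visits",
     "general_medical", "none", "single_count", "visits", False),
    ("emergency_dental_visits", "Emergency dental care visits",
     "general_medical", "none", "single_count", "visits", False),
    ("trauma_counseling_visits", "Provider visits for trauma counseling",
     "general_medical", "none", "single_count", "visits", False),
    ("shelter_nights", "Nights in homeless or emergency shelter",
     "general_medical", "none", "single_count", "nights", False),
    ("case_manager_visits", "Case managers or case workers",
     "general_medical", "none", "single_count", "visits", False),
    ("times_treated_alcohol", "Times treated for alcohol use",
     "sud_treatment", "none", "single_count", "episodes", False),
    ("times_treated_sud", "Times treated for substance use disorder",
     "sud_treatment", "none", "single_count", "episodes", False),
    ("residential_treatment",
     "Residential drug or alcohol treatment facility / detoxification hospital",
     "sud_treatment", "healthcare_sector", "frequency_duration", "days", True),
    ("sud_provider_visits", "Alcohol / drug treatment provider visits",
     "sud_treatment", "healthcare_sector", "provider_visits", "visits", True),
    ("sud_provider_visits_medmgmt",
     "Alcohol / drug treatment provider visits (medication management)",
     "sud_treatment", "healthcare_sector", "provider_visits", "visits", True),
    ("rx_med_aud", "Prescribed medication for alcohol use disorder",
     "medications", "none", "binary", "indicator", False),
    ("rx_med_sud", "Prescribed medication for substance use disorder",
     "medications", "none", "binary", "indicator", False),
    ("money_spent_drugs", "Money spent on drugs",
     "spending", "societal", "dollars", "USD", True),
    ("money_spent_alcohol", "Money spent on alcohol",
     "spending", "societal", "dollars", "USD", True),
    ("days_alcohol_problems", "Days experiencing alcohol problems",
     "problem_days", "societal", "single_count", "days", True),
    ("days_drug_problems", "Days experiencing drug problems",
     "problem_days", "societal", "single_count", "days", True),
]

# PACTo and RETAIN share one instrument layout; BRIGHT 2 used 12-month
# recall, lacked the dental/trauma/shelter, spending and problem-day items,
# and asked the medication items over lifetime.
_PACTO_RETAIN_RECALL: dict[str, int | str] = {
    "ed_visits": 182, "hospitalizations": 182, "hospital_clinic_visits": 182,
    "community_clinic_visits": 182, "physician_visits": 182,
    "mh_visits_psych": 182, "mh_visits_medmgmt": 182,
    "dental_visits": 182, "emergency_dental_visits": 182,
    "trauma_counseling_visits": 182, "shelter_nights": 182,
    "case_manager_visits": 182,
    "times_treated_alcohol": LIFETIME, "times_treated_sud": LIFETIME,
    "residential_treatment": 182, "sud_provider_visits": 182,
    "sud_provider_visits_medmgmt": 182,
    "rx_med_aud": 30, "rx_med_sud": 30,
    "money_spent_drugs": 30, "money_spent_alcohol": 30,
    "days_alcohol_problems": 30, "days_drug_problems": 30,
}

_BRIGHT2_RECALL: dict[str, int | str] = {
    "ed_visits": 365, "hospitalizations": 365, "hospital_clinic_visits": 365,
    "community_clinic_visits": 365, "physician_visits": 365,
    "mh_visits_psych": 365, "mh_visits_medmgmt": 365,
    "case_manager_visits": 365,
    "times_treated_alcohol": LIFETIME, "times_treated_sud": LIFETIME,
    "residential_treatment": 365, "sud_provider_visits": 365,
    "sud_provider_visits_medmgmt": 365,
    "rx_med_aud": LIFETIME, "rx_med_sud": LIFETIME,
}

# (measure_id, unit_cost USD, source, billing code)
_DEFAULT_MCFS = [
    ("ed_visits", 989.0, _MEPS, None),
    ("hospitalizations", 4255.0, _MEPS, None),           # inpatient stay, per night
    ("residential_treatment", 126.0, _ADSS, None),       # residential treatment, per day
    ("hospital_clinic_visits", 1128.0, _MEPS, None),
    ("community_clinic_visits", 1128.0, _MEPS, None),
    ("physician_visits", 1128.0, _MEPS, None),
    ("mh_visits_psych", 85.0, _PFS, "90834"),
    ("mh_visits_medmgmt", 44.0, _PFS, "99212"),
    ("sud_provider_visits", 153.0, _ADSS, None),
    ("sud_provider_visits_medmgmt", 44.0, _ADSS, None),
    ("days_alcohol_problems", 19.0, _PROBLEM_DAY, None),
    ("days_drug_problems", 19.0, _PROBLEM_DAY, None),
]

PRICE_YEAR = 2017


def default_catalog() -> Catalog:
    """The built-in three-study catalog (PACTo n=409, RETAIN n=360, BRIGHT 2 n=99)."""
    measures = [
        MeasureDefinition(
            measure_id=mid, label=label, domain=dom, perspective=persp,
            structure=struct, unit=unit, costable=costable,
        )
        for mid, label, dom, persp, struct, unit, costable in _DEFAULT_MEASURES
    ]
    studies = [
        StudyConfig("PACTO", dict(_PACTO_RETAIN_RECALL), n_participants=409),
        StudyConfig("RETAIN", dict(_PACTO_RETAIN_RECALL), n_participants=360),
        StudyConfig("BRIGHT2", dict(_BRIGHT2_RECALL), n_participants=99),
    ]
    mcfs = [
        McfEntry(mid, cost, PRICE_YEAR, source, code)
        for mid, cost, source, code in _DEFAULT_MCFS
    ]
    return Catalog(measures, studies, mcfs)


# ---------------------------------------------------------------------------
# YAML (de)serialization
# ---------------------------------------------------------------------------

def _measure_to_dict(m: MeasureDefinition) -> dict:
    d = {
        "measure_id": m.measure_id, "label": m.label, "domain": m.domain,
        "perspective": m.perspective, "structure": m.structure, "unit": m.unit,
        "costable": m.costable,
    }
    if m.count_range is not None:
        d["count_range"] = list(m.count_range)
    if m.duration_range != (1.0, 365.0):
        d["duration_range"] = list(m.duration_range)
    return d


def dump_catalog(catalog: Catalog) -> str:
    """Serialize a catalog to the structured text (YAML) config format."""
    doc = {
        "measures": [_measure_to_dict(m) for m in catalog.measures],
        "studies": [
            {
                "study_id": s.study_id,
                "n_participants": s.n_participants,
                "max_recorded_events": s.max_recorded_events,
                "recall_days": dict(s.recall_days),
            }
            for s in catalog.studies
        ],
        "mcfs": [
            {
                "measure_id": e.measure_id, "unit_cost": e.unit_cost,
                "price_year": e.price_year, "source": e.source,
                **({"code": e.code} if e.code is not None else {}),
            }
            for e in catalog.mcfs
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)


def _require(d: dict, key: str, section: str) -> object:
    if key not in d:
        raise ConfigError(f"{section}: missing required field {key!r}")
    return d[key]


def load_catalog(config_text: str) -> Catalog:
    """Parse and validate a YAML catalog config (sections measures/studies/mcfs).

    Extra top-level sections (e.g. ``synth``) are ignored here; the
    synthetic-data module reads its own section.
    """
    try:
        doc = yaml.safe_load(config_text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"config does not parse: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError("config must be a mapping with sections measures/studies/mcfs")

    measures = []
    for raw in doc.get("measures") or []:
        kwargs = dict(
            measure_id=_require(raw, "measure_id", "measures"),
            label=_require(raw, "label", "measures"),
            domain=_require(raw, "domain", "measures"),
            perspective=_require(raw, "perspective", "measures"),
            structure=_require(raw, "structure", "measures"),
            unit=_require(raw, "unit", "measures"),
            costable=bool(_require(raw, "costable", "measures")),
        )
        if "count_range" in raw:
            kwargs["count_range"] = tuple(float(v) for v in raw["count_range"])
        if "duration_range" in raw:
            kwargs["duration_range"] = tuple(float(v) for v in raw["duration_range"])
        measures.append(MeasureDefinition(**kwargs))

    studies = []
    for raw in doc.get("studies") or []:
        studies.append(
            StudyConfig(
                study_id=_require(raw, "study_id", "studies"),
                recall_days=dict(_require(raw, "recall_days", "studies")),
                n_participants=int(_require(raw, "n_participants", "studies")),
                max_recorded_events=int(raw.get("max_recorded_events", 5)),
            )
        )

    mcfs = []
    for raw in doc.get("mcfs") or []:
        mcfs.append(
            McfEntry(
                measure_id=_require(raw, "measure_id", "mcfs"),
                unit_cost=float(_require(raw, "unit_cost", "mcfs")),
                price_year=int(_require(raw, "price_year", "mcfs")),
                source=str(_require(raw, "source", "mcfs")),
                code=str(raw["code"]) if raw.get("code") is not None else None,
            )
        )

    return Catalog(measures, studies, mcfs)
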