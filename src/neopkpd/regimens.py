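"""Dosing regimens: formulary rules resolved into explicit dose-event schedules.

A regimen is a list of mutually exclusive :class:`RegimenRule` strata over
(birth weight, GA, PNA). Resolving a rule for a subject yields a
:class:`DoseSchedule`: intermittent regimens place 5-min infusions at
0, tau, 2*tau, ... within the analysis window; continuous regimens place a
5-min loading infusion at t=0 plus a constant-rate infusion delivering the
total daily dose per 24 h for the whole window.

Benzylpenicillin doses written in international units are converted at a
configurable 0.6 ug/IU (1,000,000 IU = 600 mg benzylpenicillin sodium).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, model_validator

#: Default benzylpenicillin sodium mass equivalent, mg per IU.
MG_PER_IU = 0.0006

#: All IV pushes are modelled as 5-minute infusions.
BOLUS_DURATION_H = 5.0 / 60.0

DEFAULT_WINDOW_H = 48.0


def iu_to_mg(iu: float, mg_per_iu: float = MG_PER_IU) -> float:
    """Convert an IU benzylpenicillin amount to mg (default 0.6 ug/IU)."""
    if iu < 0:
        raise ValueError(f"IU amount must be >= 0, got {iu}")
    return iu * mg_per_iu


@dataclass(frozen=True)
class DoseEvent:
    """One constant-rate infusion: ``amount`` mg over ``duration`` h from ``start_time``."""

    start_time: float  # h since birth
    amount: float  # mg
    duration: float  # h

    def __post_init__(self) -> None:
        if self.start_time < 0:
            raise ValueError("dose start_time must be >= 0")
        if self.amount <= 0:
            raise ValueError("dose amount must be > 0")
        if self.duration <= 0:
            raise ValueError("infusion duration must be > 0")

    @property
    def rate(self) -> float:
        return self.amount / self.duration


@dataclass
class DoseSchedule:
    """Ordered dose events for one subject over the analysis window."""

    subject_id: str
    events: list[DoseEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.start_time)

    @property
    def total_amount(self) -> float:
        return sum(e.amount for e in self.events)

    def scaled(self, factor: float) -> "DoseSchedule":
        """Schedule with every dose amount multiplied by ``factor``."""
        return DoseSchedule(
            self.subject_id,
            [DoseEvent(e.start_time, e.amount * factor, e.duration) for e in self.events],
        )


class RegimenRule(BaseModel):
    """One stratum of a formulary regimen.

    Stratifier bounds are half-open intervals ``min <= x < max``; ``None``
    means unbounded. ``dose_per_kg`` is mg/kg for ``unit='mg'`` or IU/kg for
    ``unit='iu'``. For ``mode='continuous'``, ``dose_per_kg`` is the total
    DAILY dose per kg and ``loading_fraction`` the fraction of it given as a
    5-min loading infusion at t=0.
    """

    drug: str
    dose_per_kg: float = Field(gt=0)
    unit: Literal["mg", "iu"] = "mg"
    interval_h: Optional[float] = None
    infusion_duration_h: float = BOLUS_DURATION_H
    mode: Literal["intermittent", "continuous"] = "intermittent"
    loading_fraction: float = Field(default=0.0, ge=0.0, lt=1.0)
    bw_min_kg: Optional[float] = None
    bw_max_kg: Optional[float] = None
    ga_min_weeks: Optional[float] = None
    ga_max_weeks: Optional[float] = None
    pna_min_days: Optional[float] = None
    pna_max_days: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "RegimenRule":
        if self.mode == "intermittent":
            if self.interval_h is None or self.interval_h <= 0:
                raise ValueError("intermittent rule needs a positive interval_h")
        if self.infusion_duration_h <= 0:
            raise ValueError("infusion_duration_h must be > 0")
        return self

    def matches(self, birth_weight: float, ga_weeks: float, pna_days: float = 0.0) -> bool:
        for value, lo, hi in (
            (birth_weight, self.bw_min_kg, self.bw_max_kg),
            (ga_weeks, self.ga_min_weeks, self.ga_max_weeks),
            (pna_days, self.pna_min_days, self.pna_max_days),
        ):
            if lo is not None and value < lo:
                return False
            if hi is not None and value >= hi:
                return False
        return True

    def dose_mg(self, birth_weight: float) -> float:
        """Per-administration (or daily, if continuous) dose in mg."""
        amount = self.dose_per_kg * birth_weight
        return iu_to_mg(amount) if self.unit == "iu" else amount


def resolve_regimen(
    subject,
    rules: list[RegimenRule],
    window_h: float = DEFAULT_WINDOW_H,
    pna_days: float = 0.0,
) -> DoseSchedule:
    """Resolve a regimen into a dose schedule for one subject.

    Exactly one rule must match the subject's covariates; treatment starts
    at birth (first administration at t=0).
    """
    matching = [r for r in rules if r.matches(subject.birth_weight, subject.ga_weeks, pna_days)]
    if len(matching) != 1:
        raise ValueError(
            f"subject {subject.subject_id} (BW {subject.birth_weight:.2f} kg, "
            f"GA {subject.ga_weeks:.1f} wk): {len(matching)} regimen rules match, expected 1"
        )
    rule = matching[0]
    sid = str(subject.subject_id)

    if rule.mode == "intermittent":
        dose = rule.dose_mg(subject.birth_weight)
        events = [
            DoseEvent(t, dose, rule.infusion_duration_h)
            for t in _dose_times(rule.interval_h, window_h)
        ]
        return DoseSchedule(sid, events)

    daily = rule.dose_mg(subject.birth_weight)
    events = []
    if rule.loading_fraction > 0:
        events.append(DoseEvent(0.0, rule.loading_fraction * daily, rule.infusion_duration_h))
    events.append(DoseEvent(0.0, daily * window_h / 24.0, window_h))
    return DoseSchedule(sid, events)


def _dose_times(interval_h: float, window_h: float) -> list[float]:
    times, t = [], 0.0
    while t < window_h - 1e-9:
        times.append(t)
        t += interval_h
    return times


#: Optimized GA-banded intermittent benzylpenicillin regimen: 30,000 IU/kg
#: q12h below GA 28 weeks, q8h from 28 to <36 weeks, q6h from 36 weeks up
#: (GA exactly 36 is assigned to the more mature, more frequent stratum).
GA_BANDED_BENZYLPENICILLIN: list[RegimenRule] = [
    RegimenRule(drug="benzylpenicillin", dose_per_kg=30_000, unit="iu", interval_h=12, ga_max_weeks=28),
    RegimenRule(drug="benzylpenicillin", dose_per_kg=30_000, unit="iu", interval_h=8, ga_min_weeks=28, ga_max_weeks=36),
    RegimenRule(drug="benzylpenicillin", dose_per_kg=30_000, unit="iu", interval_h=6, ga_min_weeks=36),
]


def alternative_ga_regimen(subject, window_h: float = DEFAULT_WINDOW_H) -> DoseSchedule:
    """Resolve the optimized GA-banded benzylpenicillin regimen for a subject."""
    if not 24.0 <= subject.ga_weeks <= 42.0:
        raise ValueError(f"GA {subject.ga_weeks} weeks outside the supported 24-42 range")
    return resolve_regimen(subject, GA_BANDED_BENZYLPENICILLIN, window_h)


_DATA_DIR = Path(__file__).parent / "data"
DEFAULT_CATALOG = _DATA_DIR / "regimens.yaml"


def load_regimen_catalog(path: str | Path = DEFAULT_CATALOG) -> dict[str, list[RegimenRule]]:
    """Load a regimen catalog: ``{'<name>/<drug>': [RegimenRule, ...]}``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    catalog: dict[str, list[RegimenRule]] = {}
    for entry in raw["regimens"]:
        key = f"{entry['name']}/{entry['drug']}"
        catalog[key] = [
            RegimenRule.model_validate({"drug": entry["drug"], **rule}) for rule in entry["rules"]
        ]
    return catalog


def save_regimen_catalog(catalog: dict[str, list[RegimenRule]], path: str | Path) -> None:
    """Write a catalog back to YAML; round-trips through ``load_regimen_catalog``."""
    regimens = []
    for key, rules in catalog.items():
        name, drug = key.split("/", 1)
        regimens.append(
            {
                "name": name,
                "drug": drug,
                "rules": [
                    {k: v for k, v in r.model_dump().items() if k != "drug" and v is not None}
                    for r in rules
                ],
            }
        )
    with open(path, "w") as fh:
        yaml.safe_dump({"regimens": regimens}, fh, sort_keys=False)
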