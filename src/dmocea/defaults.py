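"""Base-case input values.

Unit costs are from the 2019 Kuopio University Hospital price catalogue;
adverse-event incidences per cycle and the two utility sets are the
published base-case inputs of the underlying evaluation.  Everything here
is ordinary data — a scenario config can override any of it.
"""
from __future__ import annotations

from .schedules import (
    AdverseEventItem,
    FollowUpItem,
    FollowUpSchedule,
    RehabComponent,
    RehabilitationSchedule,
    TreatmentStrategy,
    UtilitySet,
)

DEXAMETHASONE = "dexamethasone"
TRIAMCINOLONE = "triamcinolone"

#: incidences per cycle; (name, unit cost EUR, dex incidence, ta incidence, once_only)
_ADVERSE_EVENTS = (
    ("iop_medication", 12.55 + 65.00, 0.0890, 0.1228, False),
    ("laser", 82.00, 0.0049, 0.0065, True),
    ("vitrectomy", 1195.00, 0.0047, 0.0129, True),
    ("cataract_surgery", 1373.00, 0.0577, 0.1264, True),
    ("endophthalmitis", 3101.00, 0.0025, 0.0020, False),
    ("retinal_detachment", 2706.00, 0.0004, 0.0003, False),
)


def _events(col: int) -> tuple[AdverseEventItem, ...]:
    return tuple(
        AdverseEventItem(name=name, unit_cost=cost,
                         incidence_per_cycle=(dex, ta)[col], once_only=once)
        for name, cost, dex, ta, once in _ADVERSE_EVENTS
    )


def dexamethasone_strategy() -> TreatmentStrategy:
    """0.7 mg implant, 1075 EUR, re-dosed every 5 months (2.4 doses/year)."""
    return TreatmentStrategy(
        id=DEXAMETHASONE,
        drug_unit_cost=1075.00,
        administration_unit_cost=90.00,   # medical visit at administration
        cycle_length_months=5.0,
        adverse_events=_events(0),
    )


def triamcinolone_strategy() -> TreatmentStrategy:
    """40 mg/ml injection, 207 EUR, re-dosed every 4 months (3 doses/year)."""
    return TreatmentStrategy(
        id=TRIAMCINOLONE,
        drug_unit_cost=207.00,
        administration_unit_cost=76.00,   # nurse visit at administration
        cycle_length_months=4.0,
        adverse_events=_events(1),
    )


def default_followup() -> FollowUpSchedule:
    return FollowUpSchedule(items=(
        FollowUpItem(name="oct_and_medical_visit", unit_cost=50.00 + 65.00,
                     utilization_per_year=6),
        FollowUpItem(name="iop_measurement", unit_cost=76.00,
                     utilization_per_year=13),
        FollowUpItem(name="fluorescein_angiography", unit_cost=77.00,
                     utilization_per_year=1),
    ))


def default_rehab() -> RehabilitationSchedule:
    return RehabilitationSchedule(components=(
        RehabComponent(name="occupational_rehabilitation", annual_cost=2496.00),
        RehabComponent(name="discretionary_rehabilitation", annual_cost=2176.00),
        RehabComponent(name="medical_rehabilitation", annual_cost=2648.00),
    ))


#: base-case utilities (Brown et al., AMD-derived, applied to DMO)
BASE_UTILITIES = (0.97, 0.89, 0.81, 0.55, 0.40)
#: alternative utilities (Sharma et al., eye disease in general)
SHARMA_UTILITIES = (0.93, 0.85, 0.66, 0.58, 0.53)


def utility_set(name: str = "base") -> UtilitySet:
    """Return a named utility set: ``base`` or ``sharma``."""
    try:
        values = {"base": BASE_UTILITIES, "sharma": SHARMA_UTILITIES}[name]
    except KeyError:
        raise ValueError(f"unknown utility set {name!r}; use 'base' or 'sharma'")
    return UtilitySet(name=name,
                      utility_by_state=dict(enumerate(values, start=1)))
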