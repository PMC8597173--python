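"""Treatment strategies, cost schedules and utility sets.

These are the configuration-facing value objects: everything here is a
plain pydantic model that round-trips through YAML/JSON.  Monetary values
are EUR (2019 Kuopio University Hospital price catalogue); utilisation
rates are per year; adverse-event incidences are probabilities per model
cycle.
"""
from __future__ import annotations

from collections.abc import Mapping, Sequence
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .states import N_STATES

OnceOnlyMode = Literal["saturating", "lump_sum"]


class AdverseEventItem(BaseModel):
    """One treatment-caused adverse event and the unit cost of treating it.

    ``once_only`` events (cataract surgery, IOP laser, vitrectomy) are
    charged at most once per patient over the whole follow-up; recurring
    events (IOP medication, endophthalmitis, retinal detachment) can be
    charged every cycle.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    unit_cost: float = Field(ge=0)
    incidence_per_cycle: float = Field(ge=0, le=1)
    once_only: bool = False


class TreatmentStrategy(BaseModel):
    """A drug, its dosing interval and its adverse-event profile.

    The cycle length equals the re-dosing interval, so doses per year are
    ``12 / cycle_length_months`` (2.4 for the 5-month dexamethasone
    implant, 3 for the 4-month triamcinolone injection).
    """

    model_config = ConfigDict(frozen=True)

    id: str
    drug_unit_cost: float = Field(ge=0)
    administration_unit_cost: float = Field(ge=0)
    cycle_length_months: float = Field(gt=0)
    adverse_events: tuple[AdverseEventItem, ...] = ()

    @property
    def doses_per_year(self) -> float:
        return 12.0 / self.cycle_length_months


class FollowUpItem(BaseModel):
    model_config = ConfigDict(frozen=True)

    name: str
    unit_cost: float = Field(ge=0)
    utilization_per_year: float = Field(ge=0)

    @property
    def cost_per_year(self) -> float:
        return self.unit_cost * self.utilization_per_year


class FollowUpSchedule(BaseModel):
    """Monitoring visits (OCT, IOP measurement, angiography) per year."""

    model_config = ConfigDict(frozen=True)

    items: tuple[FollowUpItem, ...] = ()

    @property
    def annual_cost(self) -> float:
        return float(sum(i.cost_per_year for i in self.items))


class RehabComponent(BaseModel):
    model_config = ConfigDict(frozen=True)

    name: str
    annual_cost: float = Field(ge=0)


class RehabilitationSchedule(BaseModel):
    """Annual rehabilitation costs for visually impaired patients."""

    model_config = ConfigDict(frozen=True)

    components: tuple[RehabComponent, ...] = ()
    applies_to_states: frozenset[int] = frozenset({4, 5})

    @field_validator("applies_to_states")
    @classmethod
    def _states_in_range(cls, v: frozenset[int]) -> frozenset[int]:
        if not all(1 <= s <= N_STATES for s in v):
            raise ValueError("rehabilitation state indices must be in 1..5")
        return v

    @property
    def annual_cost(self) -> float:
        return float(sum(c.annual_cost for c in self.components))

    def state_mask(self) -> np.ndarray:
        return np.array([(i + 1) in self.applies_to_states
                         for i in range(N_STATES)])


class UtilitySet(BaseModel):
    """Health-state utilities (QALY weights), one value per state."""

    model_config = ConfigDict(frozen=True)

    name: str
    utility_by_state: Mapping[int, float]

    @field_validator("utility_by_state")
    @classmethod
    def _complete_and_bounded(cls, v: Mapping[int, float]) -> Mapping[int, float]:
        if sorted(v) != list(range(1, N_STATES + 1)):
            raise ValueError("utilities must be given for states 1..5 exactly")
        if not all(0.0 <= u <= 1.0 for u in v.values()):
            raise ValueError("utilities must lie in [0, 1]")
        return dict(v)

    def as_array(self) -> np.ndarray:
        return np.array([self.utility_by_state[i]
                         for i in range(1, N_STATES + 1)], dtype=float)


def step_once_only_ledger(
    occupancy: np.ndarray,
    events: Sequence[AdverseEventItem],
    ledger: Mapping[str, float],
    cycle_fraction: float = 1.0,
    *,
    treated_mask: np.ndarray,
    cycle_index: int = 0,
    mode: OnceOnlyMode = "saturating",
) -> tuple[dict[str, float], dict[str, float]]:
    """Advance the once-only adverse-event ledger by one cycle.

    The ledger maps each once-only event name to the fraction of the
    cohort that has already incurred it.  In ``saturating`` mode the
    not-yet-affected treated fraction incurs the event at the per-cycle
    incidence each cycle; in ``lump_sum`` mode the whole per-cycle
    incidence is charged once, in the first cycle.

    Returns ``(newly_affected_fraction, updated_ledger)``; recurring
    events are ignored here (they never enter the ledger).
    """
    total = float(occupancy.sum())
    treated_frac = float(occupancy[treated_mask].sum()) / total if total > 0 else 0.0
    newly: dict[str, float] = {}
    updated = dict(ledger)
    for ev in events:
        if not ev.once_only:
            continue
        already = float(updated.get(ev.name, 0.0))
        if mode == "lump_sum":
            frac = ev.incidence_per_cycle * treated_frac * cycle_fraction \
                if cycle_index == 0 else 0.0
        else:
            eligible = max(treated_frac - already, 0.0)
            frac = ev.incidence_per_cycle * eligible * cycle_fraction
        newly[ev.name] = frac
        updated[ev.name] = min(already + frac, 1.0)
    return newly, updated
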