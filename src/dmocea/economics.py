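"""Cost and QALY accrual over a cohort trace, with discounting.

Accrual rules, per cycle, using occupancy at the cycle start (no
half-cycle correction):

* drug + administration costs per treated eye and dose — one eye in
  state 1, two in states 2-4 (both eyes treated once both have DMO),
  none in state 5 by default;
* follow-up (OCT/IOP/angiography) pro rata temporis for states 1-4;
* rehabilitation pro rata temporis for states 4-5;
* adverse events on the drug-treated population: recurring events every
  cycle, once-only events (cataract surgery, laser, vitrectomy) only for
  the cohort fraction not yet affected;
* QALYs as occupancy-weighted utilities times cycle duration.

Costs and QALYs of a cycle are discounted with ``(1 + r)^(-t)`` at the
cycle's start time; a truncated final cycle accrues a pro-rata fraction.
"""
from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError, InvalidParameterError
from .markov import CohortTrace
from .schedules import (
    FollowUpSchedule,
    OnceOnlyMode,
    RehabilitationSchedule,
    TreatmentStrategy,
    UtilitySet,
    step_once_only_ledger,
)
from .states import N_STATES, treated_eyes_vector


def discount_factor(time_years: float, annual_rate: float) -> float:
    """``(1 + r)^(-t)`` — continuous in time, so fractional years work."""
    if time_years < 0:
        raise InvalidParameterError("time_years cannot be negative")
    if annual_rate < 0:
        raise InvalidParameterError("annual_rate cannot be negative")
    return float((1.0 + annual_rate) ** (-time_years))


def cycle_drug_cost(
    occupancy: np.ndarray,
    strategy: TreatmentStrategy,
    cycle_fraction: float = 1.0,
    *,
    treat_in_state5: bool = False,
) -> float:
    """Drug plus administration cost of one cycle.

    Each treated eye receives one dose: states 2-4 incur double drug
    costs because both eyes have DMO and both are treated.
    """
    doses = _dose_count(occupancy, cycle_fraction, treat_in_state5)
    return float(doses * (strategy.drug_unit_cost
                          + strategy.administration_unit_cost))


def _dose_count(occupancy: np.ndarray, cycle_fraction: float,
                treat_in_state5: bool) -> float:
    occ = _check_occupancy(occupancy)
    eyes = treated_eyes_vector(treat_in_state5)
    return float(occ @ eyes) * cycle_fraction


def _check_occupancy(occupancy) -> np.ndarray:
    occ = np.asarray(occupancy, dtype=float)
    if occ.shape != (N_STATES,):
        raise InvalidInputError(
            f"occupancy must be a length-{N_STATES} vector, got {occ.shape}")
    if np.any(occ < 0):
        raise InvalidInputError("occupancy counts cannot be negative")
    return occ


def cycle_adverse_event_cost(
    occupancy: np.ndarray,
    strategy: TreatmentStrategy,
    ledger: Mapping[str, float],
    cycle_fraction: float = 1.0,
    *,
    cycle_index: int = 0,
    mode: OnceOnlyMode = "saturating",
    treat_in_state5: bool = False,
) -> tuple[float, dict[str, float]]:
    """Adverse-event treatment cost of one cycle, plus the updated ledger.

    Events strike the drug-treated population (treatment-caused).
    Recurring events contribute ``treated * incidence * unit_cost`` every
    cycle; once-only events only for the cohort fraction that has not yet
    incurred them (the ledger), so their contribution saturates.
    """
    occ = _check_occupancy(occupancy)
    if any(not 0.0 <= v <= 1.0 for v in ledger.values()):
        raise InvalidInputError("once-only ledger values must lie in [0, 1]")
    total = float(occ.sum())
    treated_mask = treated_eyes_vector(treat_in_state5) >= 1
    treated = float(occ[treated_mask].sum())
    cost = 0.0
    for ev in strategy.adverse_events:
        if not ev.once_only:
            cost += treated * ev.incidence_per_cycle * ev.unit_cost \
                * cycle_fraction
    newly, updated = step_once_only_ledger(
        occ, strategy.adverse_events, ledger, cycle_fraction,
        treated_mask=treated_mask, cycle_index=cycle_index, mode=mode)
    for ev in strategy.adverse_events:
        if ev.once_only:
            cost += newly.get(ev.name, 0.0) * total * ev.unit_cost
    return cost, updated


def cycle_followup_cost(
    occupancy: np.ndarray,
    followup: FollowUpSchedule,
    cycle_length_months: float,
    cycle_fraction: float = 1.0,
    *,
    followup_in_state5: bool = False,
) -> float:
    """Monitoring cost of one cycle, pro rata from annual utilisation."""
    occ = _check_occupancy(occupancy)
    monitored = float(occ.sum()) if followup_in_state5 \
        else float(occ[:4].sum())
    return monitored * followup.annual_cost \
        * (cycle_length_months / 12.0) * cycle_fraction


def cycle_rehab_cost(
    occupancy: np.ndarray,
    rehab: RehabilitationSchedule,
    cycle_length_months: float,
    cycle_fraction: float = 1.0,
) -> float:
    """Rehabilitation cost of one cycle for visually impaired states."""
    occ = _check_occupancy(occupancy)
    impaired = float(occ[rehab.state_mask()].sum())
    return impaired * rehab.annual_cost \
        * (cycle_length_months / 12.0) * cycle_fraction


def cycle_followup_and_rehab_cost(
    occupancy: np.ndarray,
    followup: FollowUpSchedule,
    rehab: RehabilitationSchedule,
    cycle_length_months: float,
    cycle_fraction: float = 1.0,
    *,
    followup_in_state5: bool = False,
) -> float:
    """Combined follow-up (states 1-4 by default) and rehab (states 4-5)."""
    return (cycle_followup_cost(occupancy, followup, cycle_length_months,
                                cycle_fraction,
                                followup_in_state5=followup_in_state5)
            + cycle_rehab_cost(occupancy, rehab, cycle_length_months,
                               cycle_fraction))


_COMPONENTS = ("drug", "administration", "followup", "adverse_events",
               "rehabilitation")


@dataclass(frozen=True)
class EconomicOutcome:
    """Expected costs and QALYs of one strategy over one horizon."""

    strategy_id: str
    horizon_years: float
    discount_rate: float
    cohort_size: float
    cost: float
    qalys: float
    cost_undiscounted: float
    qalys_undiscounted: float
    components: Mapping[str, float] = field(default_factory=dict)
    per_cycle_ledger: pd.DataFrame | None = None


def accrue_outcomes(
    trace: CohortTrace,
    strategy: TreatmentStrategy,
    followup: FollowUpSchedule,
    rehab: RehabilitationSchedule,
    utilities: UtilitySet,
    annual_rate: float = 0.0,
    *,
    treat_in_state5: bool = False,
    followup_in_state5: bool = False,
    keep_ledger: bool = True,
) -> EconomicOutcome:
    """Accrue all cost components and QALYs over a trace.

    Per cycle, undiscounted components are computed from occupancy at the
    cycle start and multiplied by the discount factor at that start time;
    totals are sums over cycles.  At rate 0 the discounted and
    undiscounted totals coincide exactly.
    """
    if trace.strategy_id != strategy.id:
        raise InvalidInputError(
            f"trace is for {trace.strategy_id!r}, strategy is {strategy.id!r}")
    if abs(trace.grid.cycle_length_months - strategy.cycle_length_months) > 1e-9:
        raise InvalidInputError(
            "trace cycle grid does not match the strategy's cycle length")
    if annual_rate < 0:
        raise InvalidParameterError("annual_rate cannot be negative")

    grid = trace.grid
    n = grid.n_cycles
    util = utilities.as_array()
    fractions = grid.fractions
    records: list[dict[str, float]] = []
    ledger = {ev.name: 0.0 for ev in strategy.adverse_events if ev.once_only}
    totals_undisc = dict.fromkeys((*_COMPONENTS, "qalys"), 0.0)
    totals_disc = dict.fromkeys((*_COMPONENTS, "qalys"), 0.0)

    for i in range(n):
        occ = trace.occupancy[i]
        frac = fractions[i]
        start_years = grid.boundaries[i] / 12.0
        df = discount_factor(start_years, annual_rate)
        doses = _dose_count(occ, frac, treat_in_state5)
        parts = {
            "drug": doses * strategy.drug_unit_cost,
            "administration": doses * strategy.administration_unit_cost,
            "followup": cycle_followup_cost(
                occ, followup, grid.cycle_length_months, frac,
                followup_in_state5=followup_in_state5),
            "rehabilitation": cycle_rehab_cost(
                occ, rehab, grid.cycle_length_months, frac),
        }
        ae_cost, ledger = cycle_adverse_event_cost(
            occ, strategy, ledger, frac, cycle_index=i,
            mode=trace.once_only_mode, treat_in_state5=treat_in_state5)
        parts["adverse_events"] = ae_cost
        qalys = float(occ @ util) * (grid.cycle_length_months / 12.0) * frac
        for key, value in (*parts.items(), ("qalys", qalys)):
            totals_undisc[key] += value
            totals_disc[key] += value * df
        if keep_ledger:
            records.append({
                "cycle": i,
                "time_months": grid.boundaries[i],
                "time_years": start_years,
                "cycle_fraction": frac,
                "discount_factor": df,
                **{f"{k}_cost": v for k, v in parts.items()},
                "total_cost": sum(parts.values()),
                "qalys": qalys,
            })

    cost_undisc = sum(totals_undisc[c] for c in _COMPONENTS)
    cost_disc = sum(totals_disc[c] for c in _COMPONENTS)
    return EconomicOutcome(
        strategy_id=strategy.id,
        horizon_years=grid.horizon_months / 12.0,
        discount_rate=annual_rate,
        cohort_size=trace.cohort_size,
        cost=cost_disc,
        qalys=totals_disc["qalys"],
        cost_undiscounted=cost_undisc,
        qalys_undiscounted=totals_undisc["qalys"],
        components={c: totals_disc[c] for c in _COMPONENTS},
        per_cycle_ledger=pd.DataFrame(records) if keep_ledger else None,
    )


def annual_cost_summary(
    strategy: TreatmentStrategy,
    followup: FollowUpSchedule | None = None,
) -> pd.DataFrame:
    """Per-year cost breakdown of a strategy (unit cost x utilisation).

    Reproduces the medication / administration / follow-up arithmetic of
    the published cost table: e.g. 2.4 dexamethasone doses per year at
    1075 EUR give 2580 EUR per year.
    """
    rows = [
        {"item": "medication", "unit_cost": strategy.drug_unit_cost,
         "utilization_per_year": strategy.doses_per_year,
         "cost_per_year": strategy.drug_unit_cost * strategy.doses_per_year},
        {"item": "administration",
         "unit_cost": strategy.administration_unit_cost,
         "utilization_per_year": strategy.doses_per_year,
         "cost_per_year": strategy.administration_unit_cost
            * strategy.doses_per_year},
    ]
    if followup is not None:
        for it in followup.items:
            rows.append({"item": it.name, "unit_cost": it.unit_cost,
                         "utilization_per_year": it.utilization_per_year,
                         "cost_per_year": it.cost_per_year})
    df = pd.DataFrame(rows)
    df.insert(0, "strategy", strategy.id)
    return df
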