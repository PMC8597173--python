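"""Incremental cost-effectiveness analysis and sensitivity scenarios.

The final output of the model is the incremental cost-effectiveness
ratio (ICER): the difference in expected costs between two strategies
divided by the difference in expected QALYs.  When one strategy costs
less *and* yields more QALYs it dominates and the ICER stops being a
meaningful price; dominance is therefore flagged explicitly and the
signed ratio is only reported as a secondary quantity.
"""
from __future__ import annotations

import enum
from collections.abc import Callable, Sequence
from dataclasses import dataclass

import pandas as pd

from . import defaults
from .config import ScenarioConfig, resolve_matrices
from .economics import EconomicOutcome, accrue_outcomes
from .errors import InvalidComparisonError, InvalidParameterError
from .markov import StrategyMatrices, run_trace

_QALY_TOL = 1e-12


class Dominance(str, enum.Enum):
    NONE = "none"
    #: comparator dominates: the reference costs more and yields less
    COMPARATOR_DOMINANT = "comparator_dominant"
    #: reference dominates: it costs less and yields more
    REFERENCE_DOMINANT = "reference_dominant"
    EXTENDED = "extended"


@dataclass(frozen=True)
class CEAResult:
    """Incremental comparison of a reference against a comparator.

    Deltas are reference minus comparator.  ``icer`` is only set when it
    is a meaningful willingness-to-pay price: positive QALY gain and no
    dominance.  ``signed_icer`` is the raw quotient whenever the QALY
    difference is non-degenerate (a negative value under comparator
    dominance mirrors how such results are sometimes printed).
    """

    reference_strategy: str
    comparator_strategy: str
    delta_cost: float
    delta_qalys: float
    icer: float | None
    signed_icer: float | None
    dominance: Dominance
    discount_rate: float
    horizon_years: float


@dataclass(frozen=True)
class WTPDecision:
    """Accept/reject the reference strategy at a willingness-to-pay."""

    threshold: float
    accept_reference: bool


def compute_icer(outcome_ref: EconomicOutcome,
                 outcome_cmp: EconomicOutcome) -> CEAResult:
    """Incremental costs, QALYs, ICER and dominance of two outcomes."""
    if abs(outcome_ref.horizon_years - outcome_cmp.horizon_years) > 1e-9 \
            or outcome_ref.discount_rate != outcome_cmp.discount_rate:
        raise InvalidComparisonError(
            "outcomes stem from different horizons or discount rates: "
            f"({outcome_ref.horizon_years} y, {outcome_ref.discount_rate}) vs "
            f"({outcome_cmp.horizon_years} y, {outcome_cmp.discount_rate})")
    delta_cost = outcome_ref.cost - outcome_cmp.cost
    delta_qalys = outcome_ref.qalys - outcome_cmp.qalys
    if delta_cost > 0 and delta_qalys < 0:
        dominance = Dominance.COMPARATOR_DOMINANT
    elif delta_cost < 0 and delta_qalys > 0:
        dominance = Dominance.REFERENCE_DOMINANT
    else:
        dominance = Dominance.NONE
    signed = delta_cost / delta_qalys if abs(delta_qalys) >= _QALY_TOL else None
    icer = signed if (signed is not None and dominance is Dominance.NONE
                      and delta_qalys > 0) else None
    return CEAResult(
        reference_strategy=outcome_ref.strategy_id,
        comparator_strategy=outcome_cmp.strategy_id,
        delta_cost=delta_cost, delta_qalys=delta_qalys,
        icer=icer, signed_icer=signed, dominance=dominance,
        discount_rate=outcome_ref.discount_rate,
        horizon_years=outcome_ref.horizon_years)


def decide(result: CEAResult, threshold: float) -> WTPDecision:
    """Accept the reference iff it dominates or its ICER is affordable."""
    if threshold < 0:
        raise InvalidParameterError("WTP threshold cannot be negative")
    accept = result.dominance is Dominance.REFERENCE_DOMINANT \
        or (result.icer is not None and result.delta_qalys > 0
            and result.icer <= threshold)
    return WTPDecision(threshold=threshold, accept_reference=accept)


def run_scenario(
    config: ScenarioConfig,
    horizon_years: float,
    discount_rate: float,
    bank: dict[str, StrategyMatrices] | None = None,
) -> tuple[dict[str, EconomicOutcome], CEAResult]:
    """Run both strategies through one (horizon, rate) cell.

    Deterministic given the config.  ``bank`` lets callers reuse
    resolved matrices across cells.
    """
    if bank is None:
        bank = resolve_matrices(config)
    sw = config.switches
    outcomes: dict[str, EconomicOutcome] = {}
    for strategy in config.strategies:
        trace = run_trace(
            strategy, bank[strategy.id], horizon_years, config.cohort_size,
            treat_in_state5=sw.treat_in_state5,
            once_only_mode=sw.once_only_mode)
        outcomes[strategy.id] = accrue_outcomes(
            trace, strategy, config.followup, config.rehab,
            config.utilities, discount_rate,
            treat_in_state5=sw.treat_in_state5,
            followup_in_state5=sw.followup_in_state5)
    result = compute_icer(outcomes[config.reference_id],
                          outcomes[config.comparator_id])
    return outcomes, result


def run_grid(
    config: ScenarioConfig,
) -> tuple[pd.DataFrame, dict[tuple[float, float], CEAResult]]:
    """All configured (horizon, rate) cells as a results-table grid.

    The table has, per cell, one row per strategy (expected costs and
    QALYs) and a difference row carrying the ICER or the dominance flag.
    """
    bank = resolve_matrices(config)
    rows: list[dict] = []
    results: dict[tuple[float, float], CEAResult] = {}
    for horizon in config.horizons_years:
        for rate in config.discount_rates:
            outcomes, result = run_scenario(config, horizon, rate, bank)
            results[(horizon, rate)] = result
            for sid in (config.reference_id, config.comparator_id):
                o = outcomes[sid]
                rows.append({
                    "horizon_years": horizon, "discount_rate": rate,
                    "row": sid, "expected_cost": o.cost,
                    "expected_qalys": o.qalys,
                    "icer": None, "dominance": None,
                })
            rows.append({
                "horizon_years": horizon, "discount_rate": rate,
                "row": "difference", "expected_cost": result.delta_cost,
                "expected_qalys": result.delta_qalys,
                "icer": result.icer, "dominance": result.dominance.value,
            })
    return pd.DataFrame(rows), results


# ---------------------------------------------------------------------------
# deterministic sensitivity analysis


@dataclass(frozen=True)
class SensitivityScenario:
    """A named one-way modification of the scenario config."""

    name: str
    transform: Callable[[ScenarioConfig], ScenarioConfig]

    def apply(self, config: ScenarioConfig) -> ScenarioConfig:
        modified = self.transform(config.model_copy(deep=True))
        return modified


def _set_cycle_length(config: ScenarioConfig, strategy_id: str,
                      months: float) -> ScenarioConfig:
    strategies = tuple(
        s.model_copy(update={"cycle_length_months": months})
        if s.id == strategy_id else s
        for s in config.strategies)
    return config.model_copy(update={"strategies": strategies})


def _scale_drug_cost(config: ScenarioConfig, strategy_id: str,
                     factor: float) -> ScenarioConfig:
    strategies = tuple(
        s.model_copy(update={"drug_unit_cost": s.drug_unit_cost * factor})
        if s.id == strategy_id else s
        for s in config.strategies)
    return config.model_copy(update={"strategies": strategies})


def triamcinolone_3_month_cycle() -> SensitivityScenario:
    """Shorten the triamcinolone re-dosing interval from 4 to 3 months.

    With synthetic matrices the per-cycle probabilities are regenerated
    for the 3-month cycle (time-based progression rescales with cycle
    length, per-dose improvement does not); explicitly supplied matrices
    are reused unchanged on the shorter grid.
    """
    return SensitivityScenario(
        name="triamcinolone_cycle_3_months",
        transform=lambda c: _set_cycle_length(c, defaults.TRIAMCINOLONE, 3.0))


def dexamethasone_price_cut(factor: float = 0.8) -> SensitivityScenario:
    """Lower the dexamethasone implant unit price (default by 20%)."""
    return SensitivityScenario(
        name="dexamethasone_price_cut_20pct",
        transform=lambda c: _scale_drug_cost(c, defaults.DEXAMETHASONE,
                                             factor))


def alternative_utilities() -> SensitivityScenario:
    """Swap in the alternative (Sharma) health-state utility set."""
    return SensitivityScenario(
        name="alternative_utilities",
        transform=lambda c: c.model_copy(
            update={"utilities": defaults.utility_set("sharma")}))


def standard_scenarios() -> tuple[SensitivityScenario, ...]:
    """The three deterministic one-way analyses of the base evaluation."""
    return (triamcinolone_3_month_cycle(), dexamethasone_price_cut(),
            alternative_utilities())


def run_sensitivity(
    config: ScenarioConfig,
    scenarios: Sequence[SensitivityScenario] | None = None,
) -> pd.DataFrame:
    """One CEAResult row per scenario and (horizon, rate) cell.

    The base config is never mutated; each scenario runs on a deep copy.
    """
    if scenarios is None:
        scenarios = standard_scenarios()
    rows: list[dict] = []
    for scenario in scenarios:
        modified = scenario.apply(config)
        _, results = run_grid(modified)
        for (horizon, rate), r in results.items():
            rows.append({
                "scenario": scenario.name,
                "horizon_years": horizon, "discount_rate": rate,
                "delta_cost": r.delta_cost, "delta_qalys": r.delta_qalys,
                "icer": r.icer, "signed_icer": r.signed_icer,
                "dominance": r.dominance.value,
            })
    columns = ["scenario", "horizon_years", "discount_rate", "delta_cost",
               "delta_qalys", "icer", "signed_icer", "dominance"]
    return pd.DataFrame(rows, columns=columns)
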