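"""Cost/QALY accrual: unit rules, discounting, totals, annual summary."""
import numpy as np
import pytest

import dmocea as d
from dmocea import defaults
from dmocea.economics import cycle_followup_cost, cycle_rehab_cost

S1 = np.array([1.0, 0, 0, 0, 0])
S2 = np.array([0.0, 1, 0, 0, 0])
S5 = np.array([0.0, 0, 0, 0, 1])


# ----------------------------------------------------------------- discounting

def test_discount_factor_closed_form():
    assert d.discount_factor(17.3, 0.0) == 1.0
    assert d.discount_factor(1, 0.03) == pytest.approx(1 / 1.03, rel=1e-12)
    assert d.discount_factor(2, 0.03) == pytest.approx(1 / 1.03 ** 2,
                                                       rel=1e-12)
    assert d.discount_factor(0.5, 0.03) == pytest.approx(1.03 ** -0.5,
                                                         rel=1e-12)


def test_discount_factor_rejects_negative_arguments():
    with pytest.raises(d.InvalidParameterError):
        d.discount_factor(-1, 0.03)
    with pytest.raises(d.InvalidParameterError):
        d.discount_factor(1, -0.03)


# ------------------------------------------------------------------ drug cost

def test_drug_cost_doubles_in_bilateral_states(dex):
    assert d.cycle_drug_cost(S1, dex) == pytest.approx(1075 + 90)
    assert d.cycle_drug_cost(S2, dex) == pytest.approx(2 * (1075 + 90))
    assert d.cycle_drug_cost(S5 * 1000, dex) == 0.0
    assert d.cycle_drug_cost(S1, dex, 0.8) == pytest.approx(0.8 * 1165)


def test_state5_treatment_switch(ta):
    assert d.cycle_drug_cost(S5, ta) == 0.0
    assert d.cycle_drug_cost(S5, ta, treat_in_state5=True) == \
        pytest.approx(2 * (207 + 76))


# ------------------------------------------------------------- adverse events

def test_recurring_adverse_event_cost(ta):
    occ = np.array([1000.0, 0, 0, 0, 0])
    only_endo = ta.model_copy(update={"adverse_events": tuple(
        ev for ev in ta.adverse_events if ev.name == "endophthalmitis")})
    cost, ledger = d.cycle_adverse_event_cost(occ, only_endo, {})
    # 1000 treated x 0.20% x 3101 EUR
    assert cost == pytest.approx(1000 * 0.0020 * 3101.00)
    assert ledger == {}


def test_zero_incidence_means_zero_cost(dex):
    muted = dex.model_copy(update={"adverse_events": tuple(
        ev.model_copy(update={"incidence_per_cycle": 0.0})
        for ev in dex.adverse_events)})
    cost, ledger = d.cycle_adverse_event_cost(
        np.array([500.0, 300, 100, 50, 50]), muted,
        {"cataract_surgery": 0.2})
    assert cost == 0.0
    assert ledger["cataract_surgery"] == 0.2


def test_once_only_events_saturate(dex):
    occ = np.array([1000.0, 0, 0, 0, 0])
    full = {ev.name: 1.0 for ev in dex.adverse_events if ev.once_only}
    cost_full, _ = d.cycle_adverse_event_cost(occ, dex, full)
    recurring = sum(1000 * ev.incidence_per_cycle * ev.unit_cost
                    for ev in dex.adverse_events if not ev.once_only)
    assert cost_full == pytest.approx(recurring)
    # from an empty ledger the once-only events do contribute
    cost_empty, ledger = d.cycle_adverse_event_cost(occ, dex, {})
    once = sum(1000 * ev.incidence_per_cycle * ev.unit_cost
               for ev in dex.adverse_events if ev.once_only)
    assert cost_empty == pytest.approx(recurring + once)
    assert ledger["cataract_surgery"] == pytest.approx(0.0577)


def test_lump_sum_mode_charges_only_in_first_cycle(ta):
    occ = np.array([1000.0, 0, 0, 0, 0])
    cost0, ledger = d.cycle_adverse_event_cost(
        occ, ta, {}, cycle_index=0, mode="lump_sum")
    cost1, _ = d.cycle_adverse_event_cost(
        occ, ta, ledger, cycle_index=1, mode="lump_sum")
    recurring = sum(1000 * ev.incidence_per_cycle * ev.unit_cost
                    for ev in ta.adverse_events if not ev.once_only)
    once = sum(1000 * ev.incidence_per_cycle * ev.unit_cost
               for ev in ta.adverse_events if ev.once_only)
    assert cost0 == pytest.approx(recurring + once)
    assert cost1 == pytest.approx(recurring)


# --------------------------------------------------------- follow-up and rehab

def test_follow_up_costs_one_person_year():
    followup = defaults.default_followup()
    # 690 + 988 + 77 EUR per person-year, accrued over a 12-month cycle
    assert cycle_followup_cost(S1, followup, 12.0) == pytest.approx(1755.0)
    assert cycle_followup_cost(S1, followup, 4.0) == pytest.approx(1755 / 3)
    assert cycle_followup_cost(S5, followup, 12.0) == 0.0
    assert cycle_followup_cost(S5, followup, 12.0,
                               followup_in_state5=True) == \
        pytest.approx(1755.0)


def test_rehabilitation_costs_one_person_year():
    rehab = defaults.default_rehab()
    assert rehab.annual_cost == pytest.approx(7320.0)
    assert cycle_rehab_cost(S5, rehab, 12.0) == pytest.approx(7320.0)
    assert cycle_rehab_cost(np.array([0.0, 0, 0, 1, 0]), rehab, 12.0) == \
        pytest.approx(7320.0)
    assert cycle_rehab_cost(S1, rehab, 12.0) == 0.0


def test_empty_schedules_cost_nothing():
    assert d.cycle_followup_and_rehab_cost(
        S2 * 1000, d.FollowUpSchedule(), d.RehabilitationSchedule(),
        12.0) == 0.0


# --------------------------------------------------------------- full accrual

def _one_person(strategy, state, horizon_years=1.0):
    """A single person parked in one state for the whole horizon."""
    occ0 = np.zeros(5)
    occ0[state - 1] = 1.0
    grid = d.build_cycle_grid(strategy.cycle_length_months, horizon_years)
    return d.CohortTrace(
        strategy_id=strategy.id, grid=grid,
        occupancy=np.tile(occ0, (grid.n_cycles + 1, 1)),
        times_months=np.append(grid.boundaries, 12.0 * horizon_years),
        cohort_size=1.0)


def test_qaly_accrual_matches_state_utilities(dex):
    utilities = defaults.utility_set()
    for state, expected in ((1, 0.97), (5, 0.40)):
        trace = _one_person(dex, state)
        outcome = d.accrue_outcomes(
            trace, dex, defaults.default_followup(), defaults.default_rehab(),
            utilities, 0.0)
        assert outcome.qalys == pytest.approx(expected, rel=1e-12)


def test_zero_horizon_accrues_nothing(dex, bank):
    trace = d.run_trace(dex, bank[dex.id], 0.0)
    outcome = d.accrue_outcomes(
        trace, dex, defaults.default_followup(), defaults.default_rehab(),
        defaults.utility_set(), 0.03)
    assert outcome.cost == 0.0
    assert outcome.qalys == 0.0


def _outcome(cfg, strategy, bank, rate, cohort=1000.0):
    trace = d.run_trace(strategy, bank[strategy.id], 2.0, cohort)
    return d.accrue_outcomes(trace, strategy, cfg.followup, cfg.rehab,
                             cfg.utilities, rate)


def test_zero_rate_identity_and_discount_monotonicity(default_cfg, bank, dex):
    at0 = _outcome(default_cfg, dex, bank, 0.0)
    assert at0.cost == at0.cost_undiscounted
    assert at0.qalys == at0.qalys_undiscounted
    costs = [_outcome(default_cfg, dex, bank, r).cost
             for r in (0.0, 0.03, 0.08)]
    qalys = [_outcome(default_cfg, dex, bank, r).qalys
             for r in (0.0, 0.03, 0.08)]
    assert costs[0] > costs[1] > costs[2]
    assert qalys[0] > qalys[1] > qalys[2]


def test_cost_additivity_over_components(default_cfg, bank, ta):
    outcome = _outcome(default_cfg, ta, bank, 0.03)
    assert outcome.cost == pytest.approx(sum(outcome.components.values()),
                                         abs=1e-9)
    ledger = outcome.per_cycle_ledger
    parts = ledger[["drug_cost", "administration_cost", "followup_cost",
                    "adverse_events_cost", "rehabilitation_cost"]].sum(axis=1)
    assert np.allclose(parts, ledger["total_cost"], atol=1e-9)


def test_costs_and_qalys_are_linear_in_cohort_size(default_cfg, bank, dex):
    small = _outcome(default_cfg, dex, bank, 0.03, cohort=1000.0)
    large = _outcome(default_cfg, dex, bank, 0.03, cohort=2000.0)
    assert large.cost == pytest.approx(2 * small.cost, rel=1e-12)
    assert large.qalys == pytest.approx(2 * small.qalys, rel=1e-12)


# -------------------------------------------------------------- annual summary

def test_annual_cost_summary_reproduces_published_arithmetic(dex, ta):
    followup = defaults.default_followup()
    table = d.annual_cost_summary(dex, followup).set_index("item")
    assert table.loc["medication", "cost_per_year"] == pytest.approx(2580.00)
    assert table.loc["administration", "cost_per_year"] == \
        pytest.approx(216.00)
    assert table.loc["oct_and_medical_visit", "cost_per_year"] == \
        pytest.approx(690.00)
    assert table.loc["iop_measurement", "cost_per_year"] == \
        pytest.approx(988.00)
    assert table.loc["fluorescein_angiography", "cost_per_year"] == \
        pytest.approx(77.00)
    ta_table = d.annual_cost_summary(ta, followup).set_index("item")
    assert ta_table.loc["medication", "cost_per_year"] == \
        pytest.approx(621.00)
    assert ta_table.loc["administration", "cost_per_year"] == \
        pytest.approx(228.00)
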