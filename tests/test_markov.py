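"""Cohort engine: cycle grids, matrix selection, propagation, traces."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dmocea as d
from dmocea.markov import EARLY_LATE_BOUNDARY_MONTHS

from .conftest import brute_force_occupancy, identity_pair, make_matrix

ROW1 = np.array([
    [0.7, 0.2, 0.08, 0.02, 0.0],
    [0.0, 0.9, 0.08, 0.02, 0.0],
    [0.0, 0.1, 0.8, 0.08, 0.02],
    [0.0, 0.02, 0.1, 0.8, 0.08],
    [0.0, 0.0, 0.0, 0.0, 1.0],
])


# --------------------------------------------------------------- health states

def test_health_state_table():
    assert len(d.HEALTH_STATES) == 5
    assert [s.index for s in d.HEALTH_STATES] == [1, 2, 3, 4, 5]
    assert [s.va_band for s in d.HEALTH_STATES] == [
        (0.5, np.inf), (0.5, np.inf), (0.3, 0.5), (0.05, 0.3), (0.0, 0.05)]
    assert [s.rehab_eligible for s in d.HEALTH_STATES] == \
        [False, False, False, True, True]
    assert [s.bilateral_dmo for s in d.HEALTH_STATES] == \
        [False, True, True, True, True]
    assert [s.treated_eyes for s in d.HEALTH_STATES] == [1, 2, 2, 2, 0]


# ----------------------------------------------------------------- cycle grid

@pytest.mark.parametrize("cycle_months, horizon_years, n_cycles, fraction", [
    (4, 2, 6, 1.0),       # 24/4 is integer
    (5, 2, 5, 0.8),       # 24 = 4x5 + 4; remainder 4/5
    (5, 5, 12, 1.0),      # 60/5 is integer
    (3, 2, 8, 1.0),
    (12, 1, 1, 1.0),
])
def test_cycle_grid_partitions_horizon(cycle_months, horizon_years,
                                       n_cycles, fraction):
    grid = d.build_cycle_grid(cycle_months, horizon_years)
    assert grid.n_cycles == n_cycles
    assert grid.final_cycle_fraction == pytest.approx(fraction)
    assert grid.boundaries[0] == 0.0
    assert np.allclose(np.diff(grid.boundaries), cycle_months)
    assert grid.horizon_months == pytest.approx(12 * horizon_years)


def test_dexamethasone_two_year_grid_boundaries():
    grid = d.build_cycle_grid(5, 2)
    assert grid.boundaries.tolist() == [0, 5, 10, 15, 20]


@pytest.mark.parametrize("cycle, horizon", [(0, 2), (-1, 2), (5, 0), (5, -3)])
def test_cycle_grid_rejects_nonpositive_inputs(cycle, horizon):
    with pytest.raises(d.InvalidParameterError):
        d.build_cycle_grid(cycle, horizon)


# ------------------------------------------------------------ matrix selection

def test_matrix_selection_by_cycle_start():
    pair = d.StrategyMatrices(
        strategy_id="x",
        early=make_matrix("x", "early", ROW1),
        late=make_matrix("x", "late", np.eye(5)))
    assert d.select_matrix(pair, 0.0) is pair.early
    # 3rd dexamethasone cycle starts at month 10, still early
    assert d.select_matrix(pair, 10.0) is pair.early
    assert d.select_matrix(pair, EARLY_LATE_BOUNDARY_MONTHS) is pair.late
    assert d.select_matrix(pair, 40.0) is pair.late


def test_missing_period_matrix_is_a_configuration_error():
    early = make_matrix("x", "early", ROW1)
    with pytest.raises(d.ConfigurationError):
        d.StrategyMatrices(strategy_id="x", early=early, late=early)
    with pytest.raises(d.ConfigurationError):
        d.StrategyMatrices(strategy_id="x", early=early, late=None)


# --------------------------------------------------------- matrix invariants

def test_matrix_violation_report_names_each_problem():
    bad = ROW1.copy()
    bad[1, 1] -= 0.1                      # row sum 0.9
    bad[2, 0] = 0.05                      # inflow to state 1
    bad[2, 2] -= 0.05
    bad[4, 4] = 0.9                       # absorbing row broken
    bad[4, 3] = 0.1
    report = make_matrix("x", "early", bad).violations()
    text = "\n".join(report)
    assert "row 2" in text and "0.9" in text
    assert "return to state 1 from state 3" in text
    assert "absorbing" in text
    with pytest.raises(d.InvalidMatrixError):
        make_matrix("x", "early", bad).validate()


def test_valid_matrix_has_no_violations():
    assert make_matrix("x", "late", ROW1).violations() == []


# ------------------------------------------------------------------ advancing

def test_advance_identity_and_absorbing():
    ident = make_matrix("x", "early", np.eye(5))
    occ = np.array([100.0, 200.0, 300.0, 250.0, 150.0])
    assert np.array_equal(d.advance_cohort(occ, ident), occ)
    blind = np.array([0.0, 0.0, 0.0, 0.0, 1000.0])
    assert np.array_equal(
        d.advance_cohort(blind, make_matrix("x", "early", ROW1)), blind)


def test_advance_matches_hand_product():
    occ = np.array([1000.0, 0, 0, 0, 0])
    out = d.advance_cohort(occ, make_matrix("x", "early", ROW1))
    assert np.allclose(out, [700, 200, 80, 20, 0])


def test_advance_rejects_bad_input():
    matrix = make_matrix("x", "early", ROW1)
    with pytest.raises(d.InvalidInputError):
        d.advance_cohort(np.ones(4), matrix)
    with pytest.raises(d.InvalidInputError):
        d.advance_cohort(np.array([-1.0, 0, 0, 0, 1]), matrix)


# --------------------------------------------------------------------- traces

def test_zero_horizon_trace_is_the_initial_occupancy(dex, bank):
    trace = d.run_trace(dex, bank[dex.id], 0.0)
    assert trace.occupancy.shape == (1, 5)
    assert np.array_equal(trace.occupancy[0], [1000, 0, 0, 0, 0])


def test_identity_matrices_freeze_the_cohort(dex):
    trace = d.run_trace(dex, identity_pair(dex.id), 3.0)
    assert np.array_equal(trace.occupancy,
                          np.tile([1000, 0, 0, 0, 0],
                                  (trace.grid.n_cycles + 1, 1)))


def test_two_cycle_trace_matches_repeated_hand_multiplication(dex):
    pair = d.StrategyMatrices(
        strategy_id=dex.id,
        early=make_matrix(dex.id, "early", ROW1),
        late=make_matrix(dex.id, "late", ROW1))
    trace = d.run_trace(dex, pair, 10.0 / 12.0)   # two 5-month cycles
    step1 = np.array([1000.0, 0, 0, 0, 0]) @ ROW1
    step2 = step1 @ ROW1
    assert np.allclose(trace.occupancy[1], step1, atol=1e-12)
    assert np.allclose(trace.occupancy[2], step2, atol=1e-12)


@pytest.mark.parametrize("strategy_fixture, n_cycles",
                         [("dex", 2), ("dex", 3), ("ta", 3)])
def test_trace_matches_path_enumeration_oracle(strategy_fixture, n_cycles,
                                               bank, request):
    """Occupancy after <=3 cycles equals the brute-force sum over paths."""
    strategy = request.getfixturevalue(strategy_fixture)
    pair = bank[strategy.id]
    horizon = n_cycles * strategy.cycle_length_months / 12.0
    trace = d.run_trace(strategy, pair, horizon)
    mats = [d.select_matrix(pair, start).p for start in trace.grid.boundaries]
    expected = brute_force_occupancy([1000, 0, 0, 0, 0], mats)
    assert np.allclose(trace.occupancy[-1], expected, atol=1e-9)


def test_conservation_and_monotone_absorption(default_cfg, bank):
    for strategy in default_cfg.strategies:
        trace = d.run_trace(strategy, bank[strategy.id], 5.0)
        sums = trace.occupancy.sum(axis=1)
        assert np.allclose(sums, 1000.0, atol=1e-6)
        state1 = trace.occupancy[:, 0]
        state5 = trace.occupancy[:, 4]
        assert np.all(np.diff(state1) <= 1e-12)
        assert np.all(np.diff(state5) >= -1e-12)
        for series in trace.cumulative_onceonly.values():
            assert np.all(np.diff(series) >= -1e-15)
            assert series[-1] <= 1.0 + 1e-12


def test_period_switch_takes_effect_at_first_late_cycle(dex, bank):
    """Early-only and early/late runs diverge exactly at the 12-month rule."""
    pair = bank[dex.id]
    early_only = d.StrategyMatrices(
        strategy_id=dex.id, early=pair.early,
        late=make_matrix(dex.id, "late", pair.early.p))
    a = d.run_trace(dex, pair, 2.0)
    b = d.run_trace(dex, early_only, 2.0)
    # dexamethasone cycles start at 0,5,10,15,20: first late cycle is index 3
    first_late = int(np.argmax(a.grid.boundaries >= 12.0))
    assert np.allclose(a.occupancy[:first_late + 1],
                       b.occupancy[:first_late + 1], atol=0)
    assert not np.allclose(a.occupancy[first_late + 1],
                           b.occupancy[first_late + 1])


@settings(max_examples=25, derandomize=True, deadline=None)
@given(data=st.data())
def test_conservation_holds_for_arbitrary_valid_matrices(data):
    """Mass conservation and absorption monotonicity are structural."""
    def row(ncols):
        return data.draw(st.lists(
            st.floats(0.0, 1.0, allow_nan=False), min_size=ncols,
            max_size=ncols))

    p = np.zeros((5, 5))
    r0 = np.array(row(5)) + 1e-3
    p[0] = r0 / r0.sum()
    for i in (1, 2, 3):
        ri = np.array([0.0, *row(4)]) + np.eye(5)[i] * 1e-3
        p[i] = ri / ri.sum()
    p[4, 4] = 1.0
    pair = d.StrategyMatrices(
        strategy_id="dexamethasone",
        early=make_matrix("dexamethasone", "early", p),
        late=make_matrix("dexamethasone", "late", p))
    from dmocea import defaults
    trace = d.run_trace(defaults.dexamethasone_strategy(), pair, 2.0)
    assert np.allclose(trace.occupancy.sum(axis=1), 1000.0, atol=1e-6)
    assert np.all(np.diff(trace.occupancy[:, 0]) <= 1e-9)
    assert np.all(np.diff(trace.occupancy[:, 4]) >= -1e-9)


# --------------------------------------------------------------------- CSV IO

def test_matrix_bank_csv_round_trip(bank, tmp_path):
    path = tmp_path / "matrices.csv"
    d.write_matrix_bank_csv(bank, path)
    loaded = d.read_matrix_bank_csv(path)
    assert set(loaded) == set(bank)
    for sid in bank:
        assert np.array_equal(loaded[sid].early.p, bank[sid].early.p)
        assert np.array_equal(loaded[sid].late.p, bank[sid].late.p)


def test_matrix_csv_missing_columns_is_configuration_error(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("strategy,period\nx,early\n")
    with pytest.raises(d.ConfigurationError):
        d.read_matrix_bank_csv(path)
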