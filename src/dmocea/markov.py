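"""Cohort state-transition engine.

A hypothetical cohort (1000 patients in the base case) starts in state 1
and is propagated through strategy-specific cycle grids by 5x5 row-
stochastic transition matrices.  Each strategy has two matrices: an
*early* one for cycles starting in the first 12 months (first doses are
more effective) and a *late* one thereafter.  The model has no mortality
and no exits: occupancy mass is conserved, state 5 is absorbing and no
row may flow back into state 1.
"""
from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    InvalidInputError,
    InvalidMatrixError,
    InvalidParameterError,
)
from .schedules import OnceOnlyMode, TreatmentStrategy, step_once_only_ledger
from .states import N_STATES, treated_eyes_vector

PERIOD_EARLY = "early"
PERIOD_LATE = "late"
#: months after which the late-period matrix takes over (cycle start time)
EARLY_LATE_BOUNDARY_MONTHS = 12.0

_ROW_SUM_TOL = 1e-9


@dataclass(frozen=True)
class TransitionMatrix:
    """A per-cycle 5x5 transition matrix for one strategy and period."""

    strategy_id: str
    period: str
    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.shape != (N_STATES, N_STATES):
            raise InvalidInputError(
                f"transition matrix must be {N_STATES}x{N_STATES}, got {p.shape}")
        p = p.copy()
        p.setflags(write=False)
        object.__setattr__(self, "p", p)
        if self.period not in (PERIOD_EARLY, PERIOD_LATE):
            raise InvalidInputError(
                f"period must be 'early' or 'late', got {self.period!r}")

    def violations(self) -> list[str]:
        """Structural invariant violations, as human-readable messages."""
        tag = f"{self.strategy_id}/{self.period}"
        out: list[str] = []
        p = self.p
        if np.any(p < -1e-15) or np.any(p > 1 + 1e-15):
            bad = np.argwhere((p < -1e-15) | (p > 1 + 1e-15))
            for i, j in bad:
                out.append(f"{tag}: entry ({i + 1},{j + 1}) = {p[i, j]:.6g} "
                           "outside [0, 1]")
        sums = p.sum(axis=1)
        for i, s in enumerate(sums):
            if abs(s - 1.0) > _ROW_SUM_TOL:
                out.append(f"{tag}: row {i + 1} sums to {s:.12g} "
                           f"(deficit {1.0 - s:+.3g})")
        inflow = p[1:, 0]
        for i in np.nonzero(inflow != 0.0)[0]:
            out.append(f"{tag}: forbidden return to state 1 from state "
                       f"{i + 2} (p = {inflow[i]:.6g})")
        expected_last = np.zeros(N_STATES)
        expected_last[-1] = 1.0
        if not np.array_equal(p[-1], expected_last):
            out.append(f"{tag}: row 5 is {p[-1].tolist()}; state 5 must be "
                       "absorbing, i.e. (0, 0, 0, 0, 1)")
        return out

    def validate(self) -> "TransitionMatrix":
        problems = self.violations()
        if problems:
            raise InvalidMatrixError("; ".join(problems))
        return self


@dataclass(frozen=True)
class StrategyMatrices:
    """The early/late matrix pair for one treatment strategy."""

    strategy_id: str
    early: TransitionMatrix
    late: TransitionMatrix

    def __post_init__(self) -> None:
        for m, period in ((self.early, PERIOD_EARLY), (self.late, PERIOD_LATE)):
            if m is None:
                raise ConfigurationError(
                    f"strategy {self.strategy_id!r}: missing {period} matrix")
            if m.period != period:
                raise ConfigurationError(
                    f"strategy {self.strategy_id!r}: matrix tagged "
                    f"{m.period!r} supplied as the {period} matrix")

    def validate(self) -> "StrategyMatrices":
        self.early.validate()
        self.late.validate()
        return self


@dataclass(frozen=True)
class CycleGrid:
    """Cycle start times covering a horizon, plus a truncated last cycle.

    All cycles have the strategy's fixed length; when the horizon is not
    an integer number of cycles, the last cycle is truncated and carries
    ``final_cycle_fraction`` of a full cycle's cost/QALY accrual.
    """

    cycle_length_months: float
    boundaries: np.ndarray
    final_cycle_fraction: float = 1.0

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        b.setflags(write=False)
        object.__setattr__(self, "boundaries", b)

    @property
    def n_cycles(self) -> int:
        return len(self.boundaries)

    @property
    def fractions(self) -> np.ndarray:
        f = np.ones(self.n_cycles)
        if self.n_cycles:
            f[-1] = self.final_cycle_fraction
        return f

    @property
    def durations_months(self) -> np.ndarray:
        return self.fractions * self.cycle_length_months

    @property
    def horizon_months(self) -> float:
        return float(self.durations_months.sum()) if self.n_cycles else 0.0


def build_cycle_grid(cycle_length_months: float,
                     horizon_years: float) -> CycleGrid:
    """Lay a fixed-length cycle grid over ``horizon_years``.

    The grid covers exactly ``12 * horizon_years`` months; a non-integer
    quotient yields a final fractional cycle whose weight is the
    remainder divided by the cycle length.
    """
    if cycle_length_months <= 0:
        raise InvalidParameterError(
            f"cycle_length_months must be positive, got {cycle_length_months}")
    if horizon_years <= 0:
        raise InvalidParameterError(
            f"horizon_years must be positive, got {horizon_years}")
    horizon_months = 12.0 * horizon_years
    quotient = horizon_months / cycle_length_months
    n_full = int(math.floor(quotient + 1e-9))
    remainder = horizon_months - n_full * cycle_length_months
    if remainder <= cycle_length_months * 1e-9:
        n_cycles, fraction = n_full, 1.0
    else:
        n_cycles, fraction = n_full + 1, remainder / cycle_length_months
    boundaries = np.arange(n_cycles) * cycle_length_months
    return CycleGrid(cycle_length_months=cycle_length_months,
                     boundaries=boundaries,
                     final_cycle_fraction=fraction)


def select_matrix(matrices: StrategyMatrices,
                  cycle_start_months: float) -> TransitionMatrix:
    """Pick the early or late matrix for a cycle by its *start* time.

    A cycle beginning before month 12 uses the early matrix even if it
    ends after month 12: dosing (and its effect) is delivered at cycle
    start.
    """
    if cycle_start_months < 0:
        raise InvalidParameterError("cycle start time cannot be negative")
    if cycle_start_months < EARLY_LATE_BOUNDARY_MONTHS:
        return matrices.early
    return matrices.late


def advance_cohort(occupancy: np.ndarray,
                   matrix: TransitionMatrix) -> np.ndarray:
    """One cycle of cohort propagation: ``occupancy . P``."""
    occ = np.asarray(occupancy, dtype=float)
    if occ.shape != (N_STATES,):
        raise InvalidInputError(
            f"occupancy must be a length-{N_STATES} vector, got {occ.shape}")
    if np.any(occ < 0):
        raise InvalidInputError("occupancy counts cannot be negative")
    matrix.validate()
    return occ @ matrix.p


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle occupancy of the cohort plus once-only bookkeeping.

    ``occupancy`` has one row per cycle start and a final row at the
    horizon (``n_cycles + 1`` rows).  ``cumulative_onceonly`` maps each
    once-only adverse event to the fraction of the cohort that has
    incurred it by each of those times.
    """

    strategy_id: str
    grid: CycleGrid
    occupancy: np.ndarray
    times_months: np.ndarray
    cohort_size: float
    cumulative_onceonly: Mapping[str, np.ndarray] = field(default_factory=dict)
    once_only_mode: OnceOnlyMode = "saturating"

    def to_frame(self) -> pd.DataFrame:
        """Trace as a tidy table: time, occupancy, once-only ledgers."""
        data: dict[str, np.ndarray] = {"time_months": self.times_months}
        for i in range(N_STATES):
            data[f"state_{i + 1}"] = self.occupancy[:, i]
        for name, series in self.cumulative_onceonly.items():
            data[f"onceonly_{name}"] = series
        return pd.DataFrame(data)


def run_trace(
    strategy: TreatmentStrategy,
    matrices: StrategyMatrices,
    horizon_years: float,
    cohort_size: float = 1000.0,
    *,
    treat_in_state5: bool = False,
    once_only_mode: OnceOnlyMode = "saturating",
) -> CohortTrace:
    """Propagate the whole cohort from state 1 over the horizon.

    Transitions in a truncated final cycle are applied in full (a state
    change is a discrete event tied to the dose); only cost/QALY accrual
    downstream is weighted by the cycle fraction.  A zero horizon yields
    a trace holding just the initial occupancy.
    """
    if matrices.strategy_id != strategy.id:
        raise ConfigurationError(
            f"matrices are for {matrices.strategy_id!r}, "
            f"strategy is {strategy.id!r}")
    if horizon_years < 0:
        raise InvalidParameterError("horizon_years cannot be negative")
    if cohort_size <= 0:
        raise InvalidParameterError("cohort_size must be positive")
    matrices.validate()

    once_names = [ev.name for ev in strategy.adverse_events if ev.once_only]
    if horizon_years == 0:
        grid = CycleGrid(cycle_length_months=strategy.cycle_length_months,
                         boundaries=np.empty(0))
        occ = np.zeros((1, N_STATES))
        occ[0, 0] = cohort_size
        return CohortTrace(
            strategy_id=strategy.id, grid=grid, occupancy=occ,
            times_months=np.zeros(1), cohort_size=cohort_size,
            cumulative_onceonly={n: np.zeros(1) for n in once_names},
            once_only_mode=once_only_mode)

    grid = build_cycle_grid(strategy.cycle_length_months, horizon_years)
    n = grid.n_cycles
    occupancy = np.zeros((n + 1, N_STATES))
    occupancy[0, 0] = cohort_size
    ledgers = {name: np.zeros(n + 1) for name in once_names}
    ledger = {name: 0.0 for name in once_names}
    treated = treated_eyes_vector(treat_in_state5) >= 1
    fractions = grid.fractions
    for i, start in enumerate(grid.boundaries):
        matrix = select_matrix(matrices, start)
        occupancy[i + 1] = occupancy[i] @ matrix.p
        _, ledger = step_once_only_ledger(
            occupancy[i], strategy.adverse_events, ledger,
            cycle_fraction=fractions[i], treated_mask=treated,
            cycle_index=i, mode=once_only_mode)
        for name in once_names:
            ledgers[name][i + 1] = ledger[name]
    times = np.append(grid.boundaries, 12.0 * horizon_years)
    return CohortTrace(
        strategy_id=strategy.id, grid=grid, occupancy=occupancy,
        times_months=times, cohort_size=cohort_size,
        cumulative_onceonly=ledgers, once_only_mode=once_only_mode)


# ---------------------------------------------------------------------------
# matrix CSV interface


def write_matrix_bank_csv(bank: Mapping[str, StrategyMatrices],
                          path) -> None:
    """Write a set of strategy matrices to a single CSV file.

    Layout: one row per origin state with columns ``strategy, period,
    from_state, to_1 .. to_5``.
    """
    rows = []
    for strategy_id, pair in bank.items():
        for matrix in (pair.early, pair.late):
            for i in range(N_STATES):
                row = {"strategy": strategy_id, "period": matrix.period,
                       "from_state": i + 1}
                row.update({f"to_{j + 1}": matrix.p[i, j]
                            for j in range(N_STATES)})
                rows.append(row)
    # %.17g round-trips float64 exactly
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_matrix_bank_csv(path) -> dict[str, StrategyMatrices]:
    """Read matrices written by :func:`write_matrix_bank_csv`."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"strategy", "period", "from_state",
                *(f"to_{j}" for j in range(1, N_STATES + 1))}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(
            f"matrix CSV {path}: missing columns {sorted(missing)}")
    bank: dict[str, StrategyMatrices] = {}
    for strategy_id, group in df.groupby("strategy", sort=False):
        matrices: dict[str, TransitionMatrix] = {}
        for period, rows in group.groupby("period", sort=False):
            rows = rows.sort_values("from_state")
            if list(rows["from_state"]) != list(range(1, N_STATES + 1)):
                raise ConfigurationError(
                    f"matrix CSV {path}: strategy {strategy_id!r} period "
                    f"{period!r} must have exactly rows 1..{N_STATES}")
            p = rows[[f"to_{j}" for j in range(1, N_STATES + 1)]].to_numpy()
            matrices[period] = TransitionMatrix(
                strategy_id=str(strategy_id), period=str(period), p=p)
        if set(matrices) != {PERIOD_EARLY, PERIOD_LATE}:
            raise ConfigurationError(
                f"matrix CSV {path}: strategy {strategy_id!r} needs one "
                f"'early' and one 'late' matrix, found {sorted(matrices)}")
        bank[str(strategy_id)] = StrategyMatrices(
            strategy_id=str(strategy_id),
            early=matrices[PERIOD_EARLY], late=matrices[PERIOD_LATE])
    return bank
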