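"""Scenario configuration: loading, validation, defaults, matrix resolution.

A scenario config bundles everything one analysis needs: the two
treatment strategies, cost schedules, a utility set, the transition
matrices (inline, from CSV, or synthetic), horizons, discount rates,
cohort size and the model switches.  The bundled defaults reproduce the
published base case: a 1000-patient cohort, 2- and 5-year horizons, 0%
and 3% discounting, 5-month dexamethasone and 4-month triamcinolone
cycles, and the 2019 Kuopio price catalogue.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Literal, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, \
    field_validator, model_validator

from . import defaults
from .errors import ConfigurationError
from .markov import StrategyMatrices, TransitionMatrix, read_matrix_bank_csv
from .schedules import FollowUpSchedule, OnceOnlyMode, \
    RehabilitationSchedule, TreatmentStrategy, UtilitySet
from .synthetic import MatrixGenSpec, generate_matrices


class Switches(BaseModel):
    """Resolutions of the model's documented open interpretation points."""

    model_config = ConfigDict(frozen=True)

    #: do blind patients (state 5) keep receiving drug?  Default: no —
    #: blindness is the model endpoint.
    treat_in_state5: bool = False
    #: do blind patients keep accruing OCT/IOP/FAG monitoring costs?
    followup_in_state5: bool = False
    #: once-only adverse events: saturating cohort-fraction ledger, or a
    #: single lump sum in the first cycle.
    once_only_mode: OnceOnlyMode = "saturating"


InlineMatrices = dict[str, dict[str, list[list[float]]]]


class ScenarioConfig(BaseModel):
    """Complete, validated description of one analysis scenario."""

    model_config = ConfigDict(frozen=True)

    strategies: tuple[TreatmentStrategy, TreatmentStrategy]
    reference_strategy: str | None = None
    #: None -> synthetic matrices from ``gen_spec``; a path string -> CSV
    #: file; a nested mapping strategy -> {early|late -> 5x5 rows}.
    matrices: Union[str, InlineMatrices, None] = None
    followup: FollowUpSchedule = Field(default_factory=defaults.default_followup)
    rehab: RehabilitationSchedule = Field(default_factory=defaults.default_rehab)
    utilities: UtilitySet = Field(default_factory=defaults.utility_set)
    horizons_years: tuple[float, ...] = (2.0, 5.0)
    discount_rates: tuple[float, ...] = (0.0, 0.03)
    cohort_size: float = Field(default=1000.0, gt=0)
    seed: int = 1
    gen_spec: MatrixGenSpec = Field(default_factory=MatrixGenSpec)
    switches: Switches = Field(default_factory=Switches)

    @field_validator("utilities", mode="before")
    @classmethod
    def _resolve_utility_selector(cls, v: Any) -> Any:
        if isinstance(v, str):
            return defaults.utility_set(v)
        return v

    @field_validator("discount_rates")
    @classmethod
    def _rates_non_negative(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if any(r < 0 for r in v):
            raise ValueError("discount rates cannot be negative")
        return v

    @field_validator("horizons_years")
    @classmethod
    def _horizons_non_negative(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if any(h < 0 for h in v):
            raise ValueError("horizons cannot be negative")
        return v

    @model_validator(mode="after")
    def _consistent(self) -> "ScenarioConfig":
        ids = [s.id for s in self.strategies]
        if len(set(ids)) != len(ids):
            raise ValueError(f"strategy ids must be distinct, got {ids}")
        if self.reference_strategy is not None \
                and self.reference_strategy not in ids:
            raise ValueError(
                f"reference_strategy {self.reference_strategy!r} is not one "
                f"of the configured strategies {ids}")
        return self

    @property
    def reference_id(self) -> str:
        return self.reference_strategy or self.strategies[0].id

    @property
    def comparator_id(self) -> str:
        ref = self.reference_id
        return next(s.id for s in self.strategies if s.id != ref)

    def strategy(self, strategy_id: str) -> TreatmentStrategy:
        for s in self.strategies:
            if s.id == strategy_id:
                return s
        raise ConfigurationError(f"no strategy {strategy_id!r} configured")


def default_config(**overrides: Any) -> ScenarioConfig:
    """The published base case; keyword overrides replace single fields."""
    base: dict[str, Any] = {
        "strategies": (defaults.dexamethasone_strategy(),
                       defaults.triamcinolone_strategy()),
    }
    base.update(overrides)
    return ScenarioConfig(**base)


def _format_validation_error(exc: ValidationError, path: Path | str) -> str:
    lines = [f"invalid scenario config {path}:"]
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        lines.append(f"  {loc}: {err['msg']}")
    return "\n".join(lines)


def load_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a YAML or JSON scenario config.

    All invariant violations are reported together in one
    :class:`ConfigurationError`.  A relative matrix CSV path inside the
    config is resolved against the config file's directory.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    try:
        text = path.read_text()
        raw = json.loads(text) if path.suffix == ".json" \
            else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    try:
        config = ScenarioConfig(**raw)
    except ValidationError as exc:
        raise ConfigurationError(_format_validation_error(exc, path)) from exc
    if isinstance(config.matrices, str):
        resolved = (path.parent / config.matrices).resolve()
        if not resolved.exists():
            raise ConfigurationError(
                f"{path}: matrices file not found: {resolved}")
        config = config.model_copy(update={"matrices": str(resolved)})
    return config


def save_config(config: ScenarioConfig, path: str | Path) -> None:
    """Write a config back to YAML/JSON; ``load_config`` round-trips it."""
    path = Path(path)
    payload = config.model_dump(mode="json")
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=True))


def resolve_matrices(config: ScenarioConfig) -> dict[str, StrategyMatrices]:
    """Produce the validated matrix bank a config refers to.

    Synthetic matrices are generated from ``gen_spec`` with the config's
    seed, so two runs with the same config are bit-identical.
    """
    if config.matrices is None:
        spec = config.gen_spec.model_copy(update={"seed": config.seed})
        bank = generate_matrices(spec, config.strategies)
    elif isinstance(config.matrices, str):
        bank = read_matrix_bank_csv(config.matrices)
    else:
        bank = {}
        for strategy_id, periods in config.matrices.items():
            if set(periods) != {"early", "late"}:
                raise ConfigurationError(
                    f"inline matrices for {strategy_id!r}: need exactly "
                    f"'early' and 'late', got {sorted(periods)}")
            bank[strategy_id] = StrategyMatrices(
                strategy_id=strategy_id,
                early=TransitionMatrix(strategy_id=strategy_id,
                                       period="early", p=periods["early"]),
                late=TransitionMatrix(strategy_id=strategy_id,
                                      period="late", p=periods["late"]))
    missing = {s.id for s in config.strategies} - set(bank)
    if missing:
        raise ConfigurationError(
            f"no transition matrices for strategies {sorted(missing)}")
    for pair in bank.values():
        pair.validate()
    return bank
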