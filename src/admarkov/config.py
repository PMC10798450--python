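"""Flat YAML run configuration with strict key validation."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict

import yaml

from .model import ModelOptions, ParameterSet, StateVector, VARIABLES
from .stochastic import StochasticConfig

__all__ = ["RunConfig", "load_config"]

logger = logging.getLogger(__name__)

ENGINES = ("deterministic", "stochastic", "ensemble")

#: run-level keys and the RunConfig attribute they map to
_RUN_KEYS = ("engine", "horizon_days", "output_dt", "inner_dt", "n_runs")
_STOCH_KEYS = (
    "sigma", "step_scale", "fixed_dt", "force_fire", "relative_noise",
    "coupling", "seed",
)
_OPTS_KEYS = ("abeta_o_clearance",)


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one run.

    Fully default construction reproduces the reference setup: the default
    initial condition and parameter set, a 10-year horizon (3650 daily output
    steps for the deterministic engine) and 25 matched replicates for
    ensembles.
    """

    engine: str = "deterministic"
    params: ParameterSet = field(default_factory=ParameterSet)
    initial: StateVector = field(default_factory=StateVector)
    opts: ModelOptions = field(default_factory=ModelOptions)
    stoch: StochasticConfig = field(default_factory=StochasticConfig)
    horizon_days: float = 3650.0
    output_dt: float = 1.0
    inner_dt: float = 0.05
    n_runs: int = 25

    def __post_init__(self) -> None:
        if self.engine not in ENGINES:
            raise ValueError(f"unknown engine {self.engine!r}; choose from {ENGINES}")
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2")

    def describe(self) -> str:
        stoch = {f.name: getattr(self.stoch, f.name)
                 for f in dataclasses.fields(self.stoch)}
        return (
            f"engine={self.engine} horizon_days={self.horizon_days} "
            f"output_dt={self.output_dt} inner_dt={self.inner_dt} "
            f"n_runs={self.n_runs} abeta_o_clearance={self.opts.abeta_o_clearance} "
            f"stochastic={stoch}"
        )


def _expect_number(key: str, value: Any) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ValueError(f"config key {key!r} must be a number, got {value!r}")
    return float(value)


def _expect_bool(key: str, value: Any) -> bool:
    if not isinstance(value, bool):
        raise ValueError(f"config key {key!r} must be a boolean, got {value!r}")
    return value


def load_config(path: str | Path) -> RunConfig:
    """Load a flat key->value YAML file over the defaults.

    Recognised keys are the parameter names (e.g. ``lambda_Nd``), the state
    variable names (initial-condition overrides), the model option
    ``abeta_o_clearance``, the stochastic knobs (``sigma``, ``step_scale``,
    ``fixed_dt``, ``force_fire``, ``relative_noise``, ``coupling``, ``seed``)
    and the run settings (``engine``, ``horizon_days``, ``output_dt``,
    ``inner_dt``, ``n_runs``).  Any unknown key is an error naming the key;
    an empty file yields pure defaults.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must be a flat key-value mapping")

    param_names = set(ParameterSet.names())
    state_names = set(VARIABLES)

    params_kw: Dict[str, float] = {}
    initial_kw: Dict[str, float] = {}
    opts_kw: Dict[str, Any] = {}
    stoch_kw: Dict[str, Any] = {}
    run_kw: Dict[str, Any] = {}

    for key, value in raw.items():
        if key in param_names:
            params_kw[key] = _expect_number(key, value)
        elif key in state_names:
            initial_kw[key] = _expect_number(key, value)
        elif key in _OPTS_KEYS:
            opts_kw[key] = _expect_bool(key, value)
        elif key in _STOCH_KEYS:
            if key in ("force_fire", "relative_noise"):
                stoch_kw[key] = _expect_bool(key, value)
            elif key == "coupling":
                stoch_kw[key] = str(value)
            elif key == "seed":
                stoch_kw[key] = int(_expect_number(key, value))
            elif key == "fixed_dt":
                stoch_kw[key] = None if value is None else _expect_number(key, value)
            else:
                stoch_kw[key] = _expect_number(key, value)
        elif key in _RUN_KEYS:
            if key == "engine":
                run_kw[key] = str(value)
            elif key == "n_runs":
                run_kw[key] = int(_expect_number(key, value))
            else:
                run_kw[key] = _expect_number(key, value)
        else:
            raise ValueError(f"unknown config key {key!r} in {path}")

    try:
        config = RunConfig(
            params=ParameterSet(**params_kw),
            initial=StateVector(**initial_kw),
            opts=ModelOptions(**opts_kw),
            stoch=StochasticConfig(**stoch_kw),
            **run_kw,
        )
    except ValueError as exc:
        raise ValueError(f"invalid configuration in {path}: {exc}") from exc
    logger.info("effective configuration: %s", config.describe())
    return config
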