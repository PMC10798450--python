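"""Two-state-Markov stochastic engine with state-dependent stoichiometry.

Every species toggles between an "existing" and a "removed/translocated"
state through birth, death and emigration events.  The stoichiometry is not
constant: when a channel fires over a global step of length ``dt``, the
concentration changes by the channel's instantaneous rate times ``dt``, so
the scheme is a randomized explicit-Euler method whose fully-accepted,
fixed-step limit reproduces the deterministic integrator exactly.

Each global step:

1. evaluates the per-variable birth/death channel rates at the current state;
2. draws per-variable waiting times (exponential, mean inversely proportional
   to each variable's share of the total rate) that set the order in which the
   species are visited, i.e. the order in which the step's random numbers are
   consumed;
3. draws the global step length ``dt`` from an exponential clock with mean
   ``step_scale`` (capped at the remaining horizon) — the per-variable waits
   themselves cannot be used as the clock because the channel rates span ten
   orders of magnitude, which would make the slowest species' wait, and hence
   any max/min rule over waits, longer than the whole horizon;
4. visits each species and accepts or rejects its channels by comparing a
   uniform draw against a noisy acceptance probability ``n`` drawn from a
   normal distribution centred on the channel's relative propensity
   (channel rate over total rate).  The acceptance noise has an absolute
   standard deviation ``sigma`` by default: rates are averages, and the noise
   floor is what lets channels whose relative propensity is vanishingly small
   still fire occasionally instead of freezing their species entirely;
5. applies the accepted channels' rate*dt changes, crediting emigration to
   the destination species, and clamps at zero.

Coupling policy: species whose transition row includes an emigration process
(A_beta_i, F_i) fire as a single both-or-none event — the translocated
quantum must leave and arrive synchronously with the local production and
clearance it is tied to.  Plain birth/death rows fire their two channels
independently, as in an ordinary birth-death Markov chain.  The ``coupling``
option also provides the fully coupled ("all") and fully independent
("none") variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, Optional, Tuple

import numpy as np

from .model import (
    ChannelRates,
    ModelOptions,
    ParameterSet,
    StateVector,
    VARIABLES,
    _birth_death_arrays,
    _params_tuple,
    _validate_state_array,
    channel_rates,
)
from .trajectory import Trajectory

__all__ = [
    "StochasticConfig",
    "JumpSchedule",
    "AbsorbedStateError",
    "draw_acceptance",
    "draw_waiting_times",
    "step",
    "simulate",
    "make_jump_schedule",
    "COUPLING_POLICIES",
]

#: coupling policy name -> boolean mask over VARIABLES (True = both-or-none).
COUPLING_POLICIES: Dict[str, Tuple[bool, ...]] = {
    "emigration": tuple(name in ("A_beta_i", "F_i") for name in VARIABLES),
    "all": tuple(True for _ in VARIABLES),
    "none": tuple(False for _ in VARIABLES),
}


class AbsorbedStateError(RuntimeError):
    """Raised when every channel rate is zero and no event can occur."""


@dataclass(frozen=True)
class StochasticConfig:
    """Knobs of the stochastic engine.

    sigma
        Standard deviation of the normal acceptance draw.  Interpreted as an
        absolute value by default; with ``relative_noise`` it scales with the
        acceptance mean instead (which silences channels whose relative
        propensity is tiny).
    step_scale
        Mean of the exponential global step, days.  The default 0.05 day
        keeps essentially all steps below the explicit-update stability bound
        2/d_Abetai ~ 0.21 day of the stiffest channel.
    fixed_dt
        Optional override: every step (and every waiting time) is exactly
        this long; removes the random clock.
    force_fire
        Treat every acceptance probability as 1.  Together with ``fixed_dt``
        the engine is fully deterministic and reproduces explicit Euler.
    coupling
        "emigration" (default), "all" or "none"; see the module docstring.
    seed
        Seed for the run's random generator.
    """

    sigma: float = 0.1
    step_scale: float = 0.05
    fixed_dt: Optional[float] = None
    force_fire: bool = False
    relative_noise: bool = False
    coupling: str = "emigration"
    seed: int = 1

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.step_scale <= 0:
            raise ValueError("step_scale must be > 0")
        if self.fixed_dt is not None and self.fixed_dt <= 0:
            raise ValueError("fixed_dt must be > 0 when set")
        if self.coupling not in COUPLING_POLICIES:
            raise ValueError(
                f"unknown coupling policy {self.coupling!r}; "
                f"choose from {sorted(COUPLING_POLICIES)}"
            )

    def replace(self, **kwargs) -> "StochasticConfig":
        return replace(self, **kwargs)

    @property
    def coupled_mask(self) -> np.ndarray:
        return np.array(COUPLING_POLICIES[self.coupling], dtype=bool)


@dataclass(frozen=True)
class JumpSchedule:
    """Pre-drawn global time increments shared by matched replicates."""

    increments: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        inc = np.asarray(self.increments, dtype=float)
        object.__setattr__(self, "increments", inc)
        if len(inc) == 0 or np.any(inc <= 0):
            raise ValueError("schedule increments must be positive")

    def __len__(self) -> int:
        return len(self.increments)

    @property
    def total(self) -> float:
        return float(self.increments.sum())


def draw_acceptance(
    mean_p: float, cfg: StochasticConfig, rng: np.random.Generator
) -> float:
    """Noisy acceptance probability for one channel, clipped to [0, 1].

    A normal draw centred on ``mean_p`` (a relative propensity) with standard
    deviation ``cfg.sigma`` (times ``mean_p`` under ``relative_noise``).
    Degenerates to ``clip(mean_p)`` at sigma 0 and to 1 under ``force_fire``.
    """
    if mean_p < 0:
        raise ValueError("mean_p must be >= 0")
    if cfg.force_fire:
        return 1.0
    std = cfg.sigma * mean_p if cfg.relative_noise else cfg.sigma
    if std == 0:
        return float(min(max(mean_p, 0.0), 1.0))
    return float(min(max(rng.normal(mean_p, std), 0.0), 1.0))


def draw_waiting_times(
    channels: ChannelRates, cfg: StochasticConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-variable time until the next event, days.

    Each variable with total rate ``r_i > 0`` gets an exponential wait with
    mean ``step_scale * (sum_j r_j) / (k * r_i)`` where ``k`` is the number of
    active variables: rare channels wait longer in proportion to their share
    of the total rate, and with equal rates the mean wait is ``step_scale``.
    Inactive variables wait forever; with ``fixed_dt`` every active variable
    gets exactly ``fixed_dt``.

    Raises
    ------
    AbsorbedStateError
        If every channel rate is zero.
    """
    totals = channels.total()
    active = totals > 0
    k = int(active.sum())
    if k == 0:
        raise AbsorbedStateError("all channel rates are zero")
    waits = np.full(9, math.inf)
    if cfg.fixed_dt is not None:
        waits[active] = cfg.fixed_dt
        return waits
    means = cfg.step_scale * totals.sum() / (k * totals[active])
    waits[active] = rng.standard_exponential(k) * means
    return waits


def _step_arrays(
    x: np.ndarray,
    pt: tuple,
    clearance: bool,
    cfg: StochasticConfig,
    rng: np.random.Generator,
    coupled: np.ndarray,
    forced_dt: Optional[float],
    max_dt: Optional[float],
    birth: np.ndarray,
    death: np.ndarray,
) -> Tuple[np.ndarray, float, np.ndarray]:
    """One engine step on raw arrays; returns (new_state, elapsed, fired)."""
    _birth_death_arrays(x, pt, clearance, birth, death)
    totals = birth + death
    tot = totals.sum()
    if tot <= 0.0:
        elapsed = max_dt if max_dt is not None else (forced_dt or math.inf)
        raise AbsorbedStateError(f"absorbed state; remaining horizon {elapsed}")

    # Waiting times fix the visit order; the global clock is exponential.
    if forced_dt is not None:
        waits = np.where(totals > 0, forced_dt, math.inf)
        dt = forced_dt
    elif cfg.fixed_dt is not None:
        waits = np.where(totals > 0, cfg.fixed_dt, math.inf)
        dt = cfg.fixed_dt
    else:
        active = totals > 0
        k = int(active.sum())
        waits = np.full(9, math.inf)
        means = cfg.step_scale * tot / (k * totals[active])
        waits[active] = rng.standard_exponential(k) * means
        dt = cfg.step_scale * rng.standard_exponential()
    if max_dt is not None and dt > max_dt:
        dt = max_dt

    order = np.argsort(waits, kind="stable")
    fired = np.zeros(9, dtype=bool)
    new = x.copy()
    if cfg.force_fire:
        new += (birth - death) * dt
        fired[:] = totals > 0
    else:
        z = rng.standard_normal((9, 2))
        u = rng.random((9, 2))
        rel = cfg.relative_noise
        sigma = cfg.sigma
        for pos in range(9):
            j = order[pos]
            if coupled[j]:
                p = totals[j] / tot
                std = sigma * p if rel else sigma
                n = p + std * z[pos, 0]
                n = 0.0 if n < 0.0 else (1.0 if n > 1.0 else n)
                if u[pos, 0] < n:
                    new[j] += (birth[j] - death[j]) * dt
                    fired[j] = True
            else:
                p = birth[j] / tot
                std = sigma * p if rel else sigma
                n = p + std * z[pos, 0]
                n = 0.0 if n < 0.0 else (1.0 if n > 1.0 else n)
                if u[pos, 0] < n and birth[j] > 0:
                    new[j] += birth[j] * dt
                    fired[j] = True
                p = death[j] / tot
                std = sigma * p if rel else sigma
                n = p + std * z[pos, 1]
                n = 0.0 if n < 0.0 else (1.0 if n > 1.0 else n)
                if u[pos, 1] < n and death[j] > 0:
                    new[j] -= death[j] * dt
                    fired[j] = True
    np.maximum(new, 0.0, out=new)
    return new, dt, fired


def step(
    state: StateVector,
    t: float,
    params: ParameterSet,
    opts: ModelOptions,
    cfg: StochasticConfig,
    rng: np.random.Generator,
    forced_dt: Optional[float] = None,
    max_dt: Optional[float] = None,
) -> Tuple[StateVector, float, Dict[str, bool]]:
    """Advance the stochastic model by one global step.

    Returns the new state, the elapsed time, and a per-variable flag saying
    whether any of its channels fired.  In an absorbed state (every rate
    zero) the state is returned unchanged and the elapsed time is the
    remaining horizon ``max_dt`` (infinite when no horizon is given).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    x = _validate_state_array(state.as_array())
    birth = np.empty(9)
    death = np.empty(9)
    try:
        new, dt, fired = _step_arrays(
            x, _params_tuple(params), opts.abeta_o_clearance, cfg, rng,
            cfg.coupled_mask, forced_dt, max_dt, birth, death,
        )
    except AbsorbedStateError:
        elapsed = max_dt if max_dt is not None else (forced_dt or math.inf)
        return state, elapsed, {name: False for name in VARIABLES}
    return (
        StateVector.from_array(new),
        dt,
        dict(zip(VARIABLES, fired.tolist())),
    )


def make_jump_schedule(
    params: ParameterSet = ParameterSet(),
    opts: ModelOptions = ModelOptions(),
    cfg: StochasticConfig = StochasticConfig(),
    horizon_days: float = 3650.0,
    seed: int = 1,
) -> JumpSchedule:
    """Pre-draw the global time increments for matched-replicate runs.

    All replicates consuming the schedule share an identical time grid, which
    is what makes cross-replicate variance computable pointwise.  With
    ``fixed_dt`` the schedule is the exact regular grid; otherwise it is the
    engine's exponential clock (mean ``step_scale``) drawn up to the horizon.
    ``params`` and ``opts`` are accepted for signature stability; the global
    clock does not depend on the state.
    """
    if horizon_days <= 0:
        raise ValueError("horizon_days must be > 0")
    if cfg.fixed_dt is not None:
        n = int(math.ceil(horizon_days / cfg.fixed_dt - 1e-12))
        return JumpSchedule(np.full(n, cfg.fixed_dt), seed=seed)
    rng = np.random.default_rng(seed)
    chunks = []
    total = 0.0
    while total < horizon_days:
        chunk = rng.standard_exponential(8192) * cfg.step_scale
        chunks.append(chunk)
        total += chunk.sum()
    increments = np.concatenate(chunks)
    stop = int(np.searchsorted(np.cumsum(increments), horizon_days)) + 1
    return JumpSchedule(increments[:stop], seed=seed)


def simulate(
    initial: StateVector = StateVector(),
    params: ParameterSet = ParameterSet(),
    opts: ModelOptions = ModelOptions(),
    cfg: StochasticConfig = StochasticConfig(),
    horizon_days: float = 3650.0,
    schedule: Optional[JumpSchedule] = None,
) -> Trajectory:
    """Run the stochastic engine to the horizon, recording every step.

    When ``schedule`` is given its increments are used verbatim as the global
    steps (truncating the final one at the horizon), so replicates sharing a
    schedule share an identical grid.  The same seed always reproduces the
    same trajectory bit for bit.
    """
    if horizon_days <= 0:
        raise ValueError("horizon_days must be > 0")
    rng = np.random.default_rng(cfg.seed)
    pt = _params_tuple(params)
    clearance = opts.abeta_o_clearance
    coupled = cfg.coupled_mask
    birth = np.empty(9)
    death = np.empty(9)

    x = _validate_state_array(initial.as_array())
    times = [0.0]
    states = [x.copy()]
    t = 0.0
    eps = 1e-9
    sched_iter = iter(schedule.increments) if schedule is not None else None
    while t < horizon_days - eps:
        remaining = horizon_days - t
        if sched_iter is not None:
            try:
                forced = float(next(sched_iter))
            except StopIteration as exc:  # guarded by the schedule invariant
                raise ValueError("jump schedule ended before the horizon") from exc
            forced = min(forced, remaining)
            max_dt = None
        else:
            forced = None
            max_dt = remaining
        try:
            x, dt, _ = _step_arrays(
                x, pt, clearance, cfg, rng, coupled, forced, max_dt, birth, death
            )
        except AbsorbedStateError:
            # no event can ever occur again; hold the state to the horizon
            times.append(horizon_days)
            states.append(x.copy())
            break
        t += dt
        times.append(min(t, horizon_days))
        states.append(x.copy())
    return Trajectory(
        times=np.array(times),
        states=np.array(states),
        metadata={
            "engine": "stochastic",
            "seed": cfg.seed,
            "sigma": cfg.sigma,
            "step_scale": cfg.step_scale,
            "fixed_dt": cfg.fixed_dt,
            "force_fire": cfg.force_fire,
            "relative_noise": cfg.relative_noise,
            "coupling": cfg.coupling,
            "horizon_days": horizon_days,
            "abeta_o_clearance": opts.abeta_o_clearance,
            "matched_schedule": schedule is not None,
        },
    )
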