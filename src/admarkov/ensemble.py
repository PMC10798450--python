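"""Matched-replicate ensembles and the variance / CV analysis.

Replicate stochastic runs are forced onto one shared sequence of time jumps
so that the cross-replicate spread is computable pointwise.  The dispersion
measure is the coefficient of variation (CV), the ratio of the sample
standard deviation to the mean across replicates at each grid time; the
summary reports each species' variance and CV averaged over the grid, the CV
at the first and last shared grid points, and the number of other species
its rate equation touches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .model import (
    ModelOptions,
    ParameterSet,
    StateVector,
    VARIABLES,
    interaction_counts,
)
from .stochastic import JumpSchedule, StochasticConfig, make_jump_schedule, simulate
from .trajectory import Trajectory

__all__ = [
    "Ensemble",
    "EnsembleSummary",
    "run_ensemble",
    "cv_series",
    "variance_series",
    "summarize",
    "direction_agreement",
    "SUMMARY_ROWS",
]

logger = logging.getLogger(__name__)

SUMMARY_ROWS = ("mean_variance", "mean_cv", "cv_first", "cv_last", "n_interactions")


@dataclass(frozen=True)
class Ensemble:
    """Replicate trajectories on one shared time grid.

    ``states`` has shape (n_runs, n_times, 9).
    """

    times: np.ndarray
    states: np.ndarray
    seeds: Tuple[int, ...]
    config: StochasticConfig
    horizon_days: float

    def __post_init__(self) -> None:
        if self.states.ndim != 3 or self.states.shape[2] != 9:
            raise ValueError(f"states must be (runs, times, 9), got {self.states.shape}")
        if self.states.shape[0] != len(self.seeds):
            raise ValueError("one seed per replicate required")
        if self.states.shape[1] != len(self.times):
            raise ValueError("grid length mismatch")

    @property
    def n_runs(self) -> int:
        return self.states.shape[0]

    def trajectory(self, i: int) -> Trajectory:
        return Trajectory(
            times=self.times,
            states=self.states[i],
            metadata={"engine": "stochastic", "seed": self.seeds[i], "replicate": i},
        )


@dataclass(frozen=True)
class EnsembleSummary:
    """Per-species dispersion summary of a matched ensemble."""

    mean_variance: np.ndarray
    mean_cv: np.ndarray
    cv_first: np.ndarray
    cv_last: np.ndarray
    n_interactions: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [self.mean_variance, self.mean_cv, self.cv_first, self.cv_last,
             self.n_interactions],
            index=list(SUMMARY_ROWS),
            columns=list(VARIABLES),
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, float_format="%.17g", index_label="measurement")

    def most_variable(self) -> str:
        """Species with the largest mean CV."""
        return VARIABLES[int(np.argmax(self.mean_cv))]

    def __str__(self) -> str:
        df = self.to_frame()
        with pd.option_context("display.float_format", "{:.3e}".format,
                               "display.width", 200):
            return df.to_string()


def run_ensemble(
    n_runs: int = 25,
    base_seed: int = 1,
    params: ParameterSet = ParameterSet(),
    opts: ModelOptions = ModelOptions(),
    cfg: StochasticConfig = StochasticConfig(),
    horizon_days: float = 3650.0,
    initial: StateVector = StateVector(),
    schedule: Optional[JumpSchedule] = None,
) -> Ensemble:
    """Run matched replicates sharing one jump schedule.

    The schedule is drawn from ``base_seed`` and the replicates use seeds
    ``base_seed + 1 .. base_seed + n_runs``, so an ensemble is reproducible
    from (base_seed, config) alone.
    """
    if n_runs < 2:
        raise ValueError("need at least 2 replicates for any variance computation")
    if schedule is None:
        schedule = make_jump_schedule(params, opts, cfg, horizon_days, seed=base_seed)
    seeds = tuple(base_seed + 1 + i for i in range(n_runs))
    runs = []
    grid = None
    for seed in seeds:
        traj = simulate(
            initial, params, opts, cfg.replace(seed=seed), horizon_days, schedule
        )
        if grid is None:
            grid = traj.times
        elif not np.array_equal(grid, traj.times):
            raise AssertionError("matched replicates diverged from the shared grid")
        runs.append(traj.states)
    return Ensemble(
        times=grid,
        states=np.stack(runs),
        seeds=seeds,
        config=cfg,
        horizon_days=horizon_days,
    )


def variance_series(ens: Ensemble) -> np.ndarray:
    """Cross-replicate sample variance (n-1 denominator) at each grid time."""
    if ens.n_runs < 2:
        raise ValueError("variance requires at least 2 replicates")
    return ens.states.var(axis=0, ddof=1)


def cv_series(ens: Ensemble) -> np.ndarray:
    """Cross-replicate coefficient of variation at each grid time.

    CV = sample standard deviation / mean; defined as 0 where the mean is 0
    (which only happens when every replicate is extinct there).
    """
    if ens.n_runs < 2:
        raise ValueError("CV requires at least 2 replicates")
    mean = ens.states.mean(axis=0)
    sd = ens.states.std(axis=0, ddof=1)
    zero = mean == 0
    if np.any(zero & (sd > 0)):
        logger.warning("zero cross-replicate mean with nonzero spread; CV set to 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(zero, 0.0, sd / np.where(zero, 1.0, mean))
    return cv


def summarize(ens: Ensemble, opts: ModelOptions = ModelOptions()) -> EnsembleSummary:
    """Grid-averaged variance and CV per species, plus interaction counts.

    The averages weight every shared grid point equally (the grid indexes
    events, not uniform time).
    """
    var = variance_series(ens)
    cv = cv_series(ens)
    counts = interaction_counts(opts)
    return EnsembleSummary(
        mean_variance=var.mean(axis=0),
        mean_cv=cv.mean(axis=0),
        cv_first=cv[0],
        cv_last=cv[-1],
        n_interactions=np.array([counts[name] for name in VARIABLES], dtype=float),
    )


def direction_agreement(traj: Trajectory, reference: Trajectory) -> Dict[str, bool]:
    """Whether each species' net change has the same sign in both runs.

    Compares sign(final - initial) per species; both trajectories must cover
    the same horizon.  Zero net change matches only zero net change.
    """
    if abs(traj.times[-1] - reference.times[-1]) > 1e-6 * max(1.0, reference.times[-1]):
        raise ValueError(
            f"trajectories cover different horizons: "
            f"{traj.times[-1]} vs {reference.times[-1]}"
        )
    s1 = np.sign(traj.states[-1] - traj.states[0])
    s2 = np.sign(reference.states[-1] - reference.states[0])
    return {name: bool(s1[i] == s2[i]) for i, name in enumerate(VARIABLES)}
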