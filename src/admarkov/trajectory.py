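"""Trajectory container and lossless CSV round-trip."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict

import numpy as np
import pandas as pd

from .model import VARIABLES, StateVector

__all__ = ["Trajectory", "write_trajectory", "read_trajectory", "CSV_COLUMNS"]

CSV_COLUMNS = ("time",) + VARIABLES


@dataclass
class Trajectory:
    """Time series of the nine concentrations.

    ``times`` are days, strictly increasing and starting at 0; ``states`` has
    one row per time point, columns in canonical variable order; ``metadata``
    carries the engine tag, seed and options so a run can be reproduced.
    """

    times: np.ndarray
    states: np.ndarray
    metadata: Dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.ndim != 2 or self.states.shape[1] != 9:
            raise ValueError(f"states must be (n, 9), got {self.states.shape}")
        if len(self.times) != len(self.states):
            raise ValueError("times and states lengths differ")
        if len(self.times) == 0:
            raise ValueError("empty trajectory")
        if self.times[0] != 0.0:
            raise ValueError("trajectory must start at time 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.states < 0):
            raise ValueError("states must be non-negative")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def initial(self) -> StateVector:
        return StateVector.from_array(self.states[0])

    @property
    def final(self) -> StateVector:
        return StateVector.from_array(self.states[-1])

    def variable(self, name: str) -> np.ndarray:
        """One species' concentration series."""
        return self.states[:, VARIABLES.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(VARIABLES))
        df.insert(0, "time", self.times)
        return df


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as CSV (17 significant digits, lossless round-trip).

    Metadata is stored in ``# key=value`` comment lines before the header.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in traj.metadata.items():
            fh.write(f"# {key}={value}\n")
        traj.to_frame().to_csv(fh, index=False, float_format="%.17g")


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a trajectory CSV written by :func:`write_trajectory`."""
    path = Path(path)
    metadata: Dict[str, Any] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                metadata[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, float_precision="round_trip")
    for col in CSV_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"trajectory file {path} is missing column {col!r}")
    extra = [c for c in df.columns if c not in CSV_COLUMNS]
    if extra:
        raise ValueError(f"trajectory file {path} has unexpected columns {extra}")
    return Trajectory(
        times=df["time"].to_numpy(),
        states=df[list(VARIABLES)].to_numpy(),
        metadata=metadata,
    )
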