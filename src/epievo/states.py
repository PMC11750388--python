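"""State containers and time-indexed trajectories."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["EpiState", "EvoState", "Trajectory"]

EPI_COLUMNS = ("sH", "sL", "iH", "iL")
EVO_COLUMNS = EPI_COLUMNS + ("epsH", "epsL")


@dataclass(frozen=True)
class EpiState:
    """Densities of the four host compartments at one time point.

    ``sH``/``sL`` are susceptible high-/low-yield hosts, ``iH``/``iL``
    the corresponding infected classes.  Densities are nonnegative.
    """

    sH: float
    sL: float
    iH: float
    iL: float

    def validate(self) -> None:
        for name in EPI_COLUMNS:
            if getattr(self, name) < 0:
                raise ValueError(f"negative density {name}={getattr(self, name)}")

    def as_array(self) -> np.ndarray:
        return np.array([self.sH, self.sL, self.iH, self.iL], dtype=float)

    @classmethod
    def from_array(cls, y) -> "EpiState":
        return cls(*map(float, y))

    @property
    def total(self) -> float:
        return self.sH + self.sL + self.iH + self.iL

    @property
    def infected(self) -> float:
        return self.iH + self.iL


@dataclass(frozen=True)
class EvoState:
    """Epidemiological state plus the mean within-host growth rate
    among infections of each host type (``epsH``, ``epsL`` > 0)."""

    epi: EpiState
    epsH: float
    epsL: float

    def validate(self) -> None:
        self.epi.validate()
        if self.epsH <= 0 or self.epsL <= 0:
            raise ValueError("mean traits epsH, epsL must be > 0")

    # convenience pass-throughs
    @property
    def sH(self) -> float:
        return self.epi.sH

    @property
    def sL(self) -> float:
        return self.epi.sL

    @property
    def iH(self) -> float:
        return self.epi.iH

    @property
    def iL(self) -> float:
        return self.epi.iL

    def as_array(self) -> np.ndarray:
        return np.concatenate([self.epi.as_array(), [self.epsH, self.epsL]])

    @classmethod
    def from_array(cls, y) -> "EvoState":
        return cls(EpiState.from_array(y[:4]), float(y[4]), float(y[5]))


class Trajectory:
    """A time-indexed sequence of model states.

    Wraps a tidy :class:`pandas.DataFrame` whose first column is
    ``time`` (strictly increasing); the remaining columns are state
    components and, after annotation, derived per-time metrics.
    """

    def __init__(self, frame: pd.DataFrame):
        if "time" not in frame.columns:
            raise ValueError("trajectory frame needs a 'time' column")
        t = frame["time"].to_numpy()
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_arrays(cls, times, data, columns) -> "Trajectory":
        times = np.asarray(times, dtype=float)
        data = np.asarray(data, dtype=float)
        if data.shape[0] != times.shape[0]:
            raise ValueError("times and states must have matching length")
        frame = pd.DataFrame(data, columns=list(columns))
        frame.insert(0, "time", times)
        return cls(frame)

    # -- basics -----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    @property
    def times(self) -> np.ndarray:
        return self.frame["time"].to_numpy()

    @property
    def columns(self) -> list[str]:
        return [c for c in self.frame.columns if c != "time"]

    def state_at(self, i: int) -> EpiState | EvoState:
        row = self.frame.iloc[i]
        epi = EpiState(row["sH"], row["sL"], row["iH"], row["iL"])
        if "epsH" in self.frame.columns:
            return EvoState(epi, row["epsH"], row["epsL"])
        return epi

    def final_state(self) -> EpiState | EvoState:
        return self.state_at(len(self) - 1)

    def with_columns(self, extra: pd.DataFrame) -> "Trajectory":
        """New trajectory with derived per-time columns appended."""
        if len(extra) != len(self.frame):
            raise ValueError("extra columns must match trajectory length")
        merged = pd.concat(
            [self.frame, extra.reset_index(drop=True)], axis=1)
        return Trajectory(merged)

    # -- export -----------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return self.frame.copy()

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        self.frame.to_json(path, orient="records", double_precision=12)
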