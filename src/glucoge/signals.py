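"""Uniformly sampled time-series container shared by all modules.

Every continuous quantity in the package (CGM glucose, meal rate of
appearance Ra, insulin on board) is carried as a :class:`UniformSignal`:
an array of samples plus a start time and a fixed sampling period, both in
minutes. The index/time bijection is ``t = t0 + i * dt``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["UniformSignal", "AlignmentError"]


class AlignmentError(ValueError):
    """Raised when signals expected to share a sampling grid do not."""


@dataclass
class UniformSignal:
    """A uniformly sampled signal.

    Parameters
    ----------
    values : array-like
        Sample values.
    t0 : float
        Time of the first sample, minutes since scenario start.
    dt : float
        Sampling period in minutes; must be positive.
    """

    values: np.ndarray
    t0: float = 0.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("signal needs at least one sample in a 1-d array")
        if not self.dt > 0:
            raise ValueError(f"sampling period must be positive, got {self.dt}")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Sample times in minutes."""
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def duration(self) -> float:
        """Span from first to last sample, minutes."""
        return self.dt * (self.values.size - 1)

    def index_of(self, t: float) -> int:
        """Index of the sample at time ``t``; ``t`` must lie on the grid."""
        x = (t - self.t0) / self.dt
        i = int(round(x))
        if abs(x - i) > 1e-9 or not (0 <= i < self.values.size):
            raise ValueError(f"time {t} is not on the sampling grid")
        return i

    def value_at(self, t: float) -> float:
        return float(self.values[self.index_of(t)])

    def subsample(self, period: float, t0: float | None = None) -> "UniformSignal":
        """Pick samples every ``period`` minutes starting at ``t0``.

        Used to move 1-min physiological signals onto the 5-min CGM grid.
        ``period`` must be an integer multiple of ``dt``.
        """
        step = period / self.dt
        if abs(step - round(step)) > 1e-9:
            raise AlignmentError(f"period {period} is not a multiple of dt {self.dt}")
        step = int(round(step))
        start = 0 if t0 is None else self.index_of(t0)
        return UniformSignal(self.values[start::step].copy(),
                             t0=self.t0 + start * self.dt, dt=period)

    def same_grid(self, other: "UniformSignal") -> bool:
        return (abs(self.dt - other.dt) < 1e-9
                and abs(self.t0 - other.t0) < 1e-9
                and len(self) == len(other))
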