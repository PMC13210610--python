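"""Uniformly sampled single-axis angular-velocity records.

The analysis works on the x-axis gyroscope channel of a chest-mounted IMU
(upper-back angular velocity, rad/s) sampled at a nominal 1 ms step.  In the
sign convention used throughout, negative angular velocity corresponds to the
drive (the rower working against the ergometer load) and positive angular
velocity to the recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DataError


@dataclass(frozen=True)
class SeriesMeta:
    """Provenance of one trial: who, when, at which power grade."""

    participant: str | None = None
    stage: str | None = None
    grade: int | None = None
    source: str | None = None

    def key(self) -> tuple:
        return (self.participant, self.stage, self.grade)

    def label(self) -> str:
        parts = [str(p) for p in self.key() if p is not None]
        return "/".join(parts) if parts else "unlabelled"


@dataclass(frozen=True)
class AngularVelocitySeries:
    """A uniformly sampled angular-velocity record.

    Parameters
    ----------
    values : array of float
        Angular-velocity samples (rad/s), at least two, all finite.
    dt : float
        Sampling step in seconds (nominally 0.001).
    t0 : float
        Time of the first sample in seconds.
    meta : SeriesMeta
        Participant / stage / grade labels carried through the pipeline.
    """

    values: np.ndarray
    dt: float
    t0: float = 0.0
    meta: SeriesMeta = field(default_factory=SeriesMeta)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise DataError("values must be one-dimensional")
        if vals.size < 2:
            raise DataError("a series needs at least 2 samples")
        if not np.all(np.isfinite(vals)):
            raise DataError("series contains non-finite samples")
        if not (self.dt > 0):
            raise DataError(f"sampling step must be positive, got {self.dt}")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def time(self) -> np.ndarray:
        """Sample times t0 + i*dt (s)."""
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def t_end(self) -> float:
        return self.t0 + self.dt * (self.values.size - 1)

    @property
    def duration(self) -> float:
        return self.dt * (self.values.size - 1)

    @property
    def nyquist(self) -> float:
        """Nyquist frequency 1/(2*dt) in Hz."""
        return 0.5 / self.dt

    def with_values(self, values: np.ndarray) -> "AngularVelocitySeries":
        """Same grid and metadata, new samples."""
        return replace(self, values=np.asarray(values, dtype=float))

    def with_meta(self, **kwargs) -> "AngularVelocitySeries":
        return replace(self, meta=replace(self.meta, **kwargs))
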