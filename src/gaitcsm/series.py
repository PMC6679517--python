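"""Core time-series container for two-channel ground contact forces.

A :class:`GCFSeries` holds one foot's ball and heel load-cell traces on a
uniform time grid. Index conventions are 0-based and intervals are
half-open throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FormatError

CHANNELS = ("ball", "heel")


@dataclass(frozen=True)
class GCFSeries:
    """Uniformly sampled two-channel force trace for one foot.

    Parameters
    ----------
    t_ms:
        Timestamps in milliseconds, uniform and strictly increasing.
    ball, heel:
        Force values (arbitrary force units) for the ball and heel
        load cells; the algorithms are scale-covariant so no unit
        conversion is applied anywhere.
    sample_rate_hz:
        Sampling rate; must agree with ``t_ms`` spacing.
    """

    t_ms: np.ndarray
    ball: np.ndarray
    heel: np.ndarray
    sample_rate_hz: float

    def __post_init__(self) -> None:
        t = np.asarray(self.t_ms, dtype=float)
        ball = np.asarray(self.ball, dtype=float)
        heel = np.asarray(self.heel, dtype=float)
        if not (len(t) == len(ball) == len(heel)):
            raise FormatError("t_ms, ball and heel must have equal length")
        if len(t) == 0:
            raise FormatError("empty series")
        if not (np.isfinite(ball).all() and np.isfinite(heel).all()):
            raise FormatError("forces must be finite")
        if len(t) > 1:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise FormatError("timestamps must be strictly increasing")
            step = 1000.0 / self.sample_rate_hz
            if not np.allclose(dt, step, rtol=1e-9, atol=1e-6):
                raise FormatError(
                    "timestamps are not uniform at the declared sample rate"
                )
        object.__setattr__(self, "t_ms", t)
        object.__setattr__(self, "ball", ball)
        object.__setattr__(self, "heel", heel)

    @property
    def n(self) -> int:
        return len(self.t_ms)

    @property
    def duration_ms(self) -> float:
        return self.n * 1000.0 / self.sample_rate_hz

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise KeyError(f"unknown channel {name!r}; expected one of {CHANNELS}")
        return getattr(self, name)

    def with_channels(self, ball: np.ndarray, heel: np.ndarray) -> "GCFSeries":
        """Return a copy of this series with replaced force channels."""
        return GCFSeries(self.t_ms.copy(), ball, heel, self.sample_rate_hz)
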