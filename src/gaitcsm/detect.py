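"""Streaming on/off-ground detection and four-pattern gait classification.

The detector initializes in the on-ground state (G = 1 for the first
three samples) and, from the fourth sample on, builds the 10-element
curve of the current 4-sample window and compares it with both status
templates. If the distance to the on-ground-start template satisfies
d1 <= epsilon the state becomes on-ground (this branch has priority);
otherwise if the off-ground-start distance satisfies d2 <= epsilon the
state becomes off-ground; otherwise the previous state persists.

A starting flag is recorded at the first window of each contiguous run
of satisfied tests (a detected phase entry); separate runs within one
cycle yield repeated same-type flags, which do not toggle the state.

The binary status codes here (1 = on-ground, 0 = off-ground) are a
distinct vocabulary from the four-phase label codes of the reference
labeling; use :attr:`gaitcsm.reference.PhaseTrack.binary` to map label
tracks into this vocabulary.

Combining the two channels of one foot yields the four gait patterns:
both on-ground = stance, both off = swing, heel only = heel strike,
ball only = heel-off.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .csm import OFF_START, ON_START, CSMModel, build_curve, curve_matrix, distance_matrix
from .series import GCFSeries

#: gait pattern codes, indexed by 2 * ball_status + heel_status
_PATTERNS = np.array(["swing", "heel_strike", "heel_off", "stance"])

STANCE = "stance"
SWING = "swing"
HEEL_STRIKE = "heel_strike"
HEEL_OFF = "heel_off"


class Flag(NamedTuple):
    """A detected status starting flag."""

    index: int
    flag_type: str  # "on_start" or "off_start"


@dataclass(frozen=True)
class StatusStream:
    """Per-sample binary status plus the flags that produced it."""

    g: np.ndarray
    flags: list[Flag]


def detect_stream(channel: np.ndarray, model: CSMModel) -> StatusStream:
    """Single-pass batch detection over a force channel.

    Causal: G(k) depends only on samples up to k. Equivalent to feeding
    the samples one by one into :class:`StreamingDetector`.
    """
    x = np.asarray(channel, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("channel must contain at least 4 samples")
    windows = np.lib.stride_tricks.sliding_window_view(x, 4)
    curves = curve_matrix(windows)
    d1 = distance_matrix(curves, model.on_template)
    d2 = distance_matrix(curves, model.off_template)
    on_fire = d1 <= model.epsilon
    off_fire = ~on_fire & (d2 <= model.epsilon)
    g = np.empty(n, dtype=np.int64)
    g[:3] = 1
    state = 1
    flags: list[Flag] = []
    prev_on = prev_off = False
    for k in range(3, n):
        i = k - 3
        if on_fire[i]:
            state = 1
            if not prev_on:
                flags.append(Flag(k, ON_START))
        elif off_fire[i]:
            state = 0
            if not prev_off:
                flags.append(Flag(k, OFF_START))
        prev_on, prev_off = bool(on_fire[i]), bool(off_fire[i])
        g[k] = state
    return StatusStream(g=g, flags=flags)


class StreamingDetector:
    """Incremental push-sample interface with O(1) work per sample."""

    def __init__(self, model: CSMModel):
        self.model = model
        self._buffer: deque[float] = deque(maxlen=4)
        self._state = 1
        self._k = -1
        self._prev_on = False
        self._prev_off = False

    @property
    def state(self) -> int:
        return self._state

    def push(self, sample: float) -> tuple[int, Flag | None]:
        """Consume one sample; return (current status, flag or None)."""
        self._k += 1
        self._buffer.append(float(sample))
        if len(self._buffer) < 4:
            return self._state, None
        curve = build_curve(np.asarray(self._buffer))
        from .csm import similarity_distance

        d1 = similarity_distance(curve, self.model.on_template)
        d2 = similarity_distance(curve, self.model.off_template)
        on_fire = d1 <= self.model.epsilon
        off_fire = not on_fire and d2 <= self.model.epsilon
        flag = None
        if on_fire:
            self._state = 1
            if not self._prev_on:
                flag = Flag(self._k, ON_START)
        elif off_fire:
            self._state = 0
            if not self._prev_off:
                flag = Flag(self._k, OFF_START)
        self._prev_on, self._prev_off = on_fire, off_fire
        return self._state, flag


def classify_gait_pattern(ball_g: np.ndarray, heel_g: np.ndarray) -> np.ndarray:
    """Map paired binary statuses to the four gait patterns.

    (ball=1, heel=1) -> stance, (0, 0) -> swing, (0, 1) -> heel_strike,
    (1, 0) -> heel_off.
    """
    b = np.asarray(ball_g, dtype=np.int64)
    h = np.asarray(heel_g, dtype=np.int64)
    if b.shape != h.shape or b.ndim != 1:
        raise ValueError("ball and heel status vectors must have equal length")
    if not (np.isin(b, (0, 1)).all() and np.isin(h, (0, 1)).all()):
        raise ValueError("status vectors must be binary")
    return _PATTERNS[2 * b + h]


def detect_series(series: GCFSeries, model: CSMModel) -> dict:
    """Detect both channels of a series and classify the gait pattern.

    Returns a dict with per-channel :class:`StatusStream` objects under
    ``"ball"`` / ``"heel"`` and the per-sample pattern under
    ``"pattern"``.
    """
    streams = {ch: detect_stream(series.channel(ch), model) for ch in ("ball", "heel")}
    pattern = classify_gait_pattern(streams["ball"].g, streams["heel"].g)
    return {"ball": streams["ball"], "heel": streams["heel"], "pattern": pattern}
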