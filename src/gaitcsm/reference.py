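"""Global-threshold reference method and four-phase labeling.

The Lopez-Meyer threshold Thr = alpha * (T_MAX - T_MIN) + T_MIN (with
T_MAX / T_MIN the means of per-cycle force maxima / minima and
alpha = 0.094) splits a force channel into on-ground and off-ground
status. Around each threshold crossing a transition buffer of duration
t_W (default 50 ms) is labeled, giving the four-phase track used both to
build training sets and as the evaluation reference:

    3 = on-ground, 1 = initial off-ground, 0 = off-ground,
    2 = initial on-ground,

repeating in the order 3 -> 1 -> 0 -> 2 -> 3. Indices are 0-based and
all windows are half-open [start, start + t_W).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateSignalError, LabelingError
from .series import GCFSeries

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.094
DEFAULT_T_W_MS = 50.0

#: four-phase label codes
ON_GROUND = 3
INITIAL_OFF = 1
OFF_GROUND = 0
INITIAL_ON = 2

#: labels mapped to binary status 1 (on) for the pointwise reference track;
#: the initial windows are pre/post transition buffers: 2 counts as on, 1 as off
_ON_LABELS = (ON_GROUND, INITIAL_ON)


@dataclass(frozen=True)
class ThresholdModel:
    """Global threshold with the extrema means it was derived from."""

    thr: float
    alpha: float
    t_max_mean: float
    t_min_mean: float

    def __post_init__(self) -> None:
        if 0.0 <= self.alpha <= 1.0:
            if not (self.t_min_mean - 1e-9 <= self.thr <= self.t_max_mean + 1e-9):
                raise DegenerateSignalError(
                    "threshold outside [T_MIN, T_MAX] for alpha in [0, 1]"
                )


@dataclass(frozen=True)
class PhaseTrack:
    """Per-sample four-phase labels with the t_W they were built with."""

    labels: np.ndarray
    t_w_ms: float = DEFAULT_T_W_MS

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int64)
        if not np.isin(labels, (0, 1, 2, 3)).all():
            raise LabelingError("labels must lie in {0, 1, 2, 3}")
        object.__setattr__(self, "labels", labels)

    @property
    def binary(self) -> np.ndarray:
        """Binary status: 1 for labels {3, 2}, 0 for labels {0, 1}."""
        return np.isin(self.labels, _ON_LABELS).astype(np.int64)

    @property
    def n(self) -> int:
        return len(self.labels)


def moving_average_filter(series: GCFSeries, window_samples: int) -> GCFSeries:
    """Centered moving average per channel; edges use a shrunk window."""
    if window_samples < 1 or window_samples % 2 == 0:
        raise ValueError("window_samples must be a positive odd integer")
    if window_samples == 1:
        return series.with_channels(series.ball.copy(), series.heel.copy())

    def smooth(x: np.ndarray) -> np.ndarray:
        n = len(x)
        half = window_samples // 2
        csum = np.concatenate(([0.0], np.cumsum(x)))
        idx = np.arange(n)
        lo = np.maximum(0, idx - half)
        hi = np.minimum(n, idx + half + 1)
        return (csum[hi] - csum[lo]) / (hi - lo)

    return series.with_channels(smooth(series.ball), smooth(series.heel))


def filter_window_for_cutoff(cutoff_hz: float, sample_rate_hz: float) -> int:
    """Odd moving-average window approximating a given cut-off frequency.

    At 100 Hz data with a 100 Hz cut-off this is 1 (pass-through).
    """
    w = max(1, int(round(sample_rate_hz / cutoff_hz)))
    return w if w % 2 == 1 else w + 1


def decimate_mean(series: GCFSeries, factor: int) -> GCFSeries:
    """Downsample by non-overlapping block means (e.g. 2000 Hz -> 100 Hz)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return series
    n_blocks = series.n // factor
    if n_blocks == 0:
        raise ValueError("series shorter than one block")

    def block(x: np.ndarray) -> np.ndarray:
        return x[: n_blocks * factor].reshape(n_blocks, factor).mean(axis=1)

    new_rate = series.sample_rate_hz / factor
    t = np.arange(n_blocks) * 1000.0 / new_rate + series.t_ms[0]
    return GCFSeries(t, block(series.ball), block(series.heel), new_rate)


def lopez_threshold_from_extrema(
    maxima: Sequence[float], minima: Sequence[float], alpha: float = DEFAULT_ALPHA
) -> ThresholdModel:
    """Thr = alpha * (T_MAX - T_MIN) + T_MIN from per-cycle extrema lists."""
    if len(maxima) == 0 or len(minima) == 0:
        raise DegenerateSignalError("need at least one per-cycle maximum and minimum")
    t_max = float(np.mean(maxima))
    t_min = float(np.mean(minima))
    return ThresholdModel(
        thr=alpha * (t_max - t_min) + t_min,
        alpha=alpha,
        t_max_mean=t_max,
        t_min_mean=t_min,
    )


def _runs(b: np.ndarray) -> list[tuple[int, int, int]]:
    """Consecutive runs of a vector as (value, start, end) half-open triples."""
    if len(b) == 0:
        return []
    change = np.flatnonzero(np.diff(b)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(b)]))
    return [(int(b[s]), int(s), int(e)) for s, e in zip(starts, ends)]


def compute_lopez_threshold(
    channel: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    sample_rate_hz: float = 100.0,
    min_segment_ms: float = 300.0,
) -> ThresholdModel:
    """Estimate the global threshold from per-cycle force extrema.

    Cycles are delimited by crossings of the channel's mid-range value;
    only segments lasting at least ``min_segment_ms`` contribute an
    extremum. A 3-sample median filter is applied first so isolated
    spike artifacts can neither delimit segments nor become their
    extrema (this estimator is an after-the-fact analysis, so the extra
    one-sample latency of filtering is irrelevant here).
    """
    x = np.asarray(channel, dtype=float)
    if len(x) == 0 or not np.isfinite(x).all():
        raise DegenerateSignalError("channel must be non-empty and finite")
    if len(x) >= 3:
        x = np.median(np.lib.stride_tricks.sliding_window_view(x, 3), axis=1)
    # robust mid-range: extreme quantiles instead of min/max so isolated
    # spike artifacts cannot drag the segmentation level
    lo, hi = (float(q) for q in np.quantile(x, [0.005, 0.995]))
    if hi <= lo:
        raise DegenerateSignalError("flat signal: no extrema to estimate from")
    mid = 0.5 * (lo + hi)
    min_len = max(1, int(round(min_segment_ms * sample_rate_hz / 1000.0)))
    maxima: list[float] = []
    minima: list[float] = []
    for value, s, e in _runs((x >= mid).astype(np.int64)):
        if e - s < min_len:
            continue
        seg = x[s:e]
        if value == 1:
            maxima.append(float(seg.max()))
        else:
            minima.append(float(seg.min()))
    if not maxima or not minima:
        raise DegenerateSignalError(
            "no cycle extrema found (signal too short or segments too brief)"
        )
    return lopez_threshold_from_extrema(maxima, minima, alpha)


def binarize(channel: np.ndarray, thr: float) -> np.ndarray:
    """G(i) = 1 if T(i) >= thr else 0 (boundary inclusive)."""
    if not np.isfinite(thr):
        raise ValueError("thr must be finite")
    return (np.asarray(channel, dtype=float) >= thr).astype(np.int64)


def debounce_binary(b: np.ndarray, min_run_samples: int) -> np.ndarray:
    """Suppress status runs shorter than ``min_run_samples``.

    Short runs are absorbed into the last preceding run of sufficient
    length (the leading run is always kept). Used to automate the
    correction of abnormal tagging caused by spike artifacts.
    """
    if min_run_samples <= 1:
        return np.asarray(b, dtype=np.int64).copy()
    out = np.empty(len(b), dtype=np.int64)
    runs = _runs(np.asarray(b, dtype=np.int64))
    current = runs[0][0]
    for value, s, e in runs:
        if e - s >= min_run_samples:
            current = value
        out[s:e] = current
    return out


def label_four_phases(
    channel: np.ndarray,
    thr: float,
    t_w_ms: float = DEFAULT_T_W_MS,
    sample_rate_hz: float = 100.0,
    min_run_ms: float = 0.0,
) -> PhaseTrack:
    """Label every sample with one of the four phase codes.

    A downward threshold crossing opens an initial-off-ground window
    (label 1) of t_W whose starting position is the first sample below
    the threshold; an upward crossing closes an initial-on-ground window
    (label 2) of t_W whose ending position is the first sample at or
    above the threshold (both boundary samples included in their
    windows, so the window's newest sample is the one that crossed). All
    other samples carry the plain on/off-ground codes (3 / 0). Windows
    truncated at the series edges are clipped and logged.

    Raises :class:`LabelingError` when an off-ground period is shorter
    than 2 * t_W so the two transition windows of a cycle would overlap;
    such abnormal tagging requires manual (or debounced, see
    ``min_run_ms``) correction.
    """
    x = np.asarray(channel, dtype=float)
    n = len(x)
    w = int(round(t_w_ms * sample_rate_hz / 1000.0))
    if w < 1:
        raise ValueError("t_w_ms must convert to at least one sample")
    b = binarize(x, thr)
    if min_run_ms > 0:
        b = debounce_binary(b, int(round(min_run_ms * sample_rate_hz / 1000.0)))
    labels = np.where(b == 1, ON_GROUND, OFF_GROUND).astype(np.int64)
    trans = np.flatnonzero(np.diff(b)) + 1
    if len(trans) == 0:
        return PhaseTrack(labels=labels, t_w_ms=t_w_ms)
    # overlap check: every off-ground period must fit both t_W windows
    down_idx = [int(i) for i in trans if b[i] == 0]
    up_idx = [int(i) for i in trans if b[i] == 1]
    for cyc, i in enumerate(down_idx):
        nxt = [j for j in up_idx if j > i]
        # label-1 occupies [i, i+w), label-2 occupies [j+1-w, j+1)
        if nxt and nxt[0] + 1 - w < i + w:
            raise LabelingError(
                f"cycle {cyc}: off-ground period of {nxt[0] - i} samples is "
                f"too short for two t_W windows of {w} samples; abnormal "
                "tagging requires manual correction"
            )
    for i in down_idx:
        end = min(i + w, n)
        if end - i < w:
            log.info("initial-off window truncated at series end (index %d)", i)
        labels[i:end] = INITIAL_OFF
    for j in up_idx:
        start = max(j + 1 - w, 0)
        if j + 1 - start < w:
            log.info("initial-on window truncated at series start (index %d)", j)
        labels[start : j + 1] = INITIAL_ON
    return PhaseTrack(labels=labels, t_w_ms=t_w_ms)
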