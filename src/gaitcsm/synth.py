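"""Synthetic treadmill-walking ground contact force generator.

Emulates the signal regime the detector is designed for: steady treadmill
walking at 2-6 km/h, gait cycles of ~1000-2000 ms (shorter at higher
speed), a smooth double-bump stance force profile whose amplitude grows
with speed, a near-zero swing baseline with additive Gaussian noise, and
occasional single-sample spike artifacts. Every trace carries its exact
ground-truth contact intervals so downstream stages are testable without
any recorded data.

All randomness flows from the integer seeds in the configuration;
identical configuration gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import ConfigurationError
from .series import CHANNELS, GCFSeries

#: speed -> cycle duration map endpoints: 2 km/h -> 2000 ms, 6 km/h -> 1000 ms
_CYCLE_MS_AT_2 = 2000.0
_CYCLE_MS_AT_6 = 1000.0


def cycle_duration_ms(speed_kmh: float) -> float:
    """Gait cycle duration implied by walking speed (linear, monotone decreasing)."""
    return _CYCLE_MS_AT_2 + (_CYCLE_MS_AT_6 - _CYCLE_MS_AT_2) * (speed_kmh - 2.0) / 4.0


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of one synthetic walking trace.

    ``peak_force`` is the stance peak amplitude at 2 km/h (arbitrary force
    units); the effective amplitude grows linearly with speed through
    ``amp_gain_per_kmh``. The heel channel makes contact ``heel_lead_ms``
    before the ball channel within each cycle (heel-strike precedes
    forefoot loading).
    """

    speed_kmh: float
    duration_s: float = 30.0
    sample_rate_hz: float = 100.0
    stance_fraction: float = 0.6
    peak_force: float = 100.0
    noise_sd: float = 2.0
    spike_rate_per_s: float = 0.1
    spike_magnitude: float = 150.0
    heel_lead_ms: float = 100.0
    seed: int = 0
    # shape of the stance profile: two Gaussian bumps under a flat-top
    # window with short half-cosine edge ramps. The loading/unloading
    # transition lasts ~40-60 ms, slightly shorter at faster walking;
    # edge_ms overrides the speed-derived default when set.
    amp_gain_per_kmh: float = 0.15
    bump_centers: tuple[float, float] = (0.25, 0.75)
    bump_width: float = 0.2
    edge_ms: float | None = None
    heel_bump_ratio: float = 0.8
    ball_bump_ratio: float = 1.25

    def __post_init__(self) -> None:
        if not (2.0 <= self.speed_kmh <= 6.0):
            raise ConfigurationError(
                f"speed_kmh must lie in [2, 6], got {self.speed_kmh}"
            )
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be positive")
        if self.sample_rate_hz <= 0:
            raise ConfigurationError("sample_rate_hz must be positive")
        if not (0.0 < self.stance_fraction < 1.0):
            raise ConfigurationError("stance_fraction must lie in (0, 1)")
        if self.peak_force <= 0:
            raise ConfigurationError("peak_force must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.spike_rate_per_s < 0:
            raise ConfigurationError("spike_rate_per_s must be non-negative")
        if self.spike_magnitude < 0:
            raise ConfigurationError("spike_magnitude must be non-negative")
        if self.n_samples < 8:
            raise ConfigurationError("series must contain at least 8 samples")

    @property
    def n_samples(self) -> int:
        return int(round(self.sample_rate_hz * self.duration_s))

    @property
    def cycle_ms(self) -> float:
        return cycle_duration_ms(self.speed_kmh)

    @property
    def amplitude(self) -> float:
        """Effective stance peak force at this speed."""
        return self.peak_force * (1.0 + self.amp_gain_per_kmh * (self.speed_kmh - 2.0))

    @property
    def effective_edge_ms(self) -> float:
        """Transition ramp duration: 60 ms at 2 km/h down to 40 ms at 6 km/h."""
        if self.edge_ms is not None:
            return self.edge_ms
        return 70.0 - 5.0 * self.speed_kmh


@dataclass(frozen=True)
class GroundTruth:
    """True contact intervals and binary on/off-ground status per channel.

    ``intervals[ch]`` is an ordered list of half-open (start_index,
    end_index) contact intervals; ``binary[ch]`` is the per-sample status
    (1 = on-ground) consistent with those intervals.
    """

    intervals: dict[str, list[tuple[int, int]]]
    binary: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for ch, ivals in self.intervals.items():
            b = self.binary[ch]
            prev_end = 0
            for s, e in ivals:
                if not (0 <= s < e <= len(b)):
                    raise ConfigurationError("interval out of series bounds")
                if s < prev_end:
                    raise ConfigurationError("intervals must be disjoint and ordered")
                prev_end = e
            rebuilt = np.zeros(len(b), dtype=np.int64)
            for s, e in ivals:
                rebuilt[s:e] = 1
            if not np.array_equal(rebuilt, b):
                raise ConfigurationError("binary track inconsistent with intervals")


def _edge_window(s: np.ndarray, r: float) -> np.ndarray:
    """Flat-top window with half-cosine ramps of width r at both edges."""
    w = np.ones_like(s)
    left = s < r
    w[left] = 0.5 * (1.0 - np.cos(np.pi * s[left] / r))
    right = s > 1.0 - r
    w[right] = 0.5 * (1.0 - np.cos(np.pi * (1.0 - s[right]) / r))
    return w


def _stance_profile(s: np.ndarray, config: SynthConfig, bump_ratio: float) -> np.ndarray:
    """Normalized double-bump stance shape on stance fraction s in [0, 1).

    Sum of two Gaussian bumps (heel-strike and push-off peaks) under a
    flat-top window whose short half-cosine edge ramps make the loading
    and unloading transitions fast, with force exactly zero at the
    stance edges; normalized to peak 1.
    """

    stance_ms = config.stance_fraction * config.cycle_ms
    r = min(0.45, config.effective_edge_ms / stance_ms)

    def shape(u: np.ndarray) -> np.ndarray:
        c1, c2 = config.bump_centers
        w = config.bump_width
        raw = np.exp(-((u - c1) ** 2) / (2 * w**2)) + bump_ratio * np.exp(
            -((u - c2) ** 2) / (2 * w**2)
        )
        return raw * _edge_window(np.clip(u, 0.0, 1.0), r)

    grid = np.linspace(0.0, 1.0, 501)
    return shape(s) / shape(grid).max()


def _channel_noiseless(
    config: SynthConfig, offset_ms: float, bump_ratio: float
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    n = config.n_samples
    fs = config.sample_rate_hz
    t = np.arange(n) * 1000.0 / fs
    force = np.zeros(n)
    intervals: list[tuple[int, int]] = []
    stance_ms = config.stance_fraction * config.cycle_ms
    start = offset_ms
    duration_ms = n * 1000.0 / fs
    while start < duration_ms:
        i0 = int(np.ceil(start * fs / 1000.0))
        i1 = min(int(np.ceil((start + stance_ms) * fs / 1000.0)), n)
        if i1 > i0:
            s = (t[i0:i1] - start) / stance_ms
            force[i0:i1] = config.amplitude * _stance_profile(s, config, bump_ratio)
            intervals.append((i0, i1))
        start += config.cycle_ms
    return force, intervals


def generate_walk(config: SynthConfig) -> tuple[GCFSeries, GroundTruth]:
    """Generate one noisy (spike-free) walking trace with its ground truth.

    Spike artifacts are a separate, composable step: see
    :func:`inject_anomalies`.
    """
    n = config.n_samples
    t = np.arange(n) * 1000.0 / config.sample_rate_hz
    heel, heel_iv = _channel_noiseless(config, 0.0, config.heel_bump_ratio)
    ball, ball_iv = _channel_noiseless(
        config, config.heel_lead_ms, config.ball_bump_ratio
    )
    rng = np.random.default_rng(config.seed)
    if config.noise_sd > 0:
        heel = heel + rng.normal(0.0, config.noise_sd, n)
        ball = ball + rng.normal(0.0, config.noise_sd, n)
    binary = {}
    intervals = {"ball": ball_iv, "heel": heel_iv}
    for ch in CHANNELS:
        b = np.zeros(n, dtype=np.int64)
        for s, e in intervals[ch]:
            b[s:e] = 1
        binary[ch] = b
    series = GCFSeries(t, ball, heel, config.sample_rate_hz)
    return series, GroundTruth(intervals=intervals, binary=binary)


def inject_anomalies(series: GCFSeries, config: SynthConfig) -> GCFSeries:
    """Add Poisson-placed single-sample spike artifacts; returns a new series.

    The number of spikes is a Poisson draw with mean
    ``spike_rate_per_s * duration``; each spike adds ``spike_magnitude``
    with random sign to one sample of one randomly chosen channel. The
    input series is not modified.
    """
    if config.spike_rate_per_s < 0:
        raise ConfigurationError("spike_rate_per_s must be non-negative")
    ball = series.ball.copy()
    heel = series.heel.copy()
    if config.spike_rate_per_s > 0:
        # independent stream: offset keeps it distinct from generate_walk's draws
        rng = np.random.default_rng(config.seed + 1_000_003)
        duration_s = series.n / series.sample_rate_hz
        count = int(rng.poisson(config.spike_rate_per_s * duration_s))
        for _ in range(count):
            ch = CHANNELS[int(rng.integers(0, 2))]
            idx = int(rng.integers(0, series.n))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            if ch == "ball":
                ball[idx] += sign * config.spike_magnitude
            else:
                heel[idx] += sign * config.spike_magnitude
    return series.with_channels(ball, heel)


def generate_dataset(
    n_subjects: int,
    speeds: Sequence[float],
    base_seed: int,
    template_config: SynthConfig | None = None,
) -> list[tuple[GCFSeries, GroundTruth]]:
    """Generate one trace per subject x speed, with per-subject jitter.

    Subjects differ by a weight-like multiplicative factor on the stance
    peak force; trace seeds are derived deterministically from
    ``base_seed`` so the full dataset is reproducible.
    """
    if n_subjects < 1:
        raise ConfigurationError("n_subjects must be >= 1")
    speeds = list(speeds)
    if not speeds:
        raise ConfigurationError("speeds must not be empty")
    base = template_config if template_config is not None else SynthConfig(speed_kmh=speeds[0])
    rng = np.random.default_rng(base_seed)
    out: list[tuple[GCFSeries, GroundTruth]] = []
    for _ in range(n_subjects):
        weight_factor = float(np.clip(rng.normal(1.0, 0.08), 0.6, 1.6))
        for speed in speeds:
            trace_seed = int(rng.integers(0, 2**31 - 1))
            cfg = replace(
                base,
                speed_kmh=float(speed),
                peak_force=base.peak_force * weight_factor,
                seed=trace_seed,
            )
            series, truth = generate_walk(cfg)
            series = inject_anomalies(series, cfg)
            out.append((series, truth))
    return out
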