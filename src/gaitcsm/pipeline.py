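"""End-to-end experiment: simulate -> label -> train -> detect -> evaluate.

This module wires the stages together the way the method is meant to be
used: synthetic walking traces are labeled per channel with the
global-threshold reference, template parameters are trained on the
training subjects' channels, the trained model is applied to held-out
subjects, and flags/statuses are scored against the reference labeling.
All randomness flows from one seed, so a run is bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .csm import DEFAULT_EPSILON, CSMModel
from .detect import detect_stream
from .evaluate import EvalCounts, ErrorReport, full_report, match_detections, pointwise_error
from .reference import (
    DEFAULT_ALPHA,
    DEFAULT_T_W_MS,
    PhaseTrack,
    compute_lopez_threshold,
    label_four_phases,
)
from .series import CHANNELS, GCFSeries
from .synth import SynthConfig, generate_dataset
from .train import ECConfig, LabeledChannel, train_csm

log = logging.getLogger(__name__)

#: debounce applied before labeling; automates the manual correction of
#: abnormal tagging caused by spike artifacts
DEFAULT_MIN_RUN_MS = 150.0


@dataclass(frozen=True)
class ExperimentConfig:
    """Study conditions for one simulated train/test experiment."""

    seed: int = 0
    n_subjects: int = 10
    speeds: tuple[float, ...] = (2.0, 4.0, 6.0)
    n_train_subjects: int = 6
    duration_s: float = 20.0
    alpha: float = DEFAULT_ALPHA
    t_w_ms: float = DEFAULT_T_W_MS
    min_run_ms: float = DEFAULT_MIN_RUN_MS
    epsilon: float = DEFAULT_EPSILON
    pop_size: int = 20
    max_gen: int = 50
    synth: SynthConfig | None = None


def label_series(
    series: GCFSeries,
    alpha: float = DEFAULT_ALPHA,
    t_w_ms: float = DEFAULT_T_W_MS,
    min_run_ms: float = DEFAULT_MIN_RUN_MS,
) -> dict[str, PhaseTrack]:
    """Reference-label both channels of a series."""
    tracks = {}
    for ch in CHANNELS:
        x = series.channel(ch)
        thr = compute_lopez_threshold(x, alpha, series.sample_rate_hz)
        tracks[ch] = label_four_phases(
            x, thr.thr, t_w_ms, series.sample_rate_hz, min_run_ms=min_run_ms
        )
    return tracks


def evaluate_series(
    series: GCFSeries, tracks: dict[str, PhaseTrack], model: CSMModel
) -> tuple[EvalCounts, int, int]:
    """Detect one series and score it against its reference tracks.

    Returns the pooled matching counts over both channels plus the
    pointwise (mismatch count, sample count) pair for E4 pooling.
    """
    counts = EvalCounts()
    mismatches = 0
    total = 0
    for ch in CHANNELS:
        stream = detect_stream(series.channel(ch), model)
        counts = counts + match_detections(stream.flags, tracks[ch])
        c = tracks[ch].binary
        mismatches += int((stream.g != c).sum())
        total += len(c)
    return counts, mismatches, total


def _score(
    data: list[tuple[GCFSeries, dict[str, PhaseTrack]]], model: CSMModel
) -> tuple[ErrorReport, EvalCounts, int]:
    counts = EvalCounts()
    mism = 0
    total = 0
    for series, tracks in data:
        c, m, n = evaluate_series(series, tracks, model)
        counts = counts + c
        mism += m
        total += n
    report = full_report(counts)
    e4 = 100.0 * mism / total
    report = ErrorReport(
        F1=report.F1, F2=report.F2, E1=report.E1, E2=report.E2, E3=report.E3, E4=e4
    )
    return report, counts, total


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the full train/test experiment; returns model, reports, history.

    The dataset holds one trace per subject x speed; the first
    ``n_train_subjects`` subjects form the training set (both channels
    of each trace feed template training) and the remaining subjects
    are held out for testing.
    """
    synth = config.synth if config.synth is not None else SynthConfig(
        speed_kmh=config.speeds[0], duration_s=config.duration_s
    )
    dataset = generate_dataset(
        config.n_subjects, config.speeds, base_seed=config.seed, template_config=synth
    )
    n_speeds = len(config.speeds)
    labeled: list[tuple[GCFSeries, dict[str, PhaseTrack]]] = []
    for series, _truth in dataset:
        labeled.append(
            (series, label_series(series, config.alpha, config.t_w_ms, config.min_run_ms))
        )
    n_train = config.n_train_subjects * n_speeds
    train_set, test_set = labeled[:n_train], labeled[n_train:]
    train_channels: list[LabeledChannel] = [
        (series.channel(ch), tracks[ch])
        for series, tracks in train_set
        for ch in CHANNELS
    ]
    ec = ECConfig(
        pop_size=config.pop_size,
        max_gen=config.max_gen,
        seed=config.seed,
        epsilon=config.epsilon,
    )
    log.info(
        "training templates on %d labeled channels (seed=%d, pop=%d, gens=%d)",
        len(train_channels), config.seed, config.pop_size, config.max_gen,
    )
    model, history = train_csm(train_channels, ec)
    train_report, train_counts, train_samples = _score(train_set, model)
    result = {
        "model": model,
        "history": history,
        "train_report": train_report,
        "train_counts": train_counts,
        "train_samples": train_samples,
    }
    if test_set:
        test_report, test_counts, test_samples = _score(test_set, model)
        result["test_report"] = test_report
        result["test_counts"] = test_counts
        result["test_samples"] = test_samples
    return result
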