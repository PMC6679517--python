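"""File formats: GCF/label/flag CSVs and model JSON.

All CSVs are plain text with a fixed header; indices are 0-based and
intervals half-open. The model JSON round-trips at full double
precision: saving, loading and saving again produces a byte-identical
file.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ModelValidityError
from .csm import CSMModel
from .detect import Flag
from .reference import DEFAULT_T_W_MS, PhaseTrack, ThresholdModel
from .series import GCFSeries
from .synth import GroundTruth

GCF_COLUMNS = ["t_ms", "ball", "heel"]


def read_gcf_csv(path: str | Path) -> GCFSeries:
    """Read a two-channel force trace from a ``t_ms,ball,heel`` CSV."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if list(df.columns) != GCF_COLUMNS:
        raise FormatError(
            f"{path}: expected header {','.join(GCF_COLUMNS)}, got "
            f"{','.join(map(str, df.columns))}"
        )
    if len(df) == 0:
        raise FormatError(f"{path}: no data rows")
    bad = df[df.isna().any(axis=1)]
    if len(bad):
        lines = (bad.index + 2).tolist()[:5]
        raise FormatError(f"{path}: malformed rows at lines {lines}")
    t = df["t_ms"].to_numpy(dtype=float)
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise FormatError(f"{path}: t_ms must be strictly increasing")
    rate = 1000.0 / float(np.median(np.diff(t))) if len(t) > 1 else 100.0
    return GCFSeries(t, df["ball"].to_numpy(float), df["heel"].to_numpy(float), rate)


def write_gcf_csv(series: GCFSeries, path: str | Path) -> None:
    df = pd.DataFrame(
        {"t_ms": series.t_ms, "ball": series.ball, "heel": series.heel}
    )
    df.to_csv(path, index=False, float_format="%.10g")


def write_ground_truth_csv(truth: GroundTruth, path: str | Path) -> None:
    """Write contact intervals as ``channel,start_index,end_index`` rows."""
    rows = [
        {"channel": ch, "start_index": s, "end_index": e}
        for ch, ivals in truth.intervals.items()
        for s, e in ivals
    ]
    pd.DataFrame(rows, columns=["channel", "start_index", "end_index"]).to_csv(
        path, index=False
    )


def write_phase_track_csv(track: PhaseTrack, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "index": np.arange(track.n),
            "label": track.labels,
            "binary": track.binary,
        }
    )
    df.to_csv(path, index=False)


def read_phase_track_csv(path: str | Path, t_w_ms: float = DEFAULT_T_W_MS) -> PhaseTrack:
    df = pd.read_csv(path)
    for col in ("index", "label", "binary"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return PhaseTrack(labels=df["label"].to_numpy(np.int64), t_w_ms=t_w_ms)


def write_flags_csv(flags: dict[str, list[Flag]], path: str | Path) -> None:
    """Write per-channel flags as ``index,channel,flag_type`` rows."""
    rows = [
        {"index": f.index, "channel": ch, "flag_type": f.flag_type}
        for ch, fl in flags.items()
        for f in fl
    ]
    pd.DataFrame(rows, columns=["index", "channel", "flag_type"]).to_csv(
        path, index=False
    )


def read_flags_csv(path: str | Path) -> dict[str, list[Flag]]:
    df = pd.read_csv(path)
    for col in ("index", "channel", "flag_type"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    out: dict[str, list[Flag]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["channel"]), []).append(
            Flag(int(row["index"]), str(row["flag_type"]))
        )
    return out


def save_threshold(model: ThresholdModel, path: str | Path) -> None:
    payload = {
        "thr": model.thr,
        "alpha": model.alpha,
        "t_max_mean": model.t_max_mean,
        "t_min_mean": model.t_min_mean,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_threshold(path: str | Path) -> ThresholdModel:
    try:
        payload = json.loads(Path(path).read_text())
        return ThresholdModel(
            thr=float(payload["thr"]),
            alpha=float(payload["alpha"]),
            t_max_mean=float(payload["t_max_mean"]),
            t_min_mean=float(payload["t_min_mean"]),
        )
    except (OSError, KeyError, json.JSONDecodeError) as exc:
        raise FormatError(f"{path}: cannot read threshold JSON: {exc}") from exc


def save_model(model: CSMModel, path: str | Path) -> None:
    Path(path).write_text(model.to_json() + "\n")


def load_model(path: str | Path) -> CSMModel:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ModelValidityError(f"{path}: cannot read model JSON: {exc}") from exc
    return CSMModel.from_dict(payload)


def load_example_model() -> CSMModel:
    """Trained template parameters for adult treadmill walking (2-6 km/h).

    A reference parameter set distributed with the package for
    demonstrations and tests; produced by evolutionary search, so the
    centers are search results rather than empirical window means.
    """
    path = resources.files("gaitcsm") / "data" / "example_model.json"
    return CSMModel.from_dict(json.loads(path.read_text()))
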