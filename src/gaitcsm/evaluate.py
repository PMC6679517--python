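"""Detection evaluation: flag matching protocol and error rates.

Detected starting flags are matched against the four-phase reference
track. For each status i (1 = off-ground, 2 = on-ground) the protocol
counts

    cn_i  true initial windows,
    tn_i  windows containing at least one correct flag,
    mn_i  windows with no flag (missed),
    fn_i  flags raised during the opposite half of the cycle (false),
    sn_i  over-detections: duplicate flags in an already-matched window,
          plus flags raised while the status was already entered
          (the protocol's "no evaluation" cells),

with cn_i = tn_i + mn_i and dn_i = tn_i + fn_i + sn_i. The per-status
fitness values F_i = (mn_i + fn_i) / 2 drive template training; the
event error rates are E_i = (mn_i + fn_i) / cn_i * 100 and the pooled
E3; the pointwise rate E4 compares per-sample binary statuses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import UndefinedRateError
from .reference import INITIAL_OFF, INITIAL_ON, OFF_GROUND, ON_GROUND, PhaseTrack
from .csm import OFF_START, ON_START

#: per-status matching rules: target window label, "no evaluation" label
#: (already-entered status), and labels where a flag is a false detection
_RULES = {
    OFF_START: dict(target=INITIAL_OFF, noeval=OFF_GROUND, wrong=(ON_GROUND, INITIAL_ON)),
    ON_START: dict(target=INITIAL_ON, noeval=ON_GROUND, wrong=(INITIAL_OFF, OFF_GROUND)),
}


@dataclass(frozen=True)
class EvalCounts:
    """Matching counts per status (suffix 1 = off-ground, 2 = on-ground)."""

    cn1: int = 0
    tn1: int = 0
    mn1: int = 0
    fn1: int = 0
    sn1: int = 0
    cn2: int = 0
    tn2: int = 0
    mn2: int = 0
    fn2: int = 0
    sn2: int = 0

    def __post_init__(self) -> None:
        for name in ("cn1", "tn1", "mn1", "fn1", "sn1", "cn2", "tn2", "mn2", "fn2", "sn2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tn1 != self.cn1 - self.mn1 or self.tn2 != self.cn2 - self.mn2:
            raise ValueError("count invariant tn_i = cn_i - mn_i violated")

    @property
    def dn1(self) -> int:
        return self.tn1 + self.fn1 + self.sn1

    @property
    def dn2(self) -> int:
        return self.tn2 + self.fn2 + self.sn2

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(
            *(getattr(self, f) + getattr(other, f)
              for f in ("cn1", "tn1", "mn1", "fn1", "sn1",
                        "cn2", "tn2", "mn2", "fn2", "sn2"))
        )


@dataclass(frozen=True)
class ErrorReport:
    """Training fitness values and error-rate percentages."""

    F1: float
    F2: float
    E1: float
    E2: float
    E3: float
    E4: float | None = None

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in ("F1", "F2", "E1", "E2", "E3")}
        if self.E4 is not None:
            d["E4"] = self.E4
        return d


def _target_run_ids(labels: np.ndarray, target: int) -> tuple[np.ndarray, int]:
    """Per-sample id of the target-label window containing it (-1 elsewhere)."""
    mask = labels == target
    starts = mask & ~np.concatenate(([False], mask[:-1]))
    rid = np.where(mask, np.cumsum(starts) - 1, -1)
    return rid, int(starts.sum())


def _count_status(
    labels: np.ndarray, flag_idx: np.ndarray, tag: str
) -> dict[str, int]:
    rule = _RULES[tag]
    rid, cn = _target_run_ids(labels, rule["target"])
    fl = labels[flag_idx] if len(flag_idx) else np.empty(0, dtype=np.int64)
    fn = int(np.isin(fl, rule["wrong"]).sum())
    in_target = fl == rule["target"]
    hit_ids = rid[flag_idx[in_target]] if in_target.any() else np.empty(0, dtype=np.int64)
    tn = int(len(np.unique(hit_ids)))
    duplicates = int(in_target.sum()) - tn
    sn = duplicates + int((fl == rule["noeval"]).sum())
    return dict(cn=cn, tn=tn, mn=cn - tn, fn=fn, sn=sn)


def match_detections(
    flags: Iterable[tuple[int, str]], truth: PhaseTrack
) -> EvalCounts:
    """Apply the matching protocol to a sorted flag list.

    ``flags`` is an iterable of (sample_index, flag_type) with flag_type
    one of ``"off_start"`` / ``"on_start"``. The first flag inside a true
    initial window is a correct detection; further same-type flags in
    that window, and flags raised during the already-entered status, are
    over-detections; flags during the opposite half of the cycle are
    false detections; an unmatched true window is a miss.
    """
    labels = truth.labels
    idx = {OFF_START: [], ON_START: []}
    prev = -1
    for i, tag in flags:
        if not (0 <= i < len(labels)):
            raise ValueError(f"flag index {i} out of range")
        if i < prev:
            raise ValueError("flags must be sorted by index")
        prev = i
        if tag not in idx:
            raise ValueError(f"unknown flag type {tag!r}")
        idx[tag].append(i)
    off = _count_status(labels, np.asarray(idx[OFF_START], dtype=np.int64), OFF_START)
    on = _count_status(labels, np.asarray(idx[ON_START], dtype=np.int64), ON_START)
    return EvalCounts(
        cn1=off["cn"], tn1=off["tn"], mn1=off["mn"], fn1=off["fn"], sn1=off["sn"],
        cn2=on["cn"], tn2=on["tn"], mn2=on["mn"], fn2=on["fn"], sn2=on["sn"],
    )


def event_error_rates(counts: EvalCounts) -> tuple[float, float, float, float, float]:
    """(F1, F2, E1, E2, E3): fitness values and event error percentages."""
    f1 = (counts.mn1 + counts.fn1) / 2.0
    f2 = (counts.mn2 + counts.fn2) / 2.0
    if counts.cn1 == 0 or counts.cn2 == 0:
        raise UndefinedRateError("E rates undefined when a true phase count is zero")
    e1 = (counts.mn1 + counts.fn1) / counts.cn1 * 100.0
    e2 = (counts.mn2 + counts.fn2) / counts.cn2 * 100.0
    e3 = (
        (counts.mn1 + counts.fn1 + counts.mn2 + counts.fn2)
        / (counts.cn1 + counts.cn2)
        * 100.0
    )
    return f1, f2, e1, e2, e3


def pointwise_error(
    h: Sequence[int], c: Sequence[int], literal: bool = False
) -> float:
    """Pointwise rate E4 in percent.

    By default this is the per-sample disagreement fraction between the
    detected binary status ``h`` and the reference binary status ``c``
    (the reading consistent with E4 being an error rate and staying
    nonzero even under perfect event detection, because the two
    protocols place the switch instants differently). ``literal=True``
    returns the agreement fraction instead, i.e. the formula as a score
    of matching samples.
    """
    h_arr = np.asarray(h, dtype=np.int64)
    c_arr = np.asarray(c, dtype=np.int64)
    if h_arr.shape != c_arr.shape or h_arr.ndim != 1:
        raise ValueError("h and c must be 1-D vectors of equal length")
    if len(h_arr) == 0:
        raise ValueError("vectors must be non-empty")
    agree = float((h_arr == c_arr).mean())
    return 100.0 * (agree if literal else 1.0 - agree)


def full_report(
    counts: EvalCounts, h: Sequence[int] | None = None, c: Sequence[int] | None = None
) -> ErrorReport:
    """Assemble the complete report; E4 included when h and c are given."""
    f1, f2, e1, e2, e3 = event_error_rates(counts)
    e4 = pointwise_error(h, c) if h is not None and c is not None else None
    return ErrorReport(F1=f1, F2=f2, E1=e1, E2=e2, E3=e3, E4=e4)
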