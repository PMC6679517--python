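"""Curve similarity model: curve construction, Gaussian transform, distance.

A detection window is the last four force samples. It is extended with
all six pairwise lagged differences (the k-scale differences, k = 1..3)
into a 10-element curve

    L = <x1 .. x10>,
    x1 = x(i), x2 = x(i-1), x3 = x(i-2), x4 = x(i-3),
    x5 = x1-x2, x6 = x1-x3, x7 = x1-x4,
    x8 = x2-x3, x9 = x2-x4, x10 = x3-x4.

A status template assigns each element a center mu_j and width delta_j;
the Gaussian transform phi(x_j) = exp(-(x_j - mu_j)^2 / (2 delta_j^2))
maps every element into (0, 1], and the similarity distance to the
template is

    d = P - sum_j phi(x_j),  P = 10,

which is 0 exactly at the template center and approaches P far from it.
A window is classified to the template's status when d <= epsilon; the
preferable threshold satisfies 0 < epsilon / P <= 0.2, i.e. epsilon = 2
for P = 10.

Public interfaces take windows in time order (oldest -> newest) and map
them internally to the newest-first element order above.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationWarning, ModelValidityError

#: number of curve elements (4 samples + 6 lagged differences)
P = 10

#: status tags: the template/flag for entering on-ground resp. off-ground
ON_START = "on_start"
OFF_START = "off_start"
STATUS_TAGS = (ON_START, OFF_START)

DEFAULT_EPSILON = 2.0


def epsilon_upper_bound(p: int = P) -> float:
    """Largest preferable similarity threshold: epsilon / p <= 0.2."""
    return 0.2 * p


def check_epsilon(epsilon: float, p: int = P) -> None:
    """Warn (not fail) when epsilon leaves the preferable (0, 0.2*p] band."""
    if not (0.0 < epsilon <= epsilon_upper_bound(p)):
        warnings.warn(
            f"epsilon = {epsilon} outside the preferable bound "
            f"(0, {epsilon_upper_bound(p)}] for P = {p}",
            ConfigurationWarning,
            stacklevel=3,
        )


def curve_matrix(windows: np.ndarray) -> np.ndarray:
    """Vectorized curve construction for an (m, 4) array of windows.

    Each row is a time-ordered (oldest -> newest) 4-sample window; the
    result rows are the corresponding 10-element curves.
    """
    w = np.asarray(windows, dtype=float)
    if w.ndim != 2 or w.shape[1] != 4:
        raise ValueError("windows must be an (m, 4) array")
    x1, x2, x3, x4 = w[:, 3], w[:, 2], w[:, 1], w[:, 0]
    return np.column_stack(
        (x1, x2, x3, x4, x1 - x2, x1 - x3, x1 - x4, x2 - x3, x2 - x4, x3 - x4)
    )


def build_curve(window: np.ndarray) -> np.ndarray:
    """Extend one time-ordered 4-sample window into its 10-element curve."""
    w = np.asarray(window, dtype=float)
    if w.shape != (4,):
        raise ValueError(f"window must contain exactly 4 values, got shape {w.shape}")
    if not np.isfinite(w).all():
        raise ValueError("window values must be finite")
    return curve_matrix(w[None, :])[0]


@dataclass(frozen=True)
class Template:
    """One status template: per-element Gaussian centers and widths."""

    mu: np.ndarray
    delta: np.ndarray
    status_tag: str

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        delta = np.asarray(self.delta, dtype=float)
        if mu.shape != (P,) or delta.shape != (P,):
            raise ModelValidityError(f"mu and delta must have length {P}")
        if not (np.isfinite(mu).all() and np.isfinite(delta).all()):
            raise ModelValidityError("template parameters must be finite")
        if np.any(delta <= 0):
            raise ModelValidityError("all delta elements must be positive")
        if self.status_tag not in STATUS_TAGS:
            raise ModelValidityError(
                f"status_tag must be one of {STATUS_TAGS}, got {self.status_tag!r}"
            )
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "delta", delta)


def gaussian_transform(curve: np.ndarray, template: Template) -> np.ndarray:
    """Element-wise Gaussian transform phi(x_j); 1 exactly where x_j = mu_j."""
    c = np.asarray(curve, dtype=float)
    if c.shape != (P,):
        raise ValueError(f"curve must have length {P}")
    if not np.isfinite(c).all():
        raise ValueError("curve elements must be finite")
    return np.exp(-((c - template.mu) ** 2) / (2.0 * template.delta**2))


def similarity_distance(curve: np.ndarray, template: Template) -> float:
    """d = P - sum_j phi(x_j); lies in [0, P), 0 iff curve equals mu."""
    return float(P - gaussian_transform(curve, template).sum())


def distance_matrix(curves: np.ndarray, template: Template) -> np.ndarray:
    """Similarity distance of every row of an (m, 10) curve matrix."""
    c = np.asarray(curves, dtype=float)
    z = (c - template.mu) / template.delta
    return P - np.exp(-0.5 * z**2).sum(axis=1)


def is_similar(d: float, epsilon: float = DEFAULT_EPSILON) -> bool:
    """Similarity rule: d <= epsilon (boundary inclusive)."""
    check_epsilon(epsilon)
    return d <= epsilon


@dataclass(frozen=True)
class CSMModel:
    """A trained pair of status templates plus the similarity threshold."""

    on_template: Template
    off_template: Template
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        if self.on_template.status_tag != ON_START:
            raise ModelValidityError("on_template must carry the on_start tag")
        if self.off_template.status_tag != OFF_START:
            raise ModelValidityError("off_template must carry the off_start tag")
        check_epsilon(self.epsilon)

    def to_dict(self) -> dict:
        return {
            "epsilon": float(self.epsilon),
            "on": {
                "mu": [float(v) for v in self.on_template.mu],
                "delta": [float(v) for v in self.on_template.delta],
            },
            "off": {
                "mu": [float(v) for v in self.off_template.mu],
                "delta": [float(v) for v in self.off_template.delta],
            },
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "CSMModel":
        try:
            on = payload["on"]
            off = payload["off"]
            epsilon = float(payload["epsilon"])
            on_t = Template(np.asarray(on["mu"]), np.asarray(on["delta"]), ON_START)
            off_t = Template(np.asarray(off["mu"]), np.asarray(off["delta"]), OFF_START)
        except (KeyError, TypeError) as exc:
            raise ModelValidityError(f"malformed model payload: {exc}") from exc
        return cls(on_template=on_t, off_template=off_t, epsilon=epsilon)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)
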