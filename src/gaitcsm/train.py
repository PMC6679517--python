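"""Evolutionary search for template parameters.

A population of candidate templates (mu, delta per curve element) is
evolved to minimize the detection-error fitness F = (mn + fn) / 2
summed over the labeled training channels. Each generation the combined
parent + offspring population is sorted by fitness; the best PopSize
individuals are graded into four fitness quartiles (kind 1 = best), each
parent of kind k produces k + 1 Gaussian-mutated descendants, and the
best descendant fills the offspring slot. Parents occupy slots
[0, PopSize) and offspring [PopSize, 2*PopSize); elitism makes the
best-so-far fitness non-increasing. The search runs independently for
the off-ground-start and on-ground-start templates.

Note the unusual reproduction grading: WORSE quartiles produce MORE
descendants (kind + 1); ``invert_kind`` flips this so the best quartile
reproduces most.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, TrainingDataError
from .csm import (
    DEFAULT_EPSILON,
    OFF_START,
    ON_START,
    P,
    CSMModel,
    Template,
    curve_matrix,
)
from .evaluate import _RULES, _target_run_ids
from .reference import PhaseTrack

log = logging.getLogger(__name__)

#: a labeled training channel: force vector + its four-phase track
LabeledChannel = tuple[np.ndarray, PhaseTrack]


@dataclass(frozen=True)
class ECConfig:
    """Evolutionary search settings.

    ``mu_init_range`` / ``delta_init_range`` are optional (low, high)
    arrays of shape (10, 2); when omitted they are derived from the
    curve elements observed at the labeled transitions, which keeps the
    search in a data-informed box. ``mutation_scale`` is the mutation
    standard deviation as a fraction of each element's init-range width.
    """

    pop_size: int = 20
    max_gen: int = 200
    seed: int = 0
    mu_init_range: np.ndarray | None = None
    delta_init_range: np.ndarray | None = None
    mutation_scale: float = 0.1
    mutation_decay: float = 0.95
    mutation_floor: float = 0.05
    epsilon: float = DEFAULT_EPSILON
    invert_kind: bool = False
    delta_floor_frac: float = 1e-6
    target_fitness: float | None = None

    def __post_init__(self) -> None:
        if self.pop_size < 4:
            raise ConfigurationError("pop_size must be >= 4 (quartile grading)")
        if self.max_gen < 1:
            raise ConfigurationError("max_gen must be >= 1")
        if self.mutation_scale <= 0:
            raise ConfigurationError("mutation_scale must be positive")


@dataclass
class Individual:
    """One candidate template with its fitness and quartile grade."""

    mu: np.ndarray
    delta: np.ndarray
    fitness: float = np.inf
    kind: int = 0

    def as_template(self, status_tag: str) -> Template:
        return Template(self.mu.copy(), self.delta.copy(), status_tag)


class _FitnessEvaluator:
    """Precomputed curve matrices and window labels for fast fitness calls."""

    def __init__(self, labeled_data: Sequence[LabeledChannel], status_tag: str):
        if status_tag not in (ON_START, OFF_START):
            raise ValueError(f"unknown status_tag {status_tag!r}")
        if not labeled_data:
            raise TrainingDataError("labeled_data must be non-empty")
        rule = _RULES[status_tag]
        self.status_tag = status_tag
        self.wrong = np.asarray(rule["wrong"], dtype=np.int64)
        self.series: list[dict] = []
        n_transitions = 0
        dyn_range = 0.0
        transition_curves = []
        for channel, track in labeled_data:
            x = np.asarray(channel, dtype=float)
            if len(x) != track.n:
                raise ValueError("channel and phase track lengths differ")
            if len(x) < 4:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(x, 4)
            curves = curve_matrix(windows)
            wlabels = track.labels[3:]
            rid_full, _ = _target_run_ids(track.labels, rule["target"])
            rid = rid_full[3:]
            cn = int(len(np.unique(rid[rid >= 0])))
            n_transitions += cn
            dyn_range = max(dyn_range, float(x.max() - x.min()))
            # the starting-flag curve of each transition: the window at the
            # threshold crossing itself (run start for off-ground, run end
            # for on-ground), the most distinctive window of the run
            edges = np.flatnonzero(
                np.diff(
                    np.concatenate(
                        ([0], (wlabels == rule["target"]).astype(np.int64), [0])
                    )
                )
            )
            starts, ends = edges[::2], edges[1::2]
            boundary = starts if status_tag == OFF_START else ends - 1
            transition_curves.append(curves[boundary])
            self.series.append(
                dict(
                    curves=curves,
                    wrong_mask=np.isin(wlabels, self.wrong),
                    rid=rid,
                    cn=cn,
                )
            )
        if n_transitions == 0:
            raise TrainingDataError(
                f"no {status_tag} transitions found in the labeled data"
            )
        self.n_transitions = n_transitions
        self.dyn_range = dyn_range if dyn_range > 0 else 1.0
        self.transition_curves = np.vstack(
            [tc for tc in transition_curves if len(tc)]
        )

    def __call__(self, mu: np.ndarray, delta: np.ndarray, epsilon: float) -> float:
        total = 0.0
        for s in self.series:
            z = (s["curves"] - mu) / delta
            d = P - np.exp(-0.5 * z**2).sum(axis=1)
            fire = d <= epsilon
            # one detected phase entry per contiguous run of firing windows
            starts = fire & ~np.concatenate(([False], fire[:-1]))
            fn = int((starts & s["wrong_mask"]).sum())
            hit = s["rid"][fire]
            tn = int(len(np.unique(hit[hit >= 0])))
            mn = s["cn"] - tn
            total += (mn + fn) / 2.0
        return total


def fitness(
    template: Template,
    labeled_data: Sequence[LabeledChannel],
    status_tag: str | None = None,
    epsilon: float = DEFAULT_EPSILON,
) -> float:
    """Detection-error fitness of a single template over labeled channels.

    Runs the single-template detector (one flag per contiguous run of
    windows with d <= epsilon), matches flags against the reference
    track, and returns the sum over channels of (mn + fn) / 2.
    """
    if status_tag is None:
        status_tag = template.status_tag
    elif status_tag != template.status_tag:
        raise ValueError(
            f"status_tag {status_tag!r} does not match template tag "
            f"{template.status_tag!r}"
        )
    evaluator = _FitnessEvaluator(labeled_data, status_tag)
    return evaluator(template.mu, template.delta, epsilon)


def _init_ranges(
    evaluator: _FitnessEvaluator, config: ECConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-element (low, high) sampling boxes for mu and delta."""
    tc = evaluator.transition_curves
    if config.mu_init_range is not None:
        mu_range = np.asarray(config.mu_init_range, dtype=float)
    else:
        # robust box around the observed starting-flag curves: extreme
        # quantiles so a few mislabeled transitions cannot stretch it
        lo = np.quantile(tc, 0.02, axis=0)
        hi = np.quantile(tc, 0.98, axis=0)
        pad = max(1e-3, 0.02 * evaluator.dyn_range)
        mu_range = np.column_stack((lo - pad, hi + pad))
    delta_floor = config.delta_floor_frac * evaluator.dyn_range
    if config.delta_init_range is not None:
        delta_range = np.asarray(config.delta_init_range, dtype=float)
    else:
        span = mu_range[:, 1] - mu_range[:, 0]
        span = np.maximum(span, 0.01 * evaluator.dyn_range)
        delta_range = np.column_stack((span / 8.0, span))
    mu_sd = config.mutation_scale * (mu_range[:, 1] - mu_range[:, 0])
    mu_sd = np.maximum(mu_sd, 1e-9)
    delta_sd = config.mutation_scale * (delta_range[:, 1] - delta_range[:, 0])
    delta_sd = np.maximum(delta_sd, 1e-9)
    return mu_range, delta_range, mu_sd, delta_sd


def _kind_of_rank(rank: int, pop_size: int) -> int:
    """Quartile grade of a sorted parent: 1 = best quartile .. 4 = worst."""
    return min(3, rank * 4 // pop_size) + 1


def train_template(
    labeled_data: Sequence[LabeledChannel],
    status_tag: str,
    config: ECConfig,
) -> tuple[Template, list[float]]:
    """Evolve one status template; returns it with the best-fitness history.

    Fully reproducible from ``config.seed``; the history is the best
    fitness in the population after each generation and is
    non-increasing (elitist retention). When ``config.target_fitness``
    is set the loop stops early once the best fitness reaches it.
    """
    evaluator = _FitnessEvaluator(labeled_data, status_tag)
    mu_range, delta_range, mu_sd, delta_sd = _init_ranges(evaluator, config)
    delta_floor = config.delta_floor_frac * evaluator.dyn_range
    rng = np.random.default_rng(config.seed)
    psize = config.pop_size

    d_lo = np.maximum(delta_range[:, 0], delta_floor)
    d_hi = np.maximum(delta_range[:, 1], d_lo * (1.0 + 1e-9))

    def sample_individual() -> Individual:
        mu = rng.uniform(mu_range[:, 0], mu_range[:, 1])
        # widths sampled log-uniformly: useful delta scales span decades
        delta = np.exp(rng.uniform(np.log(d_lo), np.log(d_hi)))
        ind = Individual(mu=mu, delta=delta)
        ind.fitness = evaluator(mu, delta, config.epsilon)
        return ind

    def mutate(parent: Individual, anneal: float) -> Individual:
        # additive Gaussian steps for the centers, multiplicative
        # (log-normal) steps for the widths, both annealed over the
        # generations; occasionally a single element is resampled from
        # the init box outright, which lets the search leave basins the
        # local steps cannot
        mu = parent.mu + rng.normal(0.0, anneal * mu_sd)
        delta = parent.delta * np.exp(
            rng.normal(0.0, anneal * 3.0 * config.mutation_scale, P)
        )
        reset = rng.random(P) < 0.05
        if reset.any():
            fresh_mu = rng.uniform(mu_range[:, 0], mu_range[:, 1])
            fresh_delta = np.exp(rng.uniform(np.log(d_lo), np.log(d_hi)))
            mu = np.where(reset, fresh_mu, mu)
            delta = np.where(reset, fresh_delta, delta)
        delta = np.maximum(delta, delta_floor)
        ind = Individual(mu=mu, delta=delta)
        ind.fitness = evaluator(mu, delta, config.epsilon)
        return ind

    pop = [sample_individual() for _ in range(2 * psize)]
    history: list[float] = []
    for gen in range(config.max_gen):
        order = np.argsort([ind.fitness for ind in pop], kind="stable")
        pop = [pop[i] for i in order]
        for rank in range(psize):
            pop[rank].kind = _kind_of_rank(rank, psize)
        anneal = max(config.mutation_decay**gen, config.mutation_floor)
        for j in range(psize):
            kind = pop[j].kind
            n_desc = (5 - kind) + 1 if config.invert_kind else kind + 1
            descendants = [mutate(pop[j], anneal) for _ in range(n_desc)]
            best = min(range(n_desc), key=lambda i: descendants[i].fitness)
            pop[psize + j] = descendants[best]
        best_fit = min(ind.fitness for ind in pop)
        history.append(best_fit)
        log.debug("generation %d: best fitness %.3f", gen + 1, best_fit)
        if config.target_fitness is not None and best_fit <= config.target_fitness:
            break
    order = np.argsort([ind.fitness for ind in pop], kind="stable")
    best_ind = pop[order[0]]
    return best_ind.as_template(status_tag), history


def train_csm(
    labeled_data: Sequence[LabeledChannel], config: ECConfig
) -> tuple[CSMModel, dict[str, list[float]]]:
    """Run the evolutionary search twice (off- then on-ground templates).

    The two runs use config.seed and config.seed + 1 so they draw
    independent random streams while staying reproducible.
    """
    from dataclasses import replace

    off_template, off_hist = train_template(labeled_data, OFF_START, config)
    on_cfg = replace(config, seed=config.seed + 1)
    on_template, on_hist = train_template(labeled_data, ON_START, on_cfg)
    model = CSMModel(
        on_template=on_template, off_template=off_template, epsilon=config.epsilon
    )
    return model, {"off": off_hist, "on": on_hist}


def labeled_channels(
    series_tracks: Sequence[tuple[np.ndarray, PhaseTrack]]
) -> list[LabeledChannel]:
    """Identity helper kept for API symmetry; validates pairing lengths."""
    out = []
    for channel, track in series_tracks:
        if len(channel) != track.n:
            raise ValueError("channel and track lengths differ")
        out.append((np.asarray(channel, dtype=float), track))
    return out
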