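"""Global-threshold reference method and four-phase labeling."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gaitcsm import (
    GCFSeries,
    binarize,
    compute_lopez_threshold,
    label_four_phases,
    moving_average_filter,
)
from gaitcsm.errors import DegenerateSignalError, LabelingError
from gaitcsm.reference import (
    debounce_binary,
    decimate_mean,
    filter_window_for_cutoff,
    lopez_threshold_from_extrema,
)


def _series(ball, heel=None, fs=100.0):
    ball = np.asarray(ball, dtype=float)
    heel = ball.copy() if heel is None else np.asarray(heel, dtype=float)
    t = np.arange(len(ball)) * 1000.0 / fs
    return GCFSeries(t, ball, heel, fs)


def _plateau_signal(levels, samples_per_level=40):
    """Concatenated constant plateaus, each long enough to count as a cycle."""
    return np.concatenate([np.full(samples_per_level, v, dtype=float) for v in levels])


class TestMovingAverage:
    def test_window_one_is_identity(self):
        s = _series([1.0, 5.0, 2.0, 8.0])
        out = moving_average_filter(s, 1)
        assert np.array_equal(out.ball, s.ball)

    def test_constant_series_unchanged(self):
        s = _series(np.full(20, 3.5))
        out = moving_average_filter(s, 5)
        assert np.allclose(out.ball, 3.5)

    def test_centered_mean_with_shrinking_edges(self):
        out = moving_average_filter(_series([0.0, 3.0, 0.0]), 3)
        assert out.ball[1] == 1.0
        assert out.ball[0] == 1.5  # edge window shrinks to 2 samples

    @pytest.mark.parametrize("w", [0, -1, 2, 4])
    def test_even_or_nonpositive_window_rejected(self, w):
        with pytest.raises(ValueError):
            moving_average_filter(_series([1.0, 2.0, 3.0]), w)

    def test_default_window_at_matching_cutoff_is_passthrough(self):
        assert filter_window_for_cutoff(100.0, 100.0) == 1

    def test_decimate_mean_blocks(self):
        s = _series(np.arange(8, dtype=float), fs=200.0)
        out = decimate_mean(s, 2)
        assert np.allclose(out.ball, [0.5, 2.5, 4.5, 6.5])
        assert out.sample_rate_hz == 100.0


class TestLopezThreshold:
    def test_hand_evaluated_extrema_means(self):
        m = lopez_threshold_from_extrema([100.0, 100.0], [0.0, 0.0], alpha=0.094)
        assert m.thr == pytest.approx(9.4)
        m = lopez_threshold_from_extrema([80.0, 120.0], [0.0, 20.0], alpha=0.5)
        assert m.thr == pytest.approx(55.0)

    def test_alpha_endpoints(self):
        assert lopez_threshold_from_extrema([10.0], [2.0], alpha=0.0).thr == 2.0
        assert lopez_threshold_from_extrema([10.0], [2.0], alpha=1.0).thr == 10.0

    def test_threshold_from_plateau_channel(self):
        x = _plateau_signal([80, 0, 120, 20])
        m = compute_lopez_threshold(x, alpha=0.5, sample_rate_hz=100.0)
        assert m.t_max_mean == pytest.approx(100.0)
        assert m.t_min_mean == pytest.approx(10.0)
        assert m.thr == pytest.approx(55.0)

    def test_monotone_in_alpha(self):
        x = _plateau_signal([100, 0, 100, 0])
        thrs = [
            compute_lopez_threshold(x, alpha=a, sample_rate_hz=100.0).thr
            for a in (0.0, 0.094, 0.5, 1.0)
        ]
        assert np.all(np.diff(thrs) >= 0)

    def test_flat_signal_rejected(self):
        with pytest.raises(DegenerateSignalError):
            compute_lopez_threshold(np.full(500, 5.0), sample_rate_hz=100.0)

    def test_isolated_spike_does_not_skew_extrema(self):
        x = _plateau_signal([100, 0, 100, 0])
        x[60] = -500.0  # single-sample artifact in a swing plateau
        m = compute_lopez_threshold(x, alpha=0.094, sample_rate_hz=100.0)
        assert m.t_min_mean == pytest.approx(0.0)
        assert m.thr == pytest.approx(9.4)


class TestBinarize:
    def test_boundary_is_inclusive(self):
        assert binarize(np.array([5.0, 10.0, 9.4]), 9.4).tolist() == [0, 1, 1]

    def test_all_below_gives_zeros(self):
        assert binarize(np.array([1.0, 2.0]), 5.0).tolist() == [0, 0]

    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_strictly_increasing_transform(self, seed):
        r = np.random.default_rng(seed)
        x = r.normal(size=50)
        thr = float(r.normal())
        f = lambda v: np.expm1(v) + 2.0 * v  # strictly increasing
        assert np.array_equal(binarize(x, thr), binarize(f(x), float(f(np.array([thr]))[0])))


def _square_wave(n_cycles=5, on=30, off=30, high=100.0):
    x = np.tile(np.concatenate([np.full(on, high), np.zeros(off)]), n_cycles)
    return x


class TestFourPhaseLabeling:
    def test_square_wave_window_lengths(self):
        x = _square_wave()
        track = label_four_phases(x, thr=9.4, t_w_ms=50.0, sample_rate_hz=100.0)
        labels = track.labels
        for lab in (1, 2):
            runs = np.diff(
                np.flatnonzero(
                    np.diff(np.concatenate(([0], (labels == lab).astype(int), [0])))
                )
            )[::2]
            assert np.all(runs == 5), f"label {lab} runs {runs}"

    def test_label_cycle_order(self):
        x = _square_wave()
        labels = label_four_phases(x, 9.4, 50.0, 100.0).labels
        compressed = labels[np.concatenate(([True], np.diff(labels) != 0))]
        order = "3102"
        text = "".join(map(str, compressed))
        assert text in (order * 10)

    def test_initial_on_window_ends_at_crossing(self):
        x = _square_wave()
        track = label_four_phases(x, 9.4, 50.0, 100.0)
        labels, b = track.labels, binarize(x, 9.4)
        ends = np.flatnonzero((labels == 2) & (np.diff(np.concatenate((labels, [3]))) != 0))
        for j in ends:
            assert b[j] == 1  # ending position is the first above-threshold sample
            assert labels[j + 1] == 3

    def test_no_crossing_gives_single_label(self):
        track = label_four_phases(np.full(50, 100.0), 9.4, 50.0, 100.0)
        assert np.all(track.labels == 3)

    def test_overlapping_windows_rejected_with_cycle_index(self):
        # off-ground period of 6 samples cannot hold two 5-sample windows
        x = np.concatenate([np.full(50, 100.0), np.zeros(6), np.full(50, 100.0)])
        with pytest.raises(LabelingError, match="cycle 0"):
            label_four_phases(x, 9.4, 50.0, 100.0)

    def test_binary_mapping_agrees_with_plain_labels(self, labeled_noisy_walk):
        _, _, tracks = labeled_noisy_walk
        for track in tracks.values():
            assert np.all(track.binary[track.labels == 3] == 1)
            assert np.all(track.binary[track.labels == 0] == 0)
            assert np.all(track.binary[track.labels == 2] == 1)
            assert np.all(track.binary[track.labels == 1] == 0)

    def test_debounce_removes_short_runs(self):
        b = np.array([1, 1, 1, 0, 1, 1, 1, 0, 0, 0, 1, 0, 0, 0])
        out = debounce_binary(b, 3)
        assert out.tolist() == [1, 1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
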