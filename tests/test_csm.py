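"""Curve construction, Gaussian transform, similarity distance, fixtures."""

import json

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gaitcsm import (
    Template,
    build_curve,
    gaussian_transform,
    is_similar,
    load_example_model,
    similarity_distance,
)
from gaitcsm.csm import OFF_START, ON_START, P, CSMModel, distance_matrix
from gaitcsm.errors import ConfigurationWarning, ModelValidityError
from gaitcsm.io import load_model, save_model

HALF_WIDTH = np.sqrt(2.0 * np.log(2.0))  # offset where the Gaussian halves


def _random_template(rng, tag=ON_START):
    return Template(rng.normal(size=P), np.abs(rng.normal(size=P)) + 0.1, tag)


def naive_distance(curve, template):
    """Definitional oracle: elementwise |phi(mu) - phi(x)| summed."""
    total = 0.0
    for x, m, d in zip(curve, template.mu, template.delta):
        phi_ref = np.exp(-((m - m) ** 2) / (2 * d**2))
        phi_x = np.exp(-((x - m) ** 2) / (2 * d**2))
        total += abs(phi_ref - phi_x)
    return total


class TestBuildCurve:
    def test_zero_window_gives_zero_vector(self):
        assert np.array_equal(build_curve([0.0, 0.0, 0.0, 0.0]), np.zeros(10))

    def test_hand_substitution(self):
        expected = [40, 30, 20, 10, 10, 20, 30, 10, 20, 10]
        assert np.array_equal(build_curve([10.0, 20.0, 30.0, 40.0]), expected)

    @pytest.mark.parametrize("window", [[1.0, 2.0, 3.0], [1.0] * 5, []])
    def test_wrong_length_rejected(self, window):
        with pytest.raises(ValueError):
            build_curve(window)

    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=4, max_size=4),
        st.floats(-100.0, 100.0),
    )
    def test_linearity_in_scaling(self, window, c):
        w = np.asarray(window)
        # cancellation error scales with the window magnitude, not the result
        tol = 1e-12 * (1.0 + abs(c) * float(np.max(np.abs(w))))
        assert np.allclose(build_curve(c * w), c * build_curve(w), rtol=1e-12, atol=tol)

    def test_difference_elements_are_exact(self, rng):
        w = rng.normal(size=4)
        x = build_curve(w)
        assert x[4] == x[0] - x[1]
        assert x[5] == x[0] - x[2]
        assert x[6] == x[0] - x[3]
        assert x[7] == x[1] - x[2]
        assert x[8] == x[1] - x[3]
        assert x[9] == x[2] - x[3]


class TestGaussianTransform:
    def test_at_center_all_ones(self, rng):
        t = _random_template(rng)
        assert np.allclose(gaussian_transform(t.mu, t), 1.0)

    def test_half_width_offset_gives_half(self, rng):
        t = _random_template(rng)
        phi = gaussian_transform(t.mu + HALF_WIDTH * t.delta, t)
        assert np.allclose(phi, 0.5)

    def test_monotone_decay_from_center(self, rng):
        t = _random_template(rng)
        offsets = np.linspace(0, 5, 20)
        values = [gaussian_transform(t.mu + o * t.delta, t)[3] for o in offsets]
        assert np.all(np.diff(values) < 0)

    def test_nonpositive_delta_rejected(self):
        with pytest.raises(ModelValidityError):
            Template(np.zeros(P), np.zeros(P), ON_START)


class TestSimilarityDistance:
    def test_self_distance_is_zero(self, example_model):
        for t in (example_model.on_template, example_model.off_template):
            assert similarity_distance(t.mu, t) == 0.0

    def test_half_width_offset_gives_five(self, rng):
        t = _random_template(rng)
        assert similarity_distance(t.mu + HALF_WIDTH * t.delta, t) == pytest.approx(5.0)

    def test_closed_form_equals_definitional_oracle(self, rng, example_model):
        t = example_model.on_template
        for _ in range(1000):
            curve = rng.normal(scale=200.0, size=P)
            d = similarity_distance(curve, t)
            assert abs(d - naive_distance(curve, t)) <= 1e-12 * max(1.0, d)

    def test_range_bounds(self, rng):
        t = _random_template(rng)
        for _ in range(200):
            # far curves can reach exactly 10.0 in floats (phi underflows)
            d = similarity_distance(rng.normal(scale=50.0, size=P), t)
            assert 0.0 <= d <= 10.0
        for _ in range(200):
            curve = t.mu + rng.normal(scale=2.0, size=P) * t.delta
            assert 0.0 <= similarity_distance(curve, t) < 10.0

    def test_coordinate_monotonicity(self, rng):
        t = _random_template(rng)
        base = t.mu.copy()
        for j in range(P):
            prev = similarity_distance(base, t)
            for step in (0.5, 1.0, 3.0, 10.0):
                moved = base.copy()
                moved[j] += step * t.delta[j]
                d = similarity_distance(moved, t)
                assert d >= prev - 1e-12
                prev = d

    def test_nonfinite_curve_rejected(self, example_model):
        bad = np.full(P, np.nan)
        with pytest.raises(ValueError):
            similarity_distance(bad, example_model.on_template)

    def test_distance_matrix_matches_scalar_calls(self, rng, example_model):
        curves = rng.normal(scale=100.0, size=(50, P))
        t = example_model.off_template
        batch = distance_matrix(curves, t)
        single = [similarity_distance(c, t) for c in curves]
        assert np.allclose(batch, single, rtol=1e-12)


class TestSimilarityRule:
    def test_boundary_inclusive(self):
        assert is_similar(0.0, 2.0)
        assert is_similar(2.0, 2.0)
        assert not is_similar(10.0, 2.0)

    def test_epsilon_outside_preferable_band_warns(self):
        with pytest.warns(ConfigurationWarning):
            is_similar(1.0, 5.0)


class TestShippedModel:
    def test_loads_and_validates(self, example_model):
        for t in (example_model.on_template, example_model.off_template):
            assert np.all(t.delta > 0)
            assert t.mu.shape == (P,)
        assert example_model.epsilon == 2.0

    def test_serialization_roundtrip_is_byte_identical(self, example_model, tmp_path):
        p1, p2 = tmp_path / "m1.json", tmp_path / "m2.json"
        save_model(example_model, p1)
        save_model(load_model(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_full_precision_roundtrip(self, example_model, tmp_path):
        p = tmp_path / "m.json"
        save_model(example_model, p)
        loaded = load_model(p)
        assert np.array_equal(loaded.on_template.mu, example_model.on_template.mu)
        assert np.array_equal(loaded.off_template.delta, example_model.off_template.delta)

    def test_wrong_vector_length_rejected(self):
        payload = {
            "epsilon": 2.0,
            "on": {"mu": [0.0] * 9, "delta": [1.0] * 9},
            "off": {"mu": [0.0] * 10, "delta": [1.0] * 10},
        }
        with pytest.raises(ModelValidityError):
            CSMModel.from_dict(payload)
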