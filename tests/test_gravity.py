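"""Gravity estimation and scalar projection: hand-computed cases and the
rotation-invariance property that motivates the whole preprocessing step."""

import numpy as np
import pytest

import gaitid as g
from gaitid.errors import (
    AlignmentError,
    DegenerateGravityError,
    InsufficientDataError,
    UsageError,
)

from conftest import make_series


class TestSlidingMeans:
    def test_hand_average_center(self):
        series = make_series([(1, 0, 0), (0, 1, 0), (1, 0, 0)])
        track = g.sliding_mean_vectors(series, 1)
        assert np.allclose(track.means[1], (2 / 3, 1 / 3, 0))

    def test_hand_average_truncated_edge(self):
        series = make_series([(1, 0, 0), (0, 1, 0), (1, 0, 0)])
        track = g.sliding_mean_vectors(series, 1)
        assert np.allclose(track.means[0], (0.5, 0.5, 0))

    @pytest.mark.parametrize("m", [1, 5, 200])
    def test_constant_series_any_window(self, m):
        series = make_series([(0, 0, 9.81)] * 50)
        track = g.sliding_mean_vectors(series, m)
        assert np.allclose(track.means, (0, 0, 9.81))
        assert len(track) == 50

    def test_matches_bruteforce_loop(self, rng):
        samples = rng.normal(size=(40, 3))
        series = make_series(samples)
        m = 4
        track = g.sliding_mean_vectors(series, m)
        for i in range(40):
            lo, hi = max(0, i - m), min(39, i + m)
            assert np.allclose(track.means[i], samples[lo : hi + 1].mean(axis=0))

    def test_empty_series_rejected(self):
        empty = g.TriaxialSeries("s0", "accelerometer", 50.0,
                                 np.empty(0), np.empty((0, 3)))
        with pytest.raises(InsufficientDataError):
            g.sliding_mean_vectors(empty, 1)


class TestUnitGravity:
    def test_axis_aligned(self):
        track = g.MeanVectorTrack(np.array([[0.0, 0.0, 9.81]]), 1)
        assert np.allclose(g.to_unit_gravity(track).unit_vectors, [[0, 0, 1]])

    def test_three_four_five(self):
        track = g.MeanVectorTrack(np.array([[3.0, 4.0, 0.0]]), 1)
        assert np.allclose(g.to_unit_gravity(track).unit_vectors, [[0.6, 0.8, 0]])

    def test_zero_mean_is_degenerate(self):
        track = g.MeanVectorTrack(np.array([[1.0, 0, 0], [0.0, 0, 0]]), 1)
        with pytest.raises(DegenerateGravityError) as err:
            g.to_unit_gravity(track)
        assert err.value.index == 1

    def test_unit_norm_on_random_tracks(self, rng):
        means = rng.normal(size=(200, 3)) + [0, 0, 9.81]
        track = g.to_unit_gravity(g.MeanVectorTrack(means, 1))
        assert np.allclose(np.linalg.norm(track.unit_vectors, axis=1), 1.0,
                           atol=1e-9)


class TestProjection:
    def test_aligned_acceleration(self):
        series = make_series([(0, 0, 9.81)])
        gravity = g.GravityTrack(np.array([[0.0, 0.0, 1.0]]), 1)
        out = g.project_vertical_acceleration(series, gravity)
        assert out.values[0] == pytest.approx(9.81)
        assert out.quantity == "vertical_acceleration"

    def test_hand_dot_product(self):
        series = make_series([(1, 0, 0)])
        ghat = np.array([[2.0, 1.0, 0.0]]) / np.sqrt(5)
        out = g.project_vertical_acceleration(series, g.GravityTrack(ghat, 1))
        assert out.values[0] == pytest.approx(2 / np.sqrt(5))

    def test_gyro_projection_aligned_and_orthogonal(self):
        gyro = make_series([(0, 0, 0.5), (1, 1, 0)], sensor="gyroscope")
        gravity = g.GravityTrack(np.array([[0.0, 0, 1], [0.0, 0, 1]]), 1)
        out = g.project_vertical_rotation(gyro, gravity)
        assert out.values == pytest.approx([0.5, 0.0])
        assert out.quantity == "vertical_rotation"

    def test_gyro_gravity_must_come_from_accelerometer(self):
        gyro = make_series([(0, 0, 0.5)], sensor="gyroscope")
        gravity = g.GravityTrack(np.array([[0.0, 0, 1]]), 1,
                                 source_sensor="gyroscope")
        with pytest.raises(UsageError):
            g.project_vertical_rotation(gyro, gravity)

    def test_length_mismatch(self):
        series = make_series([(0, 0, 9.81)] * 3)
        gravity = g.GravityTrack(np.array([[0.0, 0, 1]]), 1)
        with pytest.raises(AlignmentError):
            g.project_vertical_acceleration(series, gravity)

    def test_mean_projected_onto_own_gravity_gives_norm(self, rng):
        # the windowed mean dotted with its own unit vector is its norm
        samples = rng.normal(size=(60, 3)) + [0, 0, 9.81]
        series = make_series(samples)
        track = g.sliding_mean_vectors(series, 5)
        gravity = g.to_unit_gravity(track)
        projected = np.einsum("ij,ij->i", track.means, gravity.unit_vectors)
        assert np.allclose(projected, np.linalg.norm(track.means, axis=1),
                           atol=1e-9)


class TestTrim:
    def test_slicing(self):
        series = g.ScalarSeries(np.arange(10.0), "vertical_acceleration", "s0", 50.0)
        out = g.trim_edges(series, 2)
        assert np.array_equal(out.values, np.arange(2.0, 8.0))
        assert out.subject_id == "s0"

    def test_zero_trim_is_identity(self):
        series = g.ScalarSeries(np.arange(10.0), "vertical_acceleration", "s0", 50.0)
        assert np.array_equal(g.trim_edges(series, 0).values, series.values)

    def test_over_trim_rejected(self):
        series = g.ScalarSeries(np.arange(10.0), "vertical_acceleration", "s0", 50.0)
        with pytest.raises(InsufficientDataError):
            g.trim_edges(series, 5)


def rotate(series, R):
    return g.TriaxialSeries(series.subject_id, series.sensor,
                            series.sampling_rate_hz, series.timestamps,
                            series.samples @ R.T)


class TestOrientationInvariance:
    def test_constant_signal_closed_form(self, rng):
        # constant acceleration c·v̂ projects to exactly c for any direction
        for _ in range(10):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            c = rng.uniform(1.0, 20.0)
            series = make_series(np.tile(c * v, (30, 1)))
            out = g.vertical_acceleration_pipeline(series, half_window_m=3,
                                                   trim_samples=2)
            assert np.allclose(out.values, c, atol=1e-9)

    def test_acceleration_pipeline_rotation_invariant(self, rng):
        samples = rng.normal(scale=2.0, size=(400, 3)) + [0, 0, 9.81]
        series = make_series(samples)
        base = g.vertical_acceleration_pipeline(series, half_window_m=20,
                                                trim_samples=20)
        for _ in range(30):
            R = g.random_rotation(rng)
            rotated = g.vertical_acceleration_pipeline(rotate(series, R),
                                                       half_window_m=20,
                                                       trim_samples=20)
            assert np.allclose(rotated.values, base.values, atol=1e-9)

    def test_rotation_pipeline_rotation_invariant(self, rng):
        acc = make_series(rng.normal(scale=2.0, size=(400, 3)) + [0, 0, 9.81])
        gyro = make_series(rng.normal(scale=1.0, size=(400, 3)),
                           sensor="gyroscope")
        base = g.vertical_rotation_pipeline(acc, gyro, half_window_m=20,
                                            trim_samples=20)
        for _ in range(30):
            R = g.random_rotation(rng)
            rotated = g.vertical_rotation_pipeline(rotate(acc, R),
                                                   rotate(gyro, R),
                                                   half_window_m=20,
                                                   trim_samples=20)
            assert np.allclose(rotated.values, base.values, atol=1e-9)
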