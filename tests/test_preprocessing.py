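"""Standardization, windowing and envelope emulation contracts."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gesturekit as gk
from gesturekit.preprocessing import WindowBatch


def brute_force_starts(n_samples: int, window_len: int, stride: int) -> list[int]:
    """Independent enumeration oracle for admissible window starts."""
    return [s for s in range(0, n_samples + 1, stride) if s + window_len <= n_samples]


class TestScaler:
    def test_two_point_channel(self):
        """x = [0, 2] -> mu 1, sigma 1 (population), z = [-1, +1]."""
        params = gk.fit_scaler(np.array([[0.0], [2.0]]))
        assert params.mean[0] == 1.0
        assert params.std[0] == 1.0
        np.testing.assert_array_equal(
            gk.apply_scaler(np.array([[0.0], [2.0]]), params), [[-1.0], [1.0]]
        )

    def test_formula_arithmetic(self):
        params = gk.ScalerParams(mean=np.array([1.0]), std=np.array([2.0]))
        assert gk.apply_scaler(np.array([[5.0]]), params)[0, 0] == 2.0
        assert gk.apply_scaler(np.array([[1.0]]), params)[0, 0] == 0.0

    def test_self_standardization_is_exact(self, small_dataset):
        data = np.concatenate([r.samples for r in small_dataset.recordings])
        params = gk.fit_scaler(data)
        z = gk.apply_scaler(data, params)
        assert np.abs(z.mean(axis=0)).max() <= 1e-9
        assert np.abs(z.std(axis=0, ddof=0) - 1.0).max() <= 1e-9

    def test_refit_on_standardized_data_is_identity(self, small_dataset):
        data = np.concatenate([r.samples for r in small_dataset.recordings])
        z = gk.apply_scaler(data, gk.fit_scaler(data))
        z2 = gk.apply_scaler(z, gk.fit_scaler(z))
        np.testing.assert_allclose(z2, z, atol=1e-9)

    def test_constant_channel_flagged_and_zeroed(self):
        data = np.column_stack([np.full(10, 3.0), np.arange(10.0)])
        params = gk.fit_scaler(data)
        assert params.degenerate.tolist() == [True, False]
        z = gk.apply_scaler(data, params)
        np.testing.assert_array_equal(z[:, 0], 0.0)

    def test_inverse_round_trip(self):
        rng = np.random.default_rng(1)
        data = rng.normal(3, 2, size=(50, 4))
        params = gk.fit_scaler(data)
        np.testing.assert_allclose(
            params.inverse_transform(gk.apply_scaler(data, params)), data, atol=1e-9
        )

    def test_transform_never_mutates_params(self):
        params = gk.fit_scaler(np.arange(20.0).reshape(10, 2))
        mean, std = params.mean.copy(), params.std.copy()
        gk.apply_scaler(np.random.default_rng(0).normal(size=(7, 2)), params)
        np.testing.assert_array_equal(params.mean, mean)
        np.testing.assert_array_equal(params.std, std)

    def test_empty_input_rejected(self):
        with pytest.raises(gk.InvalidArgumentError):
            gk.fit_scaler([])

    def test_channel_mismatch_rejected(self):
        params = gk.fit_scaler(np.zeros((5, 3)) + np.arange(5)[:, None])
        with pytest.raises(gk.ShapeError):
            gk.apply_scaler(np.zeros((5, 4)), params)


class TestWindowing:
    @pytest.mark.parametrize(
        "n_samples,expected",
        [(64, 3), (32, 1), (31, 0), (100, 5)],
    )
    def test_printed_geometry(self, n_samples, expected):
        """32-sample windows at 50% overlap: stride 16."""
        batch = gk.segment_windows(np.zeros((n_samples, 4)), gk.WindowingConfig())
        assert len(batch) == expected

    def test_window_contents_match_starts(self):
        x = np.arange(64 * 2, dtype=float).reshape(64, 2)
        batch = gk.segment_windows(x, gk.WindowingConfig())
        for i, start in enumerate([0, 16, 32]):
            np.testing.assert_array_equal(batch.windows[i], x[start : start + 32].T)

    @settings(max_examples=200, deadline=None)
    @given(
        n_samples=st.integers(0, 400),
        window_len=st.integers(1, 64),
        overlap=st.floats(0.0, 0.95),
    )
    def test_window_count_matches_enumeration_oracle(self, n_samples, window_len, overlap):
        stride = int(round(window_len * (1.0 - overlap)))
        if stride < 1:
            return
        cfg = gk.WindowingConfig(window_len=window_len, overlap_fraction=overlap)
        batch = gk.segment_windows(np.zeros((n_samples, 2)), cfg)
        assert len(batch) == len(brute_force_starts(n_samples, window_len, stride))

    def test_majority_label_with_center_tie_break(self):
        labels = np.array([0] * 16 + [1] * 16)
        batch = gk.segment_windows(
            np.zeros((32, 1)), gk.WindowingConfig(), sample_labels=labels
        )
        assert batch.labels[0] == labels[16]  # tie -> center sample's label

    def test_no_window_spans_recording_boundary(self, small_dataset, class_map):
        """Windowing recordings separately never mixes two recordings."""
        recs = small_dataset.recordings[:2]
        batch = gk.batch_from_recordings(recs, class_map)
        per_rec = [gk.segment_windows(r.samples, label=class_map[r.gesture_id]) for r in recs]
        assert len(batch) == sum(len(b) for b in per_rec)
        joined = np.concatenate([r.samples for r in recs])
        spanning = gk.segment_windows(joined)
        assert len(spanning) > len(batch)  # the boundary windows were dropped


class TestEnvelopeFromRaw:
    def test_zero_input_gives_zero_envelope(self):
        raw = gk.Recording(np.zeros((1000, 2)), sampling_rate=500.0)
        env = gk.envelope_from_raw(raw)
        np.testing.assert_array_equal(env.samples, 0.0)
        assert env.sampling_rate == 50.0

    def test_dc_step_converges_to_input_level(self):
        """First-order low-pass has unit DC gain: constant +a in -> a out."""
        a = 3.5
        raw = gk.Recording(np.full((5000, 1), a), sampling_rate=1000.0)
        env = gk.envelope_from_raw(raw)
        assert abs(env.samples[-1, 0] - a) < 0.01 * a

    def test_output_nonnegative_for_signed_input(self):
        rng = np.random.default_rng(2)
        raw = gk.Recording(rng.normal(0, 2, size=(2000, 3)), sampling_rate=1000.0)
        env = gk.envelope_from_raw(raw)
        assert env.samples.min() >= 0.0

    def test_cutoff_above_target_nyquist_rejected(self):
        raw = gk.Recording(np.zeros((100, 1)), sampling_rate=1000.0)
        with pytest.raises(gk.InvalidArgumentError):
            gk.envelope_from_raw(raw, lowpass_cutoff=30.0, target_rate=50.0)

    def test_low_raw_rate_rejected(self):
        raw = gk.Recording(np.zeros((100, 1)), sampling_rate=5.0)
        with pytest.raises(gk.InvalidArgumentError):
            gk.envelope_from_raw(raw, lowpass_cutoff=3.6)


def test_window_batch_shape_validation():
    with pytest.raises(gk.ShapeError):
        WindowBatch(windows=np.zeros((3, 4)), labels=np.zeros(3))
    with pytest.raises(gk.ShapeError):
        WindowBatch(windows=np.zeros((3, 4, 32)), labels=np.zeros(2))
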