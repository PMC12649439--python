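"""Synthetic sEMG generator: gain formula, banks, phenotypes, invariants."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import gesturekit as gk
from gesturekit.synth import ChannelProfile, GestureTemplate


@pytest.mark.parametrize(
    "r_kohm,expected",
    [(1.0, 200.0), (0.0, 0.0), (2.5, 500.0)],
)
def test_sensor_gain_is_linear_in_resistance(r_kohm, expected):
    assert gk.sensor_gain(r_kohm) == expected


def test_sensor_gain_rejects_negative_resistance():
    with pytest.raises(gk.InvalidArgumentError):
        gk.sensor_gain(-0.1)


class TestGestureBank:
    def test_ten_gestures_pairwise_distinct(self):
        bank = gk.make_gesture_bank(10, 4, seed=7)
        assert len(bank) == 10
        keys = {
            tuple(
                (p.onset_fraction, p.duration_fraction, p.peak_amplitude, p.shape)
                for p in t.profiles
            )
            for t in bank
        }
        assert len(keys) == 10

    def test_single_gesture_bank(self):
        bank = gk.make_gesture_bank(1, 4, seed=0)
        assert len(bank) == 1
        assert bank[0].n_channels == 4

    def test_seeded_determinism(self):
        a = gk.make_gesture_bank(5, 4, seed=42)
        b = gk.make_gesture_bank(5, 4, seed=42)
        assert a == b

    def test_amplitudes_within_physiological_range(self):
        for t in gk.make_gesture_bank(15, 4, seed=1):
            for p in t.profiles:
                assert 0.0 <= p.peak_amplitude <= 10.0

    def test_rejects_empty_bank_request(self):
        with pytest.raises(gk.InvalidArgumentError):
            gk.make_gesture_bank(0)


class TestPhenotypes:
    def test_zero_variability_yields_identical_identity_phenotypes(self):
        phen = gk.sample_phenotypes(5, 0.0, seed=3)
        assert len(phen) == 5
        for p in phen:
            np.testing.assert_allclose(p.gains, 1.0)
            np.testing.assert_allclose(p.channel_mixing, np.eye(4))
            assert p.timing_jitter_sd == 0.0
            assert p.timing_offset_s == 0.0
            assert p.drift_amplitude == 0.0
            assert p.noise_sd == phen[0].noise_sd

    @pytest.mark.parametrize("seed", range(5))
    def test_positive_variability_separates_users(self, seed):
        phen = gk.sample_phenotypes(5, 1.0, seed=seed)
        dists = [
            np.linalg.norm(a.gains - b.gains)
            + np.linalg.norm(a.channel_mixing - b.channel_mixing)
            for i, a in enumerate(phen)
            for b in phen[i + 1 :]
        ]
        assert min(dists) > 0

    def test_single_user_cohort(self):
        assert len(gk.sample_phenotypes(1, 2.0, seed=0)) == 1

    def test_mixing_rows_are_stochastic(self):
        for p in gk.sample_phenotypes(8, 2.5, seed=9):
            assert np.all(p.channel_mixing >= 0)
            np.testing.assert_allclose(p.channel_mixing.sum(axis=1), 1.0, atol=1e-9)

    def test_dispersion_scales_with_variability_level(self):
        def spread(v):
            gains = np.array([p.gains for p in gk.sample_phenotypes(20, v, seed=4)])
            return gains.std()

        assert spread(0.0) == 0.0
        assert spread(0.5) < spread(2.0)


class TestRepetition:
    def test_identity_phenotype_reproduces_template_exactly(self, bank3):
        phen = gk.sample_phenotypes(1, 0.0, seed=0)[0]
        phen = dataclasses.replace(phen, noise_sd=0.0)
        cfg = gk.SimConfig(repetition_duration=2.0, variability_level=0.0, rng_seed=0)
        rec = gk.synthesize_repetition(bank3[0], phen, cfg)
        expected = bank3[0].render(100, 2.0).T
        np.testing.assert_array_equal(rec.samples, expected)

    def test_sample_count_follows_duration_and_rate(self, bank3):
        phen = gk.sample_phenotypes(1, 1.0, seed=0)[0]
        cfg = gk.SimConfig(repetition_duration=2.0, rng_seed=0)
        rec = gk.synthesize_repetition(bank3[0], phen, cfg)
        assert rec.samples.shape == (100, 4)  # round(2 s * 50 Hz)

    @pytest.mark.parametrize("seed", range(3))
    def test_envelope_nonnegativity(self, bank3, seed):
        phen = gk.sample_phenotypes(1, 2.5, seed=seed)[0]
        cfg = gk.SimConfig(repetition_duration=2.0, variability_level=2.5, rng_seed=seed)
        rec = gk.synthesize_repetition(bank3[1], phen, cfg)
        assert rec.samples.min() >= 0.0

    def test_channel_mismatch_raises_shape_error(self, bank3):
        phen = gk.sample_phenotypes(1, 1.0, seed=0, n_channels=3)[0]
        with pytest.raises(gk.ShapeError):
            gk.synthesize_repetition(bank3[0], phen, gk.SimConfig())


class TestDataset:
    def test_live_protocol_shape(self, bank3):
        """7 users x 3 gestures x 5 reps = 105 recordings."""
        phen = gk.sample_phenotypes(7, 1.0, seed=1)
        ds = gk.synthesize_dataset(bank3, phen, 5, gk.SimConfig(rng_seed=2))
        assert len(ds) == 105
        assert all(r.gesture_id in {t.gesture_id for t in bank3} for r in ds.recordings)

    def test_minimal_dataset(self, bank3):
        phen = gk.sample_phenotypes(1, 1.0, seed=1)
        ds = gk.synthesize_dataset(bank3[:1], phen, 1, gk.SimConfig(rng_seed=2))
        assert len(ds) == 1

    def test_seeded_determinism(self, bank3):
        phen = gk.sample_phenotypes(2, 1.5, seed=1)
        cfg = gk.SimConfig(rng_seed=9, variability_level=1.5)
        a = gk.synthesize_dataset(bank3, phen, 2, cfg)
        b = gk.synthesize_dataset(bank3, phen, 2, cfg)
        for ra, rb in zip(a.recordings, b.recordings):
            np.testing.assert_array_equal(ra.samples, rb.samples)

    def test_empty_bank_rejected(self):
        with pytest.raises(gk.InvalidArgumentError):
            gk.synthesize_dataset([], gk.sample_phenotypes(1, 0.0, seed=0), 1, gk.SimConfig())

    def test_zero_variability_zero_noise_recordings_identical_across_users(self, bank3):
        phen = [
            dataclasses.replace(p, noise_sd=0.0)
            for p in gk.sample_phenotypes(3, 0.0, seed=4)
        ]
        cfg = gk.SimConfig(variability_level=0.0, rng_seed=5)
        ds = gk.synthesize_dataset(bank3[:1], phen, 1, cfg)
        ref = ds.recordings[0].samples
        for rec in ds.recordings[1:]:
            np.testing.assert_array_equal(rec.samples, ref)

    @pytest.mark.parametrize("levels", [(0.5, 2.0)])
    def test_variability_increases_between_user_distance(self, bank3, levels):
        """Mean pairwise distance between users' mean per-gesture signals
        grows with the variability level (averaged over 5 seeds)."""

        def cohort_distance(v, seed):
            phen = gk.sample_phenotypes(3, v, seed=seed)
            cfg = gk.SimConfig(variability_level=v, rng_seed=seed)
            ds = gk.synthesize_dataset(bank3, phen, 3, cfg)
            means = {}
            for rec in ds.recordings:
                means.setdefault((rec.user_id, rec.gesture_id), []).append(rec.samples)
            mean_sig = {k: np.mean(v_, axis=0) for k, v_ in means.items()}
            users = sorted({u for u, _ in mean_sig})
            dists = []
            for gid in {g for _, g in mean_sig}:
                for i, a in enumerate(users):
                    for b in users[i + 1 :]:
                        dists.append(np.linalg.norm(mean_sig[(a, gid)] - mean_sig[(b, gid)]))
            return np.mean(dists)

        low, high = levels
        lows = [cohort_distance(low, s) for s in range(5)]
        highs = [cohort_distance(high, s) for s in range(5)]
        assert np.mean(highs) > np.mean(lows)


def test_raw_mode_rectified_mean_tracks_envelope(bank3):
    phen = gk.sample_phenotypes(1, 0.0, seed=0)[0]
    cfg = gk.SimConfig(repetition_duration=2.0, variability_level=0.0, rng_seed=0)
    raw = gk.synthesize_raw_repetition(bank3[0], phen, cfg, raw_rate=1000.0)
    assert raw.sampling_rate == 1000.0
    env = bank3[0].render(2000, 2.0).T
    # |raw| should average to the envelope over the active plateau
    active = env[:, 0] > env[:, 0].max() * 0.9
    if active.sum() > 100:
        ratio = np.abs(raw.samples[active, 0]).mean() / env[active, 0].mean()
        assert 0.8 < ratio < 1.2


def test_template_invariants_rejected():
    with pytest.raises(gk.InvalidArgumentError):
        ChannelProfile(0.5, 0.6, 5.0)  # onset + duration > 1
    with pytest.raises(gk.InvalidArgumentError):
        ChannelProfile(0.1, 0.5, 12.0)  # above the 10 mV envelope ceiling
    with pytest.raises(gk.InvalidArgumentError):
        GestureTemplate("g", (ChannelProfile(0.0, 1.0, 0.05),), baseline_amplitude=0.05)
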