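"""1D-CNN classifier: shapes, training loop, early stopping, artifacts."""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.neighbors import NearestCentroid

import gesturekit as gk
from gesturekit.model import (
    ModelConfig,
    TrainConfig,
    build_model,
    simulate_early_stopping,
    train,
)
from gesturekit.nn import softmax_cross_entropy
from gesturekit.preprocessing import WindowBatch


def separable_windows(n_per_class=40, n_classes=3, seed=0):
    """Linearly separable window set: each class activates its own channel."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 0.3, size=(n_per_class * n_classes, 4, 32))
    y = np.repeat(np.arange(n_classes), n_per_class)
    for c in range(n_classes):
        X[y == c, c, :] += 3.0
    return WindowBatch(X, y)


class TestBuildModel:
    def test_forward_shape_contract(self):
        net = build_model(ModelConfig(n_channels=4, n_classes=3), seed=0)
        logits = net.forward(np.zeros((8, 4, 32)))
        assert logits.shape == (8, 3)

    def test_seeded_initialization_is_deterministic(self):
        a = build_model(ModelConfig(4, 5), seed=9)
        b = build_model(ModelConfig(4, 5), seed=9)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_single_class_model_is_valid(self):
        net = build_model(ModelConfig(4, 1), seed=0)
        assert net.forward(np.zeros((2, 4, 32))).shape == (2, 1)

    def test_window_too_short_for_convs_raises_with_minimum(self):
        with pytest.raises(gk.ConfigurationError, match="at least"):
            build_model(ModelConfig(4, 2, window_len=4), seed=0)

    def test_class_count_only_changes_output_layer(self):
        small = build_model(ModelConfig(4, 2), seed=0)
        large = build_model(ModelConfig(4, 9), seed=0)
        for k in small.params:
            if k.startswith("dense4"):
                continue
            assert small.params[k].shape == large.params[k].shape
        assert large.params["dense4_W"].shape[1] == 9

    def test_gradient_matches_finite_differences(self):
        """Backward pass checked against numerical differentiation."""
        cfg = ModelConfig(2, 2, window_len=16, conv_blocks=((3, 3, 2), (4, 3, 2)),
                          dense_hidden=(8, 8, 8, 8))
        net = build_model(cfg, seed=1)
        rng = np.random.default_rng(2)
        x = rng.normal(size=(5, 2, 16))
        y = np.array([0, 1, 0, 1, 1])

        logits, cache = net.forward(x, want_cache=True)
        _, dlogits = softmax_cross_entropy(logits, y)
        grads = net.backward(cache, dlogits)

        eps = 1e-6
        for name in ["conv0_W", "conv1_b", "dense0_W", "dense4_b"]:
            p = net.params[name]
            idx = tuple(rng.integers(0, s) for s in p.shape)
            p[idx] += eps
            up, _ = softmax_cross_entropy(net.forward(x), y)
            p[idx] -= 2 * eps
            down, _ = softmax_cross_entropy(net.forward(x), y)
            p[idx] += eps
            numeric = (up - down) / (2 * eps)
            assert abs(grads[name][idx] - numeric) < 1e-5, name


class TestEarlyStopping:
    def test_min_epochs_binds_when_patience_exhausts_early(self):
        """Plateau from epoch 2 with patience 3 stops at the 10-epoch floor."""
        losses = [1.0] + [0.9] * 30
        assert simulate_early_stopping(losses, min_epochs=10, patience=3) == (10, "early_stop")

    def test_improving_sequence_runs_to_the_end(self):
        losses = [1.0 / (e + 1) for e in range(20)]
        assert simulate_early_stopping(losses, min_epochs=10, patience=5) == (20, "max_epochs")

    def test_plateau_after_min_epochs_stops_at_patience(self):
        losses = [1.0 - 0.05 * e for e in range(12)] + [0.5] * 10
        stopped, reason = simulate_early_stopping(losses, min_epochs=10, patience=4)
        assert reason == "early_stop"
        assert stopped == 16  # last improvement at epoch 12, +4 patience


class TestTrain:
    def test_single_class_validation_accuracy_is_one(self):
        batch = WindowBatch(np.random.default_rng(0).normal(size=(20, 4, 32)), np.zeros(20, dtype=int))
        _, report = train(batch, ModelConfig(4, 1), TrainConfig(max_epochs=10, seed=0))
        assert report.val_accuracy[-1] == 1.0

    def test_separable_gestures_match_nearest_centroid_oracle(self):
        batch = separable_windows()
        mcfg, tcfg = ModelConfig(4, 3), TrainConfig(max_epochs=30, seed=1)
        artifact, report = train(batch, mcfg, tcfg)
        # oracle on the identical stratified split
        from sklearn.model_selection import train_test_split

        idx_tr, idx_va = train_test_split(
            np.arange(len(batch)), test_size=tcfg.validation_fraction,
            stratify=batch.labels, random_state=tcfg.seed % (2**32),
        )
        oracle = NearestCentroid().fit(
            batch.windows[idx_tr].reshape(len(idx_tr), -1), batch.labels[idx_tr]
        )
        oracle_acc = oracle.score(
            batch.windows[idx_va].reshape(len(idx_va), -1), batch.labels[idx_va]
        )
        assert report.final_val_accuracy >= oracle_acc - 0.01
        assert report.final_val_accuracy == 1.0

    def test_fixed_seed_reproduces_loss_curves(self):
        batch = separable_windows(seed=3)
        a = train(batch, ModelConfig(4, 3), TrainConfig(max_epochs=12, seed=5))[1]
        b = train(batch, ModelConfig(4, 3), TrainConfig(max_epochs=12, seed=5))[1]
        assert a.train_loss == b.train_loss
        assert a.val_loss == b.val_loss

    def test_best_epoch_not_worse_than_final(self):
        batch = separable_windows(seed=4)
        _, report = train(batch, ModelConfig(4, 3), TrainConfig(max_epochs=15, seed=2))
        assert report.best_val_loss <= report.val_loss[-1] + 1e-12

    def test_missing_class_listed_in_error(self):
        batch = WindowBatch(np.zeros((10, 4, 32)), np.zeros(10, dtype=int))
        with pytest.raises(gk.InvalidArgumentError, match=r"\[1\]"):
            train(batch, ModelConfig(4, 2), TrainConfig(max_epochs=10))

    def test_stopped_epoch_respects_minimum(self):
        batch = separable_windows(seed=6)
        _, report = train(
            batch, ModelConfig(4, 3),
            TrainConfig(min_epochs=10, max_epochs=50, early_stop_patience=1, seed=0),
        )
        assert report.stopped_epoch >= 10


class TestPredict:
    def test_probabilities_sum_to_one(self, artifact):
        rng = np.random.default_rng(0)
        _, probs = gk.predict_window(artifact, rng.normal(size=(4, 32)))
        assert abs(probs.sum() - 1.0) <= 1e-9

    def test_identical_window_identical_output(self, artifact):
        w = np.random.default_rng(1).normal(size=(4, 32))
        l1, p1 = gk.predict_window(artifact, w)
        l2, p2 = gk.predict_window(artifact, w)
        assert l1 == l2
        np.testing.assert_array_equal(p1, p2)

    def test_shape_mismatch_names_expectation(self, artifact):
        with pytest.raises(gk.ShapeError, match=r"\(4, 32\)"):
            gk.predict_window(artifact, np.zeros((3, 32)))

    def test_argmax_tie_breaks_to_lowest_index(self):
        from gesturekit.nn import softmax

        logits = np.array([[1.0, 1.0, 0.0]])
        assert softmax(logits).argmax(axis=1)[0] == 0


class TestArtifact:
    def test_round_trip_preserves_predictions(self, artifact, tmp_path):
        path = tmp_path / "m.gkm"
        gk.save_artifact(artifact, path)
        loaded = gk.load_artifact(path)
        windows = np.random.default_rng(7).normal(size=(100, 4, 32))
        i1, p1 = gk.predict_batch(artifact, windows)
        i2, p2 = gk.predict_batch(loaded, windows)
        np.testing.assert_array_equal(i1, i2)
        np.testing.assert_array_equal(p1, p2)
        assert loaded.gesture_map == artifact.gesture_map
        np.testing.assert_array_equal(loaded.scaler.mean, artifact.scaler.mean)
        assert loaded.sensor_config == artifact.sensor_config

    def test_truncated_file_raises_artifact_error(self, artifact, tmp_path):
        path = tmp_path / "m.gkm"
        gk.save_artifact(artifact, path)
        path.write_bytes(path.read_bytes()[: path.stat().st_size // 2])
        with pytest.raises(gk.ArtifactError):
            gk.load_artifact(path)

    def test_schema_version_mismatch_is_explicit(self, artifact, tmp_path):
        import io as _io
        import json
        import zipfile

        path = tmp_path / "m.gkm"
        gk.save_artifact(artifact, path)
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            weights = zf.read("weights.npz")
        meta["schema_version"] = 99
        path2 = tmp_path / "m2.gkm"
        with zipfile.ZipFile(path2, "w") as zf:
            zf.writestr("meta.json", json.dumps(meta))
            zf.writestr("weights.npz", weights)
        with pytest.raises(gk.SchemaVersionError):
            gk.load_artifact(path2)

    def test_default_model_artifact_under_five_megabytes(self, artifact, tmp_path):
        path = tmp_path / "m.gkm"
        gk.save_artifact(artifact, path)
        assert path.stat().st_size <= 5 * 1024 * 1024
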