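"""Shared fixtures: a small synthetic cohort and a trained 3-gesture model.

Everything is generated programmatically at test time; session scope keeps
the one real training run shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

import gesturekit as gk
from gesturekit.model import ModelConfig, TrainConfig, train


@pytest.fixture(scope="session")
def bank3():
    return gk.make_gesture_bank(3, 4, seed=7)


@pytest.fixture(scope="session")
def sim_config():
    return gk.SimConfig(repetition_duration=2.0, variability_level=1.0, rng_seed=11)


@pytest.fixture(scope="session")
def small_dataset(bank3, sim_config):
    phenotypes = gk.sample_phenotypes(2, 1.0, seed=5)
    return gk.synthesize_dataset(bank3, phenotypes, 5, sim_config)


@pytest.fixture(scope="session")
def class_map(bank3):
    return {t.gesture_id: i for i, t in enumerate(bank3)}


@pytest.fixture(scope="session")
def trained(small_dataset, class_map):
    """A quick-but-real trained artifact plus its training data scaler."""
    recs = [r for r in small_dataset.recordings if r.user_id == "u00"]
    scaler = gk.fit_scaler(recs)
    batch = gk.batch_from_recordings(recs, class_map, scaler=scaler)
    artifact, report = train(
        batch,
        ModelConfig(n_channels=4, n_classes=3),
        TrainConfig(max_epochs=15, early_stop_patience=5, seed=3),
        scaler=scaler,
        gesture_map=class_map,
    )
    return artifact, report, recs


@pytest.fixture(scope="session")
def artifact(trained):
    return trained[0]
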