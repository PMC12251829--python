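"""Shared fixtures.

The expensive fixtures (the desk-scale training run and its predictions) are
session-scoped and shared across the end-to-end tests so the network is
trained exactly once per test session.
"""

from __future__ import annotations

import numpy as np
import pytest

from afdet.io import WindowSet, extract_windows
from afdet.nn.models import build_model
from afdet.synth import SynthConfig, make_dataset, make_records
from afdet.train import TrainConfig, train

# Desk-scale study conditions: 2000 balanced training windows, 500 held-out,
# ten epochs of the default model.
TRAIN_RECORDS = 334     # x 6 windows/record = 2004 windows
VAL_RECORDS = 84        # x 6 = 504 windows
TRAIN_SEED = 101
VAL_SEED = 202
EPOCHS = 10
BATCH_SIZE = 32


@pytest.fixture(scope="session")
def train_ws() -> WindowSet:
    return make_dataset(TRAIN_RECORDS, afib_fraction=0.5, seed=TRAIN_SEED)


@pytest.fixture(scope="session")
def val_ws() -> WindowSet:
    return make_dataset(VAL_RECORDS, afib_fraction=0.5, seed=VAL_SEED)


@pytest.fixture(scope="session")
def trained(train_ws):
    """The default ConvNeXt model trained at desk scale, plus its history."""
    model = build_model()
    cfg = TrainConfig(epochs=EPOCHS, batch_size=BATCH_SIZE, seed=0)
    model, history = train(model, train_ws, None, cfg)
    return model, history


@pytest.fixture(scope="session")
def mixed_records():
    """Paroxysmal-style records (alternating NSR/AFib plans) for episode tests."""
    return make_records(12, SynthConfig(duration_s=300.0,
                                        rhythm_plan=(("NSR", 300.0),)),
                        seed=777, mixed=True)


@pytest.fixture(scope="session")
def small_model():
    """A miniature ConvNeXt for fast structural tests."""
    from afdet.nn.models import ModelConfig

    return build_model(ModelConfig(dims=(4, 8, 12, 16), depths=(1, 1, 2, 1),
                                   seed=7))
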