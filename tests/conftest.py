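"""Shared fixtures.

The forecaster ensemble is expensive to train (three Informer+LSTM models,
nine epochs each on a 96-day synthetic record), so it is trained once per
session and shared by the lead-time, accuracy and closed-loop tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import cropcast as cc
from cropcast.informer import ForecastWindowConfig, ModelConfig
from cropcast.intervention import TrainingConfig

STUDY_SEED = 1


@pytest.fixture(scope="session")
def trained_ensemble():
    """Three-run forecaster ensemble trained on the burn-in season."""
    return cc.train_ensemble(cc.SimulatorConfig(seed=STUDY_SEED), seed=STUDY_SEED)


@pytest.fixture(scope="session")
def lead_records(trained_ensemble):
    """Lead-time study over 20 seeded operational seasons."""
    return cc.lead_time_study(n_seasons=20, seed=STUDY_SEED,
                              trained=trained_ensemble)


@pytest.fixture()
def tiny_model_cfg():
    """Desk-minimum model for fast unit tests of the training machinery."""
    return ModelConfig(
        d_model=16, d_ff=32, n_heads=4, lstm_hidden=8,
        window=ForecastWindowConfig(seq_len=48, label_len=36, pred_len=24))


@pytest.fixture()
def tiny_train_cfg():
    return TrainingConfig(epochs=2, batch_size=16, windows_per_epoch=32,
                          cov_pretrain_steps=50)


@pytest.fixture()
def small_season():
    """A small noiseless-ish season for preprocessing/feature tests."""
    cfg = cc.SimulatorConfig(horizon_days=16, seed=11)
    return cc.simulate_season(cfg)
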