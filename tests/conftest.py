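"""Shared fixtures: small synthetic worlds built once per session."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from reachdecode.conditioning import (
    ConditioningConfig,
    RawRecording,
    condition_recording,
)
from reachdecode.decoder import build_lagged_design
from reachdecode.features import extract_features
from reachdecode.kinematics import frame_series
from reachdecode.synth import default_encoding, simulate_session, trial_table
from reachdecode.task import TaskConfig

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_world():
    """8-channel, 24-trial strong-encoding session through the full
    conditioning/feature/kinematics path (shared, read-only)."""
    cfg = TaskConfig(n_trials=24, seed=11)
    ds = simulate_session(cfg, default_encoding(8), seed=11)
    tdf = trial_table(ds.trials)
    cond = condition_recording(
        RawRecording(ds.voltages.astype(np.float64), ds.fs), ConditioningConfig()
    )
    feats = extract_features(cond.voltages, ds.fs, tdf)
    frames = frame_series(ds.kin_t, ds.kin_position, tdf, cfg.kin_fs)
    design, valid = build_lagged_design(feats.values)
    return {
        "config": cfg,
        "dataset": ds,
        "trial_df": tdf,
        "features": feats,
        "frames": frames,
        "design": design,
        "valid": valid,
    }
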