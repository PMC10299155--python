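"""Shared synthetic fixtures.

The expensive ensemble + pooled HMM fit is session-scoped and reused by
the idealization, dwell and kinetics tests.
"""
from __future__ import annotations

import numpy as np
import pytest

from smg4 import (
    BindingModel,
    analyze_trajectories,
    simulate_ensemble,
)

V_PLUS1 = 0.5
K_OFF = 0.61
FRAME = 0.1
PRE = 300


@pytest.fixture(scope="session")
def two_state_model() -> BindingModel:
    return BindingModel.two_state(
        V_PLUS1, K_OFF, n_frames=1500, pre_frames=PRE, frame_interval=FRAME
    )


@pytest.fixture(scope="session")
def ensemble(two_state_model):
    """120 two-state molecules at SNR 5 with ground truth."""
    return simulate_ensemble(two_state_model, 120, seed=42)


@pytest.fixture(scope="session")
def analysis(ensemble):
    """Full QC -> HMM -> dwell analysis of the shared ensemble."""
    trajs, _ = ensemble
    return analyze_trajectories(trajs, pre_frames=PRE, n_states=2, seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
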