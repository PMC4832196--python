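"""Shared fixtures: small geometries and noise-free parameter sets."""

from __future__ import annotations

import numpy as np
import pytest

from barrelvsd import synthetic as syn
from barrelvsd.core import AcquisitionGeometry


def quiet(params):
    """Turn off every stochastic/artifact source (amplitudes must stay > 0,
    so they are set far below float resolution of the signal)."""
    return params.evolve(
        noise_sd=1e-15,
        spont_amplitude=1e-15,
        heartbeat_amp=1e-15,
        bleach_tau=1e15,
    )


@pytest.fixture
def small_evoked_geometry() -> AcquisitionGeometry:
    return AcquisitionGeometry(n_rows=40, n_cols=40, n_frames=30, stim_onset_frame=5)


@pytest.fixture
def ctrl_params():
    return syn.ctrl_like_params()


@pytest.fixture
def quiet_ctrl():
    return quiet(syn.ctrl_like_params())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
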