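"""Shared fixtures: small synthetic scenarios so every stage can be tested
against known ground truth without full-size movies."""
from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import omkit


@pytest.fixture(scope="session")
def small_mouse():
    """Down-scaled noisy mouse scenario (80x80, full 2 s window)."""
    sc = omkit.load_scenario("mouse_control", shape=(80, 80), seed=7)
    recording, truth = sc.simulate()
    return sc, recording, truth


@pytest.fixture(scope="session")
def small_cond(small_mouse):
    sc, recording, truth = small_mouse
    params = omkit.ConditioningParams(
        pcl=sc.wave.pcl,
        spatial_window=sc.spatial_window,
        spatial_sigma=sc.spatial_sigma,
        ensemble_window_ms=sc.ensemble_window_ms,
        snr_cutoff=sc.snr_cutoff,
        intensity_cutoff=sc.intensity_cutoff,
    )
    return omkit.condition_recording(recording, params)


@pytest.fixture(scope="session")
def noiseless_mouse():
    """Noise-free, drift-free mouse scenario (60x60, 0.5 s)."""
    sc = omkit.load_scenario("mouse_control", shape=(60, 60), duration_ms=500.0,
                             seed=3)
    sc.noise = dataclasses.replace(sc.noise, noise_sd=0.0, drift_per_second=0.0)
    recording, truth = sc.simulate()
    return sc, recording, truth


@pytest.fixture(scope="session")
def noiseless_cond(noiseless_mouse):
    sc, recording, truth = noiseless_mouse
    params = omkit.ConditioningParams(
        pcl=sc.wave.pcl, intensity_cutoff=sc.intensity_cutoff,
        snr_cutoff=0.0,  # conditioned SNR is infinite without noise
    )
    return omkit.condition_recording(recording, params)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
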