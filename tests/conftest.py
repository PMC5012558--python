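"""Shared fixtures: small phantom problem sizes that keep the suite fast.

The unit-test protocol keeps the default axial/lateral sampling (which the
segmentation operates in) but shrinks the circumferential sweep; module- and
session-scoped fixtures cache the expensive generated volumes.
"""

from __future__ import annotations

import numpy as np
import pytest

from aosoct import (ScanProtocol, SeedPoint, TruthParams, make_mb_series,
                    make_static_volume, propagate_volume)

try:
    from hypothesis import settings
    settings.register_profile("ci", deadline=None, derandomize=True,
                              max_examples=25)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover - hypothesis is an optional extra
    pass


@pytest.fixture(scope="session")
def small_protocol() -> ScanProtocol:
    """Default lateral/axial sampling, short circumferential sweep."""
    return ScanProtocol(n_bscans=16)


@pytest.fixture(scope="session")
def default_params() -> TruthParams:
    return TruthParams(rng_seed=11)


@pytest.fixture(scope="session")
def noiseless_params() -> TruthParams:
    return TruthParams(rng_seed=11, noiseless=True)


@pytest.fixture(scope="session")
def volume_30(small_protocol, default_params):
    """Noisy phantom volume at 30 mmHg plus its truth."""
    return make_static_volume(small_protocol, default_params, 30.0)


@pytest.fixture(scope="session")
def noiseless_volume_30(small_protocol, noiseless_params):
    return make_static_volume(small_protocol, noiseless_params, 30.0)


@pytest.fixture(scope="session")
def segmented_30(volume_30):
    """Propagated segmentation of the 30 mmHg volume, all structures."""
    vol, truth = volume_30
    ref = vol.intensity.shape[0] // 2
    seeds = [SeedPoint(lb, x, z, y_or_frame=ref)
             for lb, (x, z) in truth.seed_points(ref).items()]
    return propagate_volume(vol, seeds, reference=ref)


@pytest.fixture(scope="session")
def mb_small(default_params):
    """Short MB record: 300 frames, step at 250 ms, tau 15 ms."""
    protocol = ScanProtocol(n_bscans=2, n_alines=180, mb_duration=1.5)
    series, truth = make_mb_series(protocol, default_params, 0.0, 30.0,
                                   switch_time=250.0)
    return protocol, series, truth


def make_height_trace(tau_ms=15.0, h0=5.0, h1=30.0, switch_ms=500.0,
                      n=400, dt=5.0, noise_sigma=0.0, seed=0):
    """Analytic first-order height trace used by the dynamics tests."""
    from aosoct import HeightTrace
    t = np.arange(n) * dt
    h = np.where(t >= switch_ms,
                 h0 + (h1 - h0) * (1 - np.exp(-np.maximum(t - switch_ms, 0)
                                              / tau_ms)),
                 h0)
    if noise_sigma:
        h = h + np.random.default_rng(seed).normal(0, noise_sigma, n)
        h = np.clip(h, 0, None)
    return HeightTrace(times=t, heights=h, label="SC", frame_interval=dt,
                       baseline_window=(0.0, switch_ms))
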