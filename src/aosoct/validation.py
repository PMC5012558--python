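"""Self-validation studies of the phantom measurement pipeline.

Three end-to-end studies quantify how well the pipeline recovers known
ground truth, each driven by a single root seed (child seeds are spawned
deterministically, so one integer reproduces the whole study):

* :func:`replicate_volume_deviation` - steady-state stability: the spread
  of the measured Schlemm's-canal volume across replicate noisy
  acquisitions of the same tissue state.
* :func:`step_response_study` - dynamic fidelity: the measured lumen-height
  response time on an MB-mode phantom with a known first-order time
  constant.
* :func:`quadrant_regression_study` - regression quality: r^2 of degree-2
  area-versus-pressure fits across simulated quadrants with heterogeneous
  lumen capacity and multiplicative measurement noise.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from .dynamics import analyze_trace, trace_from_masks
from .geometry import area_profile, lumen_volume
from .phantom import (ScanProtocol, TruthParams, make_mb_series,
                      make_static_volume, true_volume)
from .segmentation import SeedPoint, SegParams, propagate_mb, propagate_volume
from .stats import polyfit_r2

# study problem sizes: reduced circumferential sampling keeps a full study
# within minutes while leaving the axial/lateral sampling (which the
# segmentation works in) at the acquisition defaults
STUDY_PROTOCOL = ScanProtocol(n_bscans=128, n_alines=180)
DEFAULT_PRESSURES = (0.0, 5.0, 10.0, 20.0, 30.0, 50.0)


def child_seeds(root_seed: int, n: int) -> list[int]:
    """Spawn ``n`` independent child seeds (< 2**31) from one root seed."""
    ss = np.random.SeedSequence(root_seed)
    return [int(c.generate_state(1, np.uint32)[0]) & 0x7FFFFFFF
            for c in ss.spawn(n)]


def _measure_sc_volume(protocol: ScanProtocol, params: TruthParams,
                       pressure: float, seg_params: SegParams) -> float:
    vol, truth = make_static_volume(protocol, params, pressure)
    ref = protocol.n_bscans // 2
    seeds_xy = truth.seed_points(ref)
    if "SC" not in seeds_xy:
        raise ValueError(f"SC closed at {pressure} mmHg; cannot seed")
    # seed every visible structure: the watershed split keeps the connected
    # collector channel out of the SC mask
    seeds = [SeedPoint(lb, x, z, y_or_frame=ref)
             for lb, (x, z) in seeds_xy.items()]
    seg = propagate_volume(vol, seeds, seg_params, reference=ref)
    profile = area_profile(seg.masks["SC"], vol.pitch_y, vol.pitch_x,
                           vol.pitch_z, pressure=pressure,
                           span_um=protocol.fov_y)
    return lumen_volume(profile)


def replicate_volume_deviation(seed: int, n_replicates: int = 10,
                               pressure: float = 30.0,
                               protocol: Optional[ScanProtocol] = None,
                               params: Optional[TruthParams] = None,
                               seg_params: SegParams = SegParams()) -> dict:
    """Replicate steady-state acquisitions; report SC-volume spread.

    Each replicate re-renders the same tissue state with independent
    speckle and noise, then runs segmentation and volume quantification.
    Returns the mean absolute relative deviation (percent) of the measured
    volume from the replicate mean, plus the per-replicate volumes.
    """
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates")
    protocol = protocol or STUDY_PROTOCOL
    base = params or TruthParams()
    volumes = []
    for s in child_seeds(seed, n_replicates):
        p = dataclasses.replace(base, rng_seed=s)
        volumes.append(_measure_sc_volume(protocol, p, pressure, seg_params))
    v = np.array(volumes)
    mean = v.mean()
    if mean == 0:
        raise ValueError("replicates measured zero volume; check pressure")
    dev_percent = float(np.mean(np.abs(v - mean)) / mean * 100.0)
    return {"mean_abs_rel_deviation_percent": dev_percent,
            "volumes_nL": volumes,
            "true_volume_nL": true_volume(base, pressure),
            "n": n_replicates}


def step_response_study(seed: int, tau_ms: float = 15.0,
                        p_baseline: float = 0.0, p_target: float = 30.0,
                        switch_time_ms: float = 2000.0,
                        duration_s: float = 4.0,
                        protocol: Optional[ScanProtocol] = None,
                        seg_params: SegParams = SegParams()) -> dict:
    """Step-pressure MB phantom; measure the SC height response time.

    The phantom's lumen height follows a first-order response with
    constant ``tau_ms``; the study runs per-frame segmentation, k-sigma
    onset detection and the 95%-of-plateau response-time measurement.
    """
    base = protocol or ScanProtocol()
    protocol = dataclasses.replace(base, mb_duration=duration_s)
    (child,) = child_seeds(seed, 1)
    params = TruthParams(rng_seed=child, tau=tau_ms)
    series, truth = make_mb_series(protocol, params, p_baseline, p_target,
                                   switch_time_ms)
    # seed where the lumen is widest (post-step); a lumen closed at baseline
    # has no frame-0 centroid
    seeds_xy = {**truth.seed_points(series.frames.shape[0] - 1),
                **truth.seed_points(0)}
    if "SC" not in seeds_xy:
        raise ValueError("SC never opens in this record; cannot seed")
    seeds = [SeedPoint(lb, x, z, y_or_frame=0)
             for lb, (x, z) in seeds_xy.items()]
    seg = propagate_mb(series, seeds, seg_params)
    trace = trace_from_masks(seg.masks["SC"], protocol.pitch_z,
                             series.frame_interval, series.switch_time)
    report = analyze_trace(trace)
    if report.onset_frame is None:
        raise ValueError("no motion detected on the MB phantom")
    return {"response_time_ms": report.response_time,
            "onset_frame": report.onset_frame,
            "true_onset_frame": truth.onset_frame,
            "plateau_height_um": report.plateau_height,
            "true_plateau_height_um": float(truth.true_height_trace[-1]),
            "max_velocity_um_per_ms": report.max_velocity,
            "n_frames": int(series.frames.shape[0])}


def quadrant_regression_study(seed: int, n_quadrants: int = 14,
                              pressures: Sequence[float] = DEFAULT_PRESSURES,
                              noise_frac: float = 0.05,
                              params: Optional[TruthParams] = None) -> dict:
    """Degree-2 area-on-pressure fits across heterogeneous quadrants.

    Each quadrant gets its own lumen capacity (``v_max`` drawn uniformly
    from 0.5-1.5x the default) with the common saturating pressure law;
    measured areas carry ``noise_frac`` multiplicative Gaussian noise.
    Returns per-quadrant r^2 of the polynomial fit and the minimum.
    """
    if n_quadrants < 1:
        raise ValueError("need >= 1 quadrant")
    base = params or TruthParams()
    pressures = np.asarray(pressures, dtype=float)
    protocol = ScanProtocol()
    r2s = []
    for s in child_seeds(seed, n_quadrants):
        rng = np.random.default_rng(s)
        v_max = base.v_max * rng.uniform(0.5, 1.5)
        q = dataclasses.replace(base, v_max=v_max)
        # mean SC cross-sectional area implied by the quadrant's volume law
        areas = np.array([true_volume(q, p) for p in pressures]) \
            / 1e-6 / protocol.fov_y
        noisy = areas * (1.0 + noise_frac * rng.standard_normal(areas.size))
        _, r2, _ = polyfit_r2(pressures, noisy, degree=2)
        r2s.append(float(r2))
    return {"min_r2": min(r2s), "r2_per_quadrant": r2s, "n": n_quadrants}
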