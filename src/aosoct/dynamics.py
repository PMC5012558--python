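"""MB-mode time-series analysis of lumen-height motion.

Given a per-frame lumen-height trace, these routines detect the first frame
of pressure-driven motion (a sustained k-sigma departure from the
pre-switch baseline), measure the response time from the reference frame
(the frame before onset) to 95% of the plateau height change, estimate the
maximum wall velocity from a smoothed derivative, and compare onset times
across structures (synchrony).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy.signal import savgol_filter

from .geometry import mask_height
from .segmentation import LumenMask


@dataclass
class HeightTrace:
    """Uniformly sampled lumen-height time series."""

    times: np.ndarray       # ms
    heights: np.ndarray     # um
    label: str
    frame_interval: float   # ms
    baseline_window: tuple  # (t0, t1) ms; frames with t0 <= t < t1 are baseline

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if self.times.shape != self.heights.shape:
            raise ValueError("times and heights must have equal length")
        if self.times.size >= 2:
            dt = np.diff(self.times)
            if not np.allclose(dt, self.frame_interval, rtol=1e-6, atol=1e-9):
                raise ValueError("times must be uniformly spaced at frame_interval")
        if np.any(self.heights < 0):
            raise ValueError("heights must be >= 0")

    def baseline_indices(self) -> np.ndarray:
        t0, t1 = self.baseline_window
        return np.nonzero((self.times >= t0) & (self.times < t1))[0]


@dataclass
class DynamicsReport:
    label: str
    onset_frame: Optional[int]
    reference_frame: Optional[int]
    response_time: Optional[float]   # ms
    max_velocity: Optional[float]    # um/ms
    plateau_height: Optional[float]  # um
    plateau_reached: bool = True

    @property
    def motion_detected(self) -> bool:
        return self.onset_frame is not None


def trace_from_masks(masks: Sequence[LumenMask], pitch_z: float,
                     frame_interval: float, switch_time: float,
                     label: Optional[str] = None) -> HeightTrace:
    """Assemble a height trace from per-frame segmentation masks."""
    heights = np.array([mask_height(m.mask, pitch_z) for m in masks])
    times = np.arange(len(masks)) * frame_interval
    return HeightTrace(times=times, heights=heights,
                       label=label or masks[0].label,
                       frame_interval=frame_interval,
                       baseline_window=(0.0, switch_time))


def detect_onset(trace: HeightTrace, k: float = 3.0,
                 sustain: int = 3) -> Optional[int]:
    """First frame whose height departs from baseline by > k sigma, sustained.

    The departure must persist for ``sustain`` consecutive frames.  Returns
    the onset frame index, or ``None`` when no motion is detected.
    """
    base = trace.baseline_indices()
    if base.size < 20:
        raise ValueError("baseline window must contain >= 20 frames")
    mu = trace.heights[base].mean()
    sigma = trace.heights[base].std(ddof=1)
    start = base[-1] + 1
    dev = np.abs(trace.heights - mu) > k * sigma
    dev[:start] = False
    n = dev.size
    for i in np.nonzero(dev)[0]:
        if i + sustain <= n and dev[i:i + sustain].all():
            return int(i)
    return None


def response_time(trace: HeightTrace, onset: int,
                  plateau_window_ms: float = 1000.0,
                  threshold: float = 0.95) -> tuple[float, bool]:
    """Time from the reference frame (onset - 1) to 95% of the plateau change.

    The plateau is the mean height over the final ``plateau_window_ms`` of
    the record.  Returns ``(time_ms, plateau_reached)``; when the trace
    never crosses the threshold the time to the post-onset extremum is
    returned instead with ``plateau_reached=False``.
    """
    if onset < 1:
        raise ValueError("onset must leave room for a reference frame")
    t_end = trace.times[-1]
    plateau_sel = trace.times >= t_end - plateau_window_ms
    plateau = trace.heights[plateau_sel].mean()
    ref_frame = onset - 1
    ref = trace.heights[ref_frame]
    change = plateau - ref
    if change == 0:
        raise ValueError("no plateau change relative to the reference frame")
    frac = (trace.heights[onset:] - ref) / change
    crossed = np.nonzero(frac >= threshold)[0]
    if crossed.size:
        idx = onset + int(crossed[0])
        return float(trace.times[idx] - trace.times[ref_frame]), True
    warnings.warn("plateau not reached; returning time to trace extremum")
    idx = onset + int(np.argmax(np.abs(trace.heights[onset:] - ref)))
    return float(trace.times[idx] - trace.times[ref_frame]), False


def max_velocity(trace: HeightTrace, smooth_window: int = 5,
                 onset: Optional[int] = None) -> float:
    """Maximum |dh/dt| (um/ms) from a locally quadratic smoothed derivative.

    A Savitzky-Golay filter (order 2, ``smooth_window`` frames) provides
    the local-quadratic central-difference derivative.  With ``onset``
    given, the maximum is taken over the post-onset region.
    """
    n = trace.heights.size
    if n <= smooth_window:
        raise ValueError("trace must be longer than smooth_window")
    if np.ptp(trace.heights) == 0:
        return 0.0
    v = savgol_filter(trace.heights, smooth_window, polyorder=2, deriv=1,
                      delta=trace.frame_interval)
    if onset is not None:
        v = v[onset:]
    return float(np.abs(v).max())


def synchrony(traces: Sequence[HeightTrace], k: float = 3.0) -> dict:
    """Pairwise onset lags (ms) across structures and the maximum |lag|.

    Raises when fewer than two traces have a detectable onset.
    """
    onsets = {}
    for tr in traces:
        o = detect_onset(tr, k=k)
        if o is not None:
            onsets[tr.label] = tr.times[o]
    if len(onsets) < 2:
        raise ValueError("need detected onsets in >= 2 traces for synchrony")
    lags = {(a, b): float(onsets[a] - onsets[b])
            for a, b in combinations(sorted(onsets), 2)}
    return {"lags_ms": lags,
            "max_abs_lag_ms": max(abs(v) for v in lags.values()),
            "onset_times_ms": onsets}


def analyze_trace(trace: HeightTrace, k: float = 3.0,
                  smooth_window: int = 5) -> DynamicsReport:
    """Full per-trace dynamic report: onset, response time, max velocity."""
    onset = detect_onset(trace, k=k)
    if onset is None:
        return DynamicsReport(label=trace.label, onset_frame=None,
                              reference_frame=None, response_time=None,
                              max_velocity=None, plateau_height=None)
    rt, reached = response_time(trace, onset)
    vmax = max_velocity(trace, smooth_window=smooth_window, onset=onset)
    plateau_sel = trace.times >= trace.times[-1] - 1000.0
    plateau = float(trace.heights[plateau_sel].mean())
    return DynamicsReport(label=trace.label, onset_frame=onset,
                          reference_frame=onset - 1, response_time=rt,
                          max_velocity=vmax, plateau_height=plateau,
                          plateau_reached=reached)
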