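"""Physical measurements from lumen masks: area, height, profiles, volume.

Areas are voxel counts scaled by the in-plane pixel area; lumen height is
the longest axial run of lumen voxels in any A-line column times the axial
pitch; volume is the trapezoidal integral of the cross-sectional area
profile along the circumferential axis, reported in nL (1 nL = 1e6 um^3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .phantom import NL_PER_UM3
from .segmentation import LumenMask

PROFILE_SPACING_UM = 10.0


@dataclass
class AreaProfile:
    """Cross-sectional area sampled on a uniform 10 um grid along y."""

    positions: np.ndarray  # um
    areas: np.ndarray      # um^2
    label: str
    pressure: float        # mmHg

    def __post_init__(self) -> None:
        if np.any(self.areas < 0):
            raise ValueError("areas must be >= 0")


@dataclass
class HeightRecord:
    height: float  # um
    label: str
    pressure: float
    y_or_frame: int = 0


def mask_area(mask: np.ndarray, pitch_x: float, pitch_z: float) -> float:
    """Cross-sectional area of a boolean mask, um^2."""
    return float(np.count_nonzero(mask)) * pitch_x * pitch_z


def mask_height(mask: np.ndarray, pitch_z: float) -> float:
    """Lumen height, um: tallest per-column count of lumen voxels x pitch.

    The per-column count (rather than a bounding box) keeps the measure
    robust to oblique lumen walls.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return 0.0
    return float(m.sum(axis=1).max()) * pitch_z


def area_profile(masks: Sequence[LumenMask], pitch_y: float, pitch_x: float,
                 pitch_z: float, pressure: float = float("nan"),
                 span_um: float = 2000.0) -> AreaProfile:
    """Resample per-B-scan areas onto the uniform 10 um grid over [0, span].

    B-scan i sits at y = i * pitch_y.  Interpolation is linear; grid points
    beyond the last B-scan position (at most one pitch) hold the nearest
    measured value.
    """
    if len(masks) < 2:
        raise ValueError("need at least 2 B-scans for an area profile")
    y = np.arange(len(masks)) * pitch_y
    a = np.array([mask_area(m.mask, pitch_x, pitch_z) for m in masks])
    grid = np.arange(0.0, span_um + 0.5 * PROFILE_SPACING_UM, PROFILE_SPACING_UM)
    areas = np.interp(grid, y, a)
    label = masks[0].label
    return AreaProfile(positions=grid, areas=areas, label=label,
                       pressure=pressure)


def lumen_volume(profile: AreaProfile) -> float:
    """Integrated lumen volume of an area profile, nL."""
    v_um3 = np.trapezoid(profile.areas, profile.positions)
    return float(v_um3 * NL_PER_UM3)


def height_change(height_at_p: float, height_at_reference: float) -> float:
    """Height change relative to the 0 mmHg reference, um."""
    if height_at_reference is None or np.isnan(height_at_reference):
        raise ValueError("missing reference height")
    return height_at_p - height_at_reference
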