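"""Seed-initialized segmentation of dark lumens in OCT B-scans.

The lumens of Schlemm's canal (SC), collector channel entrances (CCE) and
intrascleral collector channels (ISCC) appear as low-backscatter regions
bounded by bright trabecular meshwork (TM) and sclera.  Segmentation is
semi-automatic: a user (or fixture) places one seed per structure on a
reference B-scan; each seed defines a local intensity threshold (a
percentile of a window around the seed), the lumen is grown from the seed
over sub-threshold voxels, and the seed is propagated to neighbouring
B-scans (or MB-mode frames) via the mask centroid.

The dark fluid covering the mounted tissue is as hypo-reflective as the
lumens, so every mask is clipped below the detected TM top surface.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk
from skimage.segmentation import watershed

from .phantom import MBSeries, OCTVolume

logger = logging.getLogger(__name__)

VALID_LABELS = ("SC", "CCE", "ISCC")


@dataclass(frozen=True)
class SeedPoint:
    """One seed: structure label plus (x, z) position on a given plane."""

    label: str
    x: int  # A-line index
    z: int  # depth index
    y_or_frame: int = 0

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise ValueError(f"label must be one of {VALID_LABELS}")


@dataclass(frozen=True)
class SegParams:
    """Tunables of the seeded region grower.

    The local threshold is derived from the intensities of a
    (2*roi_halfwidth+1)^2 window around the seed: either an Otsu bimodal
    split (default — tracks the lumen/tissue boundary regardless of how
    much of the window the lumen fills) or a fixed quantile
    (``threshold_method="percentile"``).  Both are invariant to positive
    rescaling of the image.
    """

    threshold_method: str = "otsu"      # "otsu" | "percentile"
    threshold_percentile: float = 0.35  # quantile of the seed ROI intensities
    roi_halfwidth: int = 12             # ROI is (2h+1) x (2h+1) voxels
    min_region: int = 25                # voxels; smaller regions -> empty mask
    max_region_frac: float = 0.25       # leak guard: larger regions -> empty
    morph_radius: int = 1               # open/close footprint radius
    connectivity: int = 8               # 4 or 8
    smooth_sigma: float = 1.0           # Gaussian pre-smoothing, voxels

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "percentile"):
            raise ValueError("threshold_method must be 'otsu' or 'percentile'")
        if not (0.0 < self.threshold_percentile < 1.0):
            raise ValueError("threshold_percentile must be in (0, 1)")
        if self.min_region < 1:
            raise ValueError("min_region must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    @property
    def _structure(self) -> np.ndarray:
        return ndimage.generate_binary_structure(2, 2 if self.connectivity == 8 else 1)


@dataclass
class LumenMask:
    """Boolean lumen mask aligned to one B-scan or MB frame."""

    mask: np.ndarray  # bool, (n_alines, n_depth)
    label: str
    y_or_frame: int = 0
    empty_allowed: bool = True

    @property
    def is_empty(self) -> bool:
        return not self.mask.any()

    def area_voxels(self) -> int:
        return int(self.mask.sum())

    def centroid(self) -> Optional[tuple[int, int]]:
        if self.is_empty:
            return None
        xs, zs = np.nonzero(self.mask)
        return int(round(xs.mean())), int(round(zs.mean()))


def detect_tm_surface(bscan: np.ndarray, smooth_columns: int = 15,
                      smooth_sigma: float = 1.0) -> np.ndarray:
    """Per-A-line depth index of the first bright band (the TM top).

    Each column is scanned from the surface down for the first sample above
    the midpoint of the B-scan's robust intensity range; columns whose
    maximum never exceeds the global median are interpolated from their
    neighbours.  The surface is smoothed by a running median over
    ``smooth_columns`` columns.  Raises if no column contains a bright band.
    """
    img = np.asarray(bscan, dtype=np.float64)
    if smooth_sigma > 0:
        img = ndimage.gaussian_filter(img, smooth_sigma)
    global_median = np.median(img)
    col_max = img.max(axis=1)
    ok = col_max > global_median
    if not ok.any():
        raise ValueError("no bright band detected in any A-line column")

    lo, hi = np.percentile(img, [5, 95])
    thr = 0.5 * (lo + hi)
    nx = img.shape[0]
    surface = np.full(nx, -1, dtype=float)
    bright = img >= thr
    has_bright = bright.any(axis=1)
    first = np.argmax(bright, axis=1)
    usable = ok & has_bright
    surface[usable] = first[usable]
    if not usable.all():
        idx = np.nonzero(usable)[0]
        surface = np.interp(np.arange(nx), idx, surface[idx])
    surface = ndimage.median_filter(surface, size=smooth_columns, mode="nearest")
    return np.round(surface).astype(int)


def _grow_from_seed(img: np.ndarray, seed: SeedPoint, params: SegParams,
                    surface: np.ndarray) -> np.ndarray:
    """Grow one lumen mask from a seed; may legitimately come back empty."""
    nx, nz = img.shape
    if not (0 <= seed.x < nx and 0 <= seed.z < nz):
        raise ValueError(f"seed {seed} outside image bounds {img.shape}")

    h = params.roi_halfwidth
    roi = img[max(seed.x - h, 0):seed.x + h + 1,
              max(seed.z - h, 0):seed.z + h + 1]
    if params.threshold_method == "otsu":
        thr = threshold_otsu(roi) if roi.max() > roi.min() else roi.min()
    else:
        thr = np.quantile(roi, params.threshold_percentile)

    below = img < thr
    # exclude the fluid layer above the TM: keep strictly below the surface
    zgrid = np.arange(nz)[None, :]
    below &= zgrid > surface[:, None]

    # the seed must sit in a genuinely dark pocket: sub-threshold AND well
    # below the ROI's bright class (a threshold from a lumen-free ROI merely
    # splits the speckle noise of one tissue class and must not seed growth)
    bright = roi[roi >= thr]
    dark_enough = (not bright.size) or img[seed.x, seed.z] < 0.5 * bright.mean()
    if not below[seed.x, seed.z] or not dark_enough:
        # expected whenever a lumen is a closed potential space on this plane
        logger.debug("seed %s at (%d,%d) lies on a bright voxel above the "
                     "local threshold; empty mask", seed.label, seed.x, seed.z)
        return np.zeros_like(below)

    lab, _ = ndimage.label(below, structure=params._structure)
    region = lab == lab[seed.x, seed.z]

    if params.morph_radius > 0:
        fp = disk(params.morph_radius)
        region = ndimage.binary_opening(region, structure=fp)
        region = ndimage.binary_closing(region, structure=fp)
        # morphology may split the region; keep the component at/nearest the seed
        lab2, n2 = ndimage.label(region, structure=params._structure)
        if n2 > 1:
            if lab2[seed.x, seed.z]:
                region = lab2 == lab2[seed.x, seed.z]
            else:
                sizes = ndimage.sum_labels(region, lab2, np.arange(1, n2 + 1))
                region = lab2 == (1 + int(np.argmax(sizes)))

    n_region = region.sum()
    if n_region > params.max_region_frac * img.size:
        warnings.warn(f"{seed.label} region of {n_region} voxels exceeds "
                      f"{params.max_region_frac:.0%} of the B-scan; treated "
                      "as a threshold leak, empty mask returned")
        return np.zeros_like(region)
    if n_region < params.min_region:
        return np.zeros_like(region)
    return region


def segment_bscan(bscan: np.ndarray, seeds: Sequence[SeedPoint],
                  params: SegParams = SegParams(),
                  surface: Optional[np.ndarray] = None) -> list[LumenMask]:
    """Segment one B-scan from per-structure seeds.

    Returns one :class:`LumenMask` per seed, in seed order.  Empty masks are
    legal results: a lumen can be a closed "potential space" at low
    pressure.
    """
    img = np.asarray(bscan, dtype=np.float64)
    if params.smooth_sigma > 0:
        img = ndimage.gaussian_filter(img, params.smooth_sigma)
    if surface is None:
        surface = detect_tm_surface(bscan)
    out = []
    for seed in seeds:
        mask = _grow_from_seed(img, seed, params, surface)
        out.append(LumenMask(mask=mask, label=seed.label,
                             y_or_frame=seed.y_or_frame))
    _split_contested(img, out, seeds)
    return out


def _split_contested(img: np.ndarray, masks: list[LumenMask],
                     seeds: Sequence[SeedPoint]) -> None:
    """Divide regions claimed by several seeds along the intensity ridge.

    Physically connected lumens (e.g. SC and a collector channel entrance
    whose covering flap does not seal the ostium) grow into one component
    from either seed; a marker-based watershed on the intensity splits the
    union at the bright ridge between them.
    """
    overlap = None
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            inter = masks[i].mask & masks[j].mask
            if inter.any():
                overlap = inter if overlap is None else overlap | inter
    if overlap is None:
        return
    union = np.zeros_like(overlap)
    for m in masks:
        union |= m.mask
    markers = np.zeros(img.shape, dtype=np.int32)
    for idx, (m, s) in enumerate(zip(masks, seeds), start=1):
        if m.mask[s.x, s.z]:
            markers[s.x, s.z] = idx
    labels = watershed(img, markers=markers, mask=union)
    for idx, m in enumerate(masks, start=1):
        contested = m.mask & (labels > 0)
        m.mask = (m.mask & ~contested) | (labels == idx)


@dataclass
class PropagationResult:
    """Per-plane masks for each structure after seed propagation."""

    masks: dict  # label -> list[LumenMask], one per plane
    warnings: list = field(default_factory=list)

    def stack(self, label: str) -> np.ndarray:
        """Boolean (n_planes, x, z) array for one structure."""
        return np.stack([m.mask for m in self.masks[label]])


def _propagate(planes: np.ndarray, seeds: Sequence[SeedPoint],
               params: SegParams, reference: int,
               max_gap: Optional[int]) -> PropagationResult:
    n = planes.shape[0]
    labels = [s.label for s in seeds]
    if len(set(labels)) != len(labels):
        raise ValueError("one seed per structure label, got duplicates")
    masks: dict[str, list[Optional[LumenMask]]] = {lb: [None] * n for lb in labels}
    warns: list[str] = []

    ref_masks = segment_bscan(planes[reference], seeds, params)
    sc = next((m for m in ref_masks if m.label == "SC"), None)
    if sc is not None and sc.is_empty:
        warns.append("SC segmentation empty on the reference plane")
    for m in ref_masks:
        m.y_or_frame = reference
        masks[m.label][reference] = m

    empty = np.zeros(planes.shape[1:], dtype=bool)
    # a closed lumen on the reference plane still carries its seed position
    seed_pos = {s.label: (s.x, s.z) for s in seeds}

    for direction in (1, -1):
        points = {m.label: m.centroid() or seed_pos[m.label]
                  for m in ref_masks}
        footprints = {m.label: (None if m.is_empty else m.mask)
                      for m in ref_masks}
        gaps = {lb: 0 for lb in labels}
        stopped = {lb: False for lb in labels}
        rng_idx = range(reference + 1, n) if direction == 1 else \
            range(reference - 1, -1, -1)
        for i in rng_idx:
            active = [lb for lb in labels if not stopped[lb]]
            if active:
                # reseed each lumen at the darkest voxel of THIS plane inside
                # the previous plane's mask footprint: robust to non-convex
                # masks (whose centroid can fall on bright tissue) and to
                # parts of the footprint leaving the lumen between planes
                sm = planes[i].astype(np.float64)
                if params.smooth_sigma > 0:
                    sm = ndimage.gaussian_filter(sm, params.smooth_sigma)
                plane_seeds = []
                for lb in active:
                    fp = footprints[lb]
                    if fp is not None:
                        x, z = np.unravel_index(
                            np.argmin(np.where(fp, sm, np.inf)), sm.shape)
                        points[lb] = (int(x), int(z))
                    plane_seeds.append(SeedPoint(lb, *points[lb], y_or_frame=i))
                results = segment_bscan(planes[i], plane_seeds, params)
            else:
                results = []
            got = {m.label: m for m in results}
            for lb in labels:
                m = got.get(lb)
                if m is None or m.is_empty:
                    masks[lb][i] = LumenMask(mask=empty.copy(), label=lb,
                                             y_or_frame=i)
                    if not stopped[lb] and max_gap is not None:
                        gaps[lb] += 1
                        if gaps[lb] > max_gap:
                            stopped[lb] = True
                            if lb == "SC":
                                msg = (f"SC propagation stopped at plane {i} "
                                       f"(empty gap > {max_gap}); remaining "
                                       "planes marked empty")
                                warns.append(msg)
                                logger.warning(msg)
                else:
                    masks[lb][i] = m
                    footprints[lb] = m.mask
                    points[lb] = m.centroid()
                    gaps[lb] = 0
    return PropagationResult(masks={lb: ms for lb, ms in masks.items()},
                             warnings=warns)


def propagate_volume(volume: OCTVolume, seeds: Sequence[SeedPoint],
                     params: SegParams = SegParams(),
                     reference: Optional[int] = None,
                     max_gap: int = 20) -> PropagationResult:
    """Segment every B-scan of a volume by sweeping seeds outward.

    Seeds are placed on the reference B-scan (default: the plane named by
    the first seed); each neighbouring B-scan is re-seeded at the centroid
    of the previous B-scan's mask.  Empty planes re-use the last centroid
    for up to ``max_gap`` consecutive B-scans before that structure's
    propagation stops.
    """
    if reference is None:
        reference = seeds[0].y_or_frame
    if not (0 <= reference < volume.intensity.shape[0]):
        raise ValueError("reference B-scan outside volume")
    return _propagate(volume.intensity, seeds, params, reference, max_gap)


def propagate_mb(series: MBSeries, seeds: Sequence[SeedPoint],
                 params: SegParams = SegParams(),
                 max_gap: Optional[int] = None) -> PropagationResult:
    """Segment every MB-mode frame, propagating from frame 0 forward.

    Unlike a spatial sweep, MB frames image one fixed cross-section, so by
    default an empty run of frames never halts propagation (``max_gap=None``):
    a lumen closed at baseline pressure reappears at the same position after
    the pressure step.
    """
    return _propagate(series.frames, seeds, params, reference=0,
                      max_gap=max_gap)


def dice(mask: np.ndarray, truth: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a, b = mask.astype(bool), truth.astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
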