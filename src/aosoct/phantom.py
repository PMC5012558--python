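"""Synthetic OCT phantoms of the limbal aqueous outflow system.

The phantom emulates what the imaging protocol sees in a radial limbal
segment mounted trabecular-meshwork (TM) up: a dark fluid layer, a bright
lamellar TM band, the dark lumen of Schlemm's canal (SC) pressed against the
TM's outer wall, a collector channel entrance (CCE) breaching SC's outer
wall under a thin bright collagen flap, and a circumferential intrascleral
collector channel (ISCC) embedded in attenuating sclera.  Lumen size follows
a saturating pressure-volume law with optional hysteresis, and MB-mode
series follow a first-order (exponential) height response to a step pressure
change.  Ground-truth label masks accompany every generated image.

Label codes: 0 background, 1 SC, 2 CCE, 3 ISCC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, field
from typing import Optional

import numpy as np

from .protocol import ScanProtocol

LABEL_BACKGROUND = 0
LABEL_SC = 1
LABEL_CCE = 2
LABEL_ISCC = 3
LABEL_NAMES = {"SC": LABEL_SC, "CCE": LABEL_CCE, "ISCC": LABEL_ISCC}

NL_PER_UM3 = 1e-6  # 1 nL = 1e6 um^3


@dataclass
class TruthParams:
    """Ground-truth tissue/lumen parameters of the phantom.

    The pressure-volume law is a saturating exponential
    ``V(P) = v_min + (v_max - v_min) * (1 - exp(-P / p_eff))`` with
    ``p_eff = p_half`` on the ascending limb and ``p_half / hysteresis_factor``
    on the descending limb (a smaller saturation constant gives a larger
    lumen at equal pressure, i.e. hysteresis).  Volumes refer to the SC
    lumen integrated over the full circumferential field of view.
    """

    # pressure-volume law
    v_min: float = 0.5        # nL at P = 0 ("potential space")
    v_max: float = 15.0       # nL asymptote
    p_half: float = 20.0      # mmHg saturation constant
    hysteresis_factor: float = 1.5
    # cross-section shape
    sc_aspect: float = 8.0    # SC ellipse half-width / half-height
    tm_thickness: float = 120.0   # um
    attenuation: float = 0.0002   # 1/um, scleral signal decay
    # MB-mode response
    tau: float = 15.0         # ms, first-order height response constant
    # speckle
    speckle_looks: float = 4.0
    noiseless: bool = False
    noise_floor_sigma: float = 0.01
    rng_seed: int = 0
    # rendering details (tissue reflectivities and layout, arbitrary units)
    fluid_intensity: float = 0.04
    tm_intensity: float = 0.9
    lamellar_amp: float = 0.35
    lamellar_period_um: float = 20.0
    sclera_intensity: float = 0.75
    lumen_intensity: float = 0.05
    tm_top_um: float = 250.0
    area_mod_amp: float = 0.1
    area_mod_periods: int = 2
    cce_width_um: float = 60.0
    cce_len_max_um: float = 150.0
    cce_x_offset_um: float = 100.0
    cce_y_halfspan_um: float = 250.0
    flap_thickness_um: float = 6.0
    flap_cover_frac: float = 0.5
    iscc_x_offset_um: float = -300.0
    iscc_depth_um: float = 650.0
    iscc_r_max_um: float = 40.0

    def __post_init__(self) -> None:
        if not (self.v_max > self.v_min >= 0):
            raise ValueError("require v_max > v_min >= 0")
        if self.p_half <= 0:
            raise ValueError("p_half must be > 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.hysteresis_factor < 1:
            raise ValueError("hysteresis_factor must be >= 1")
        if self.speckle_looks < 1:
            raise ValueError("speckle_looks must be >= 1")
        if self.tm_thickness <= 0 or self.sc_aspect <= 0:
            raise ValueError("tm_thickness and sc_aspect must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TruthParams":
        return cls(**d)


@dataclass
class OCTVolume:
    """One 3-D intensity volume indexed (B-scan y, A-line x, depth z)."""

    intensity: np.ndarray  # float32, (n_bscans, n_alines, n_depth)
    pitch_y: float  # um
    pitch_x: float  # um
    pitch_z: float  # um
    pressure: float  # mmHg
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be 3-D (y, x, z)")
        if not np.all(np.isfinite(self.intensity)) or self.intensity.min() < 0:
            raise ValueError("intensities must be finite and non-negative")


@dataclass
class MBSeries:
    """Repeated B-scans over time at one y-position, indexed (t, x, z)."""

    frames: np.ndarray  # float32, (n_frames, n_alines, n_depth)
    frame_interval: float  # ms
    switch_time: float  # ms
    p_baseline: float  # mmHg
    p_target: float  # mmHg
    metadata: dict = field(default_factory=dict)

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.frames.shape[0]) * self.frame_interval


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated volume or MB series."""

    masks: np.ndarray  # uint8 label array, same leading shape as the image
    true_volume: Optional[float] = None       # nL (static volumes)
    true_areas_um2: Optional[np.ndarray] = None  # per-B-scan SC area
    true_height_trace: Optional[np.ndarray] = None  # um per frame (MB)
    onset_frame: Optional[int] = None

    def seed_points(self, plane: int) -> dict:
        """Centroid (x, z) of each structure's truth mask in one plane.

        Returns a mapping label-name -> (x, z) for the structures present in
        B-scan/frame ``plane``; structures absent there are omitted.  These
        centroids play the role of the user-placed seeds of a semi-automatic
        segmentation.
        """
        out = {}
        plane_mask = self.masks[plane]
        for name, code in LABEL_NAMES.items():
            xs, zs = np.nonzero(plane_mask == code)
            if xs.size:
                out[name] = (int(round(xs.mean())), int(round(zs.mean())))
        return out


def true_volume(params: TruthParams, pressure: float,
                direction: str = "ascending") -> float:
    """Ground-truth SC volume (nL) at a perfusion pressure.

    Saturating exponential in pressure; the descending limb uses a smaller
    effective saturation constant, so at equal pressure the descending
    volume is >= the ascending one (hysteresis).
    """
    if pressure < 0:
        raise ValueError("pressure must be >= 0 mmHg")
    p_eff = _effective_p_half(params, direction)
    return params.v_min + (params.v_max - params.v_min) * (
        1.0 - math.exp(-pressure / p_eff))


def _effective_p_half(params: TruthParams, direction: str) -> float:
    if direction == "ascending":
        return params.p_half
    if direction == "descending":
        return params.p_half / params.hysteresis_factor
    raise ValueError(f"unknown direction {direction!r}")


def opening_fraction(params: TruthParams, pressure: float,
                     direction: str = "ascending") -> float:
    """Normalized lumen opening in [0, 1): 1 - exp(-P / p_eff)."""
    if pressure < 0:
        raise ValueError("pressure must be >= 0 mmHg")
    return 1.0 - math.exp(-pressure / _effective_p_half(params, direction))


def _sc_mean_area_um2(params: TruthParams, protocol: ScanProtocol,
                      pressure: float, direction: str) -> float:
    v_um3 = true_volume(params, pressure, direction) / NL_PER_UM3
    return v_um3 / protocol.fov_y


def _sc_area_at_y(params: TruthParams, protocol: ScanProtocol, y_um: float,
                  mean_area: float) -> float:
    # smooth modulation with an integer number of periods: integrates to the
    # mean over the field of view, so volume is preserved
    mod = params.area_mod_amp * math.sin(
        2.0 * math.pi * params.area_mod_periods * y_um / protocol.fov_y)
    return mean_area * (1.0 + mod)


def _sc_half_height_from_area(params: TruthParams, area_um2: float) -> float:
    # ellipse area = pi * a * b with a = aspect * b
    if area_um2 <= 0:
        return 0.0
    return math.sqrt(area_um2 / (math.pi * params.sc_aspect))


def _check_geometry(protocol: ScanProtocol, params: TruthParams) -> None:
    # worst case: descending limb at arbitrarily high pressure -> v_max
    a_max = params.v_max / NL_PER_UM3 / protocol.fov_y
    b_max = _sc_half_height_from_area(params, a_max * (1 + params.area_mod_amp))
    z_extent = (params.tm_top_um + params.tm_thickness + 2 * b_max
                + params.cce_len_max_um)
    z_iscc = params.iscc_depth_um + params.iscc_r_max_um
    x_half = params.sc_aspect * b_max
    if max(z_extent, z_iscc) > protocol.depth_range:
        raise ValueError(
            "lumen geometry exceeds field of view: depth extent "
            f"{max(z_extent, z_iscc):.0f} um > {protocol.depth_range:.0f} um; "
            "reduce v_max, tm_top_um or iscc_depth_um")
    if 2 * x_half > protocol.fov_x:
        raise ValueError(
            "lumen geometry exceeds field of view: SC width "
            f"{2 * x_half:.0f} um > {protocol.fov_x:.0f} um; reduce v_max or sc_aspect")


def _render_bscan(protocol: ScanProtocol, params: TruthParams,
                  sc_half_height_um: float, opening: float,
                  cce_active: bool) -> tuple[np.ndarray, np.ndarray]:
    """Render one noiseless B-scan and its truth label plane.

    ``sc_half_height_um`` is the SC ellipse semi-minor (axial) axis;
    ``opening`` in [0, 1] scales the CCE channel length and ISCC area.
    Returns (intensity (x, z) float32, labels (x, z) uint8).
    """
    nx, nz = protocol.n_alines, protocol.n_depth
    x_um = (np.arange(nx) + 0.5) * protocol.pitch_x
    z_um = (np.arange(nz) + 0.5) * protocol.pitch_z

    tm_top = params.tm_top_um
    tm_bot = tm_top + params.tm_thickness

    img = np.empty((nx, nz), dtype=np.float32)
    labels = np.zeros((nx, nz), dtype=np.uint8)

    fluid = z_um < tm_top
    tm_band = (z_um >= tm_top) & (z_um < tm_bot)
    sclera = z_um >= tm_bot

    row = np.empty(nz, dtype=np.float32)
    row[fluid] = params.fluid_intensity
    row[tm_band] = params.tm_intensity * (
        1.0 + params.lamellar_amp * np.sin(
            2.0 * np.pi * (z_um[tm_band] - tm_top) / params.lamellar_period_um))
    row[sclera] = params.sclera_intensity * np.exp(
        -params.attenuation * (z_um[sclera] - tm_bot))
    img[:] = row[None, :]

    x_c = 0.5 * protocol.fov_x
    b = sc_half_height_um
    a = params.sc_aspect * b
    sc_bottom = tm_bot + 2.0 * b

    if b > 0:
        zc = tm_bot + b
        ellipse = ((x_um[:, None] - x_c) / a) ** 2 + \
                  ((z_um[None, :] - zc) / b) ** 2 <= 1.0
        img[ellipse] = params.lumen_intensity
        labels[ellipse] = LABEL_SC

    if cce_active and opening > 0 and b > 0:
        w = params.cce_width_um
        x0 = x_c + params.cce_x_offset_um - 0.5 * w
        cce_len = opening * params.cce_len_max_um
        in_x = (x_um >= x0) & (x_um <= x0 + w)
        in_z = (z_um >= sc_bottom) & (z_um <= sc_bottom + cce_len)
        channel = in_x[:, None] & in_z[None, :]
        img[channel] = params.lumen_intensity
        labels[channel] = LABEL_CCE
        # thin bright collagen flap covering the inner part of the ostium
        flap_x = (x_um >= x0) & (x_um <= x0 + params.flap_cover_frac * w)
        flap_z = (z_um >= sc_bottom) & (z_um <= sc_bottom + params.flap_thickness_um)
        flap = flap_x[:, None] & flap_z[None, :]
        img[flap] = params.tm_intensity
        labels[flap] = LABEL_BACKGROUND

    if opening > 0:
        r = params.iscc_r_max_um * math.sqrt(opening)
        if r > 0:
            xc_i = x_c + params.iscc_x_offset_um
            circle = (x_um[:, None] - xc_i) ** 2 + \
                     (z_um[None, :] - params.iscc_depth_um) ** 2 <= r * r
            img[circle] = params.lumen_intensity
            labels[circle] = LABEL_ISCC

    return img, labels


def _apply_speckle(img: np.ndarray, params: TruthParams,
                   rng: np.random.Generator) -> np.ndarray:
    """Multiplicative gamma speckle (L looks) plus an additive noise floor."""
    looks = params.speckle_looks
    out = img * rng.gamma(looks, 1.0 / looks, size=img.shape).astype(np.float32)
    out += rng.normal(0.0, params.noise_floor_sigma, size=img.shape).astype(np.float32)
    np.clip(out, 0.0, None, out=out)
    return out


def make_static_volume(protocol: ScanProtocol, params: TruthParams,
                       pressure: float, direction: str = "ascending",
                       rng: Optional[np.random.Generator] = None
                       ) -> tuple[OCTVolume, PhantomTruth]:
    """Generate one steady-state 3-D volume at a perfusion pressure.

    The SC cross-sectional area varies smoothly along y and integrates to
    the ground-truth volume ``true_volume(params, pressure, direction)``
    over the circumferential field of view.
    """
    _check_geometry(protocol, params)
    v_nl = true_volume(params, pressure, direction)
    opening = opening_fraction(params, pressure, direction)
    mean_area = _sc_mean_area_um2(params, protocol, pressure, direction)
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)

    ny = protocol.n_bscans
    intensity = np.empty((ny, protocol.n_alines, protocol.n_depth), dtype=np.float32)
    masks = np.empty((ny, protocol.n_alines, protocol.n_depth), dtype=np.uint8)
    areas = np.empty(ny)
    y_cce = 0.5 * protocol.fov_y
    for i in range(ny):
        y_um = i * protocol.pitch_y
        area = _sc_area_at_y(params, protocol, y_um, mean_area)
        areas[i] = area
        b = _sc_half_height_from_area(params, area)
        cce_here = abs(y_um - y_cce) <= params.cce_y_halfspan_um
        img, lab = _render_bscan(protocol, params, b, opening, cce_here)
        if not params.noiseless:
            img = _apply_speckle(img, params, rng)
        intensity[i] = img
        masks[i] = lab

    meta = {"protocol": protocol.to_dict(), "params": params.to_dict(),
            "pressure": pressure, "direction": direction,
            "seed": params.rng_seed}
    vol = OCTVolume(intensity=intensity, pitch_y=protocol.pitch_y,
                    pitch_x=protocol.pitch_x, pitch_z=protocol.pitch_z,
                    pressure=pressure, metadata=meta)
    truth = PhantomTruth(masks=masks, true_volume=v_nl, true_areas_um2=areas)
    return vol, truth


def make_pressure_series(protocol: ScanProtocol, params: TruthParams,
                         pressures: list, loop: bool = False,
                         rng: Optional[np.random.Generator] = None
                         ) -> list[tuple[OCTVolume, PhantomTruth]]:
    """Generate a sequence of static volumes over a pressure protocol.

    With ``loop=True`` the reversed pressure list is appended, generated on
    the descending limb of the hysteretic pressure-volume law.
    """
    if not pressures:
        raise ValueError("pressures must be non-empty")
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    out = [make_static_volume(protocol, params, p, "ascending", rng)
           for p in pressures]
    if loop:
        out += [make_static_volume(protocol, params, p, "descending", rng)
                for p in reversed(pressures)]
    return out


def make_mb_series(protocol: ScanProtocol, params: TruthParams,
                   p_baseline: float, p_target: float, switch_time: float,
                   rng: Optional[np.random.Generator] = None
                   ) -> tuple[MBSeries, PhantomTruth]:
    """Generate an MB-mode series with a step pressure change.

    The SC lumen height follows a first-order response
    ``h(t) = h_base + (h_target - h_base) * (1 - exp(-(t - switch)/tau))``
    for ``t >= switch``; speckle is resampled independently per frame.
    ``switch_time`` is in ms from the start of the record.
    """
    _check_geometry(protocol, params)
    if p_baseline < 0 or p_target < 0:
        raise ValueError("pressures must be >= 0 mmHg")
    duration_ms = protocol.mb_duration * 1000.0
    if not (0.0 <= switch_time <= duration_ms):
        raise ValueError("switch_time must lie within the record")
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)

    # height and opening at the (central) reference y-position
    y_ref = 0.5 * protocol.fov_y

    def _h_and_f(p: float) -> tuple[float, float]:
        mean_area = _sc_mean_area_um2(params, protocol, p, "ascending")
        area = _sc_area_at_y(params, protocol, y_ref, mean_area)
        return 2.0 * _sc_half_height_from_area(params, area), \
            opening_fraction(params, p, "ascending")

    h_base, f_base = _h_and_f(p_baseline)
    h_tgt, f_tgt = _h_and_f(p_target)

    n = protocol.n_frames
    dt = protocol.frame_interval_ms
    t = np.arange(n) * dt
    step = np.where(t >= switch_time,
                    1.0 - np.exp(-np.maximum(t - switch_time, 0.0) / params.tau),
                    0.0)
    h_trace = h_base + (h_tgt - h_base) * step
    f_trace = f_base + (f_tgt - f_base) * step

    onset = None
    if p_target != p_baseline:
        moved = np.nonzero(h_trace != h_base)[0]
        onset = int(moved[0]) if moved.size else None

    frames = np.empty((n, protocol.n_alines, protocol.n_depth), dtype=np.float32)
    masks = np.empty((n, protocol.n_alines, protocol.n_depth), dtype=np.uint8)
    for i in range(n):
        img, lab = _render_bscan(protocol, params, 0.5 * h_trace[i],
                                 f_trace[i], cce_active=True)
        if not params.noiseless:
            img = _apply_speckle(img, params, rng)
        frames[i] = img
        masks[i] = lab

    meta = {"protocol": protocol.to_dict(), "params": params.to_dict(),
            "p_baseline": p_baseline, "p_target": p_target,
            "switch_time_ms": switch_time, "seed": params.rng_seed}
    series = MBSeries(frames=frames, frame_interval=dt, switch_time=switch_time,
                      p_baseline=p_baseline, p_target=p_target, metadata=meta)
    truth = PhantomTruth(masks=masks, true_height_trace=h_trace,
                         onset_frame=onset)
    return series, truth
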