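"""OCT scanning protocol and optical-resolution helpers.

The default protocol mirrors a spectral-domain OCT platform imaging the
limbal aqueous outflow system: a 2 mm (circumferential, y) x 3 mm (lateral,
x) field scanned as 512 B-scans of 360 A-lines with 1024 depth samples over
~2.2 mm in tissue, acquired at 200 B-scans/s; MB-mode repeats one B-scan
position for 7 s to resolve millisecond tissue motion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict


@dataclass(frozen=True)
class ScanProtocol:
    """Scan geometry and timing of one acquisition.

    Axis convention: y = circumferential (along Schlemm's canal, one B-scan
    per position), x = lateral within a B-scan (one A-line per position),
    z = depth from the trabecular meshwork surface.
    """

    n_bscans: int = 512
    n_alines: int = 360
    n_depth: int = 1024
    fov_y: float = 2000.0  # um
    fov_x: float = 3000.0  # um
    depth_range: float = 2200.0  # um
    frame_rate: float = 200.0  # B-scans / s (MB-mode)
    mb_duration: float = 7.0  # s

    def __post_init__(self) -> None:
        for name in ("n_bscans", "n_alines", "n_depth"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        for name in ("fov_y", "fov_x", "depth_range", "frame_rate", "mb_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def pitch_y(self) -> float:
        """B-scan spacing, um."""
        return self.fov_y / self.n_bscans

    @property
    def pitch_x(self) -> float:
        """A-line spacing, um."""
        return self.fov_x / self.n_alines

    @property
    def pitch_z(self) -> float:
        """Axial sample spacing, um."""
        return self.depth_range / self.n_depth

    @property
    def frame_interval_ms(self) -> float:
        return 1000.0 / self.frame_rate

    @property
    def n_frames(self) -> int:
        """Number of MB-mode frames."""
        return round(self.frame_rate * self.mb_duration)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScanProtocol":
        return cls(**d)


def axial_resolution_um(center_wavelength_nm: float = 1340.0,
                        bandwidth_nm: float = 110.0) -> float:
    """Theoretical FWHM axial resolution of an OCT source in air, in um.

    For a Gaussian spectrum the coherence-gated axial resolution is
    (2 ln 2 / pi) * lambda0^2 / (delta lambda).  The default source
    (1340 nm center, 110 nm bandwidth) gives ~7.2 um in air.
    """
    if center_wavelength_nm <= 0 or bandwidth_nm <= 0:
        raise ValueError("wavelength and bandwidth must be positive")
    return (2.0 * math.log(2.0) / math.pi) * center_wavelength_nm ** 2 / bandwidth_nm / 1000.0
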