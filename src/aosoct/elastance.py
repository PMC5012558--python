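"""Pressure-volume curves and elastance of the Schlemm's canal lumen.

Elastance is the bulk stiffness of a hollow organ: the local slope dP/dV of
its pressure-volume relation.  Pressure is regressed on volume with a
low-order polynomial because dP/dV is the quantity of interest; the fitted
polynomial's analytic derivative is the local elastance, and the rising
shape of that derivative is the signature of a tissue that stiffens as it
distends.  Ascending/descending sweep pairs are compared via the enclosed
loop area and the mean volume excess of the descending limb (hysteresis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np


@dataclass
class PressureVolumeCurve:
    pressures: np.ndarray  # mmHg, in acquisition order
    volumes: np.ndarray    # nL
    direction: str         # "ascending" | "descending"

    def __post_init__(self) -> None:
        self.pressures = np.asarray(self.pressures, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.pressures.shape != self.volumes.shape or self.pressures.size < 3:
            raise ValueError("need >= 3 paired (pressure, volume) points")
        if np.any(self.volumes < 0):
            raise ValueError("volumes must be >= 0")
        if self.direction not in ("ascending", "descending"):
            raise ValueError("direction must be ascending or descending")
        step = np.diff(self.pressures)
        ok = np.all(step >= 0) if self.direction == "ascending" else np.all(step <= 0)
        if not ok:
            raise ValueError("pressures must be sorted in direction order")


@dataclass
class ElastanceFit:
    coefficients: np.ndarray  # highest-power-first polynomial of P(V)
    r2: float
    degenerate: bool = False
    _deriv: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._deriv = np.polyder(self.coefficients)

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1

    def pressure(self, volume) -> np.ndarray:
        return np.polyval(self.coefficients, volume)

    def local_elastance(self, volume) -> np.ndarray:
        """dP/dV (mmHg/nL) of the fitted relation at given volume(s)."""
        return np.polyval(self._deriv, volume)


def build_pv_curve(volumes_by_pressure: Sequence[tuple[float, float]],
                   direction: str = "ascending") -> PressureVolumeCurve:
    """Assemble a curve from (pressure, volume) pairs in acquisition order.

    Duplicate pressures within one sweep are averaged with a warning.
    """
    pairs = list(volumes_by_pressure)
    if len({p for p, _ in pairs}) < 3:
        raise ValueError("need >= 3 distinct pressures")
    seen: dict[float, list[float]] = {}
    order: list[float] = []
    for p, v in pairs:
        if p not in seen:
            order.append(p)
            seen[p] = []
        seen[p].append(v)
    if any(len(vs) > 1 for vs in seen.values()):
        warnings.warn("duplicate pressures within one sweep; volumes averaged")
    ps = np.array(order)
    vs = np.array([np.mean(seen[p]) for p in order])
    if np.ptp(vs) == 0:
        warnings.warn("degenerate pressure-volume curve: all volumes equal")
    return PressureVolumeCurve(pressures=ps, volumes=vs, direction=direction)


def fit_elastance(curve: PressureVolumeCurve, degree: int = 2) -> ElastanceFit:
    """Least-squares polynomial fit of P as a function of V."""
    n = curve.pressures.size
    if degree >= n:
        raise ValueError(f"degree {degree} needs more than {n} points")
    if np.ptp(curve.volumes) == 0:
        raise ValueError("zero volume variance: elastance fit undefined")
    coeffs = np.polyfit(curve.volumes, curve.pressures, degree)
    pred = np.polyval(coeffs, curve.volumes)
    ss_res = float(np.sum((curve.pressures - pred) ** 2))
    ss_tot = float(np.sum((curve.pressures - curve.pressures.mean()) ** 2))
    degenerate = ss_tot == 0
    r2 = 0.0 if degenerate else 1.0 - ss_res / ss_tot
    return ElastanceFit(coefficients=coeffs, r2=r2, degenerate=degenerate)


def hysteresis_index(ascending: PressureVolumeCurve,
                     descending: PressureVolumeCurve
                     ) -> tuple[float, float]:
    """Quantify the gap between the two limbs of a pressure loop.

    Returns ``(loop_area, mean_volume_excess)``: the trapezoidal area
    (mmHg*nL) enclosed between the descending and ascending V(P) branches
    over their shared pressure interval, and the mean of
    V_descending - V_ascending there.  A distensible tissue that keeps its
    dilated lumen while pressure falls gives positive values.
    """
    lo = max(ascending.pressures.min(), descending.pressures.min())
    hi = min(ascending.pressures.max(), descending.pressures.max())
    if hi <= lo:
        raise ValueError("ascending and descending curves share no pressure interval")
    pa = ascending.pressures
    va = ascending.volumes
    sel = (pa >= lo) & (pa <= hi)
    p_shared = pa[sel]
    pd = descending.pressures[::-1]
    vd = descending.volumes[::-1]
    v_desc = np.interp(p_shared, pd, vd)
    diff = v_desc - va[sel]
    mean_excess = float(diff.mean())
    loop_area = float(np.trapezoid(diff, p_shared))
    return loop_area, mean_excess
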