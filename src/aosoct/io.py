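"""File formats: multi-page TIFF images with JSON sidecars, CSV tables.

Volumes and MB series are stored as multi-page TIFF (one page per B-scan or
frame) next to a ``.json`` sidecar holding pitches, pressure, protocol and
seed.  Label masks are 8-bit multi-page TIFF with codes
{0: background, 1: SC, 2: CCE, 3: ISCC}.  Tabular outputs (area profiles,
pressure-volume curves, height traces) are plain CSV.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .geometry import AreaProfile
from .phantom import LABEL_NAMES, MBSeries, OCTVolume
from .segmentation import LumenMask, PropagationResult


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def save_volume(volume: OCTVolume, path: str | Path) -> Path:
    """Write a volume as multi-page TIFF + JSON sidecar; returns TIFF path."""
    path = Path(path).with_suffix(".tif")
    tifffile.imwrite(path, volume.intensity)
    meta = {"pitch_y": volume.pitch_y, "pitch_x": volume.pitch_x,
            "pitch_z": volume.pitch_z, "pressure": volume.pressure,
            "metadata": volume.metadata}
    _sidecar(path).write_text(json.dumps(meta, indent=1, default=_jsonable))
    return path


def load_volume(path: str | Path) -> OCTVolume:
    path = Path(path).with_suffix(".tif")
    meta = json.loads(_sidecar(path).read_text())
    return OCTVolume(intensity=tifffile.imread(path),
                     pitch_y=meta["pitch_y"], pitch_x=meta["pitch_x"],
                     pitch_z=meta["pitch_z"], pressure=meta["pressure"],
                     metadata=meta.get("metadata", {}))


def save_mb_series(series: MBSeries, path: str | Path) -> Path:
    path = Path(path).with_suffix(".tif")
    tifffile.imwrite(path, series.frames)
    meta = {"frame_interval": series.frame_interval,
            "switch_time": series.switch_time,
            "p_baseline": series.p_baseline, "p_target": series.p_target,
            "metadata": series.metadata}
    _sidecar(path).write_text(json.dumps(meta, indent=1, default=_jsonable))
    return path


def load_mb_series(path: str | Path) -> MBSeries:
    path = Path(path).with_suffix(".tif")
    meta = json.loads(_sidecar(path).read_text())
    return MBSeries(frames=tifffile.imread(path),
                    frame_interval=meta["frame_interval"],
                    switch_time=meta["switch_time"],
                    p_baseline=meta["p_baseline"], p_target=meta["p_target"],
                    metadata=meta.get("metadata", {}))


def masks_to_labels(result: PropagationResult) -> np.ndarray:
    """Merge a propagation result into one uint8 label stack (plane, x, z)."""
    labels_present = list(result.masks)
    n = len(result.masks[labels_present[0]])
    shape = result.masks[labels_present[0]][0].mask.shape
    out = np.zeros((n,) + shape, dtype=np.uint8)
    for name in labels_present:
        code = LABEL_NAMES[name]
        for i, m in enumerate(result.masks[name]):
            out[i][m.mask] = code
    return out


def labels_to_masks(stack: np.ndarray, label: str) -> list[LumenMask]:
    """Extract one structure's per-plane boolean masks from a label stack."""
    code = LABEL_NAMES[label]
    return [LumenMask(mask=stack[i] == code, label=label, y_or_frame=i)
            for i in range(stack.shape[0])]


def save_masks(stack: np.ndarray, path: str | Path) -> Path:
    path = Path(path).with_suffix(".tif")
    tifffile.imwrite(path, stack.astype(np.uint8))
    return path


def load_masks(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path).with_suffix(".tif"))


def save_area_profile(profile: AreaProfile, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"position_um": profile.positions,
                  "area_um2": profile.areas}).to_csv(path, index=False)
    return path


def load_area_profile(path: str | Path, label: str = "SC",
                      pressure: float = float("nan")) -> AreaProfile:
    df = pd.read_csv(path)
    return AreaProfile(positions=df["position_um"].to_numpy(),
                       areas=df["area_um2"].to_numpy(),
                       label=label, pressure=pressure)


def save_pv_table(rows: list[dict], path: str | Path) -> Path:
    """Rows: {pressure_mmHg, volume_nL, direction}."""
    path = Path(path)
    pd.DataFrame(rows, columns=["pressure_mmHg", "volume_nL", "direction"]
                 ).to_csv(path, index=False)
    return path


def load_pv_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_traces(traces, path: str | Path) -> Path:
    """Height traces as long CSV (time_ms, height_um, label)."""
    path = Path(path)
    frames = [pd.DataFrame({"time_ms": tr.times, "height_um": tr.heights,
                            "label": tr.label}) for tr in traces]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def load_traces(path: str | Path, frame_interval: float,
                switch_time: float) -> list:
    from .dynamics import HeightTrace
    df = pd.read_csv(path)
    out = []
    for label, g in df.groupby("label", sort=False):
        out.append(HeightTrace(times=g["time_ms"].to_numpy(),
                               heights=g["height_um"].to_numpy(),
                               label=str(label),
                               frame_interval=frame_interval,
                               baseline_window=(0.0, switch_time)))
    return out


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
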