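"""End-to-end pipeline: simulate -> segment -> quantify -> elastance/dynamics/stats.

``run_pipeline`` drives the whole chain on a synthetic phantom from one
config mapping and one root seed, writing each stage's outputs plus a run
manifest (config snapshot, seed, output digests, warnings) into the output
directory.  Identical config + seed reproduces identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .dynamics import analyze_trace, synchrony, trace_from_masks
from .elastance import build_pv_curve, fit_elastance, hysteresis_index
from .geometry import area_profile, lumen_volume
from .io import (file_digest, masks_to_labels, save_area_profile, save_masks,
                 save_pv_table, save_traces, _jsonable)
from .phantom import (ScanProtocol, TruthParams, make_mb_series,
                      make_pressure_series)
from .segmentation import (SeedPoint, SegParams, propagate_mb,
                           propagate_volume)
from .stats import anova_oneway, boxplot_summary, polyfit_r2, tukey_pairwise

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 123,
    "protocol": {"n_bscans": 128, "n_alines": 180, "n_depth": 1024},
    "params": {},
    "pressures": [0.0, 5.0, 10.0, 20.0, 30.0, 50.0],
    "loop": False,
    "segmentation": {},
    "max_gap": 20,
    "elastance_degree": 2,
    "mb": {"p_baseline": 0.0, "p_target": 30.0, "switch_time_ms": 500.0,
           "duration_s": 2.0},
    "save_images": False,
}


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    outputs: dict = field(default_factory=dict)  # relative path -> sha256
    warnings: list = field(default_factory=list)
    started: str = ""
    finished: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, default=_jsonable)


def _merge(defaults: dict, override: dict) -> dict:
    out = dict(defaults)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"[{name}] {exc}") from exc
        return wrapped
    return deco


@_stage("simulate")
def _simulate(protocol, params, cfg, rng):
    return make_pressure_series(protocol, params, cfg["pressures"],
                                loop=cfg["loop"], rng=rng)


@_stage("segment")
def _segment(volumes, seg_params, max_gap):
    results = []
    for vol, truth in volumes:
        ref = vol.intensity.shape[0] // 2
        seeds_xy = truth.seed_points(ref)
        if "SC" not in seeds_xy:
            # closed lumen at this pressure: place the seed where SC would sit
            ref_vols = [t for _, t in volumes if "SC" in t.seed_points(ref)]
            if ref_vols:
                seeds_xy = {**ref_vols[-1].seed_points(ref), **seeds_xy}
        seeds = [SeedPoint(lb, x, z, y_or_frame=ref)
                 for lb, (x, z) in seeds_xy.items()]
        if not seeds:
            raise ValueError("no seedable structure on the reference B-scan")
        results.append(propagate_volume(vol, seeds, seg_params,
                                        reference=ref, max_gap=max_gap))
    return results


def run_pipeline(config: dict | None = None,
                 out_dir: str | Path = "aosoct_run") -> RunManifest:
    """Execute the full phantom pipeline; returns the run manifest."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, seed=int(cfg["seed"]),
                           version=__version__,
                           started=datetime.datetime.now().isoformat())

    protocol = ScanProtocol(**cfg["protocol"])
    params = TruthParams(**{**cfg["params"], "rng_seed": int(cfg["seed"])})
    seg_params = SegParams(**cfg["segmentation"])
    rng = np.random.default_rng(int(cfg["seed"]))

    def _write(relpath: str, writer) -> None:
        path = out / relpath
        writer(path)
        manifest.outputs[relpath] = file_digest(path)

    # --- static sweep ---------------------------------------------------
    volumes = _simulate(protocol, params, cfg, rng)
    seg_results = _segment(volumes, seg_params, cfg["max_gap"])

    n_asc = len(cfg["pressures"])
    pv_rows = []
    area_groups: dict[float, np.ndarray] = {}
    for idx, ((vol, truth), seg) in enumerate(zip(volumes, seg_results)):
        direction = "ascending" if idx < n_asc else "descending"
        manifest.warnings.extend(seg.warnings)
        profile = area_profile(seg.masks["SC"], vol.pitch_y, vol.pitch_x,
                               vol.pitch_z, pressure=vol.pressure,
                               span_um=protocol.fov_y)
        vol_nl = lumen_volume(profile)
        pv_rows.append({"pressure_mmHg": vol.pressure, "volume_nL": vol_nl,
                        "direction": direction})
        _write(f"area_profile_{direction}_{vol.pressure:g}mmHg.csv",
               lambda p, profile=profile: save_area_profile(profile, p))
        if direction == "ascending":
            area_groups[vol.pressure] = profile.areas
        if cfg["save_images"]:
            _write(f"masks_{direction}_{vol.pressure:g}mmHg.tif",
                   lambda p, seg=seg: save_masks(masks_to_labels(seg), p))
    _write("pv_curve.csv", lambda p: save_pv_table(pv_rows, p))

    # --- elastance -------------------------------------------------------
    try:
        asc = build_pv_curve([(r["pressure_mmHg"], r["volume_nL"])
                              for r in pv_rows[:n_asc]], "ascending")
        fit = fit_elastance(asc, degree=int(cfg["elastance_degree"]))
        v_grid = np.linspace(asc.volumes.min(), asc.volumes.max(), 50)
        report = {"direction_of_fit": "P regressed on V",
                  "degree": fit.degree,
                  "coefficients_highest_first": fit.coefficients.tolist(),
                  "r2": fit.r2,
                  "volume_grid_nL": v_grid.tolist(),
                  "elastance_mmHg_per_nL": fit.local_elastance(v_grid).tolist()}
        if cfg["loop"]:
            desc = build_pv_curve([(r["pressure_mmHg"], r["volume_nL"])
                                   for r in pv_rows[n_asc:]], "descending")
            loop_area, excess = hysteresis_index(asc, desc)
            report["hysteresis_index"] = {"loop_area_mmHg_nL": loop_area,
                                          "mean_volume_excess_nL": excess}
        _write("elastance.json",
               lambda p: p.write_text(json.dumps(report, indent=1)))
    except Exception as exc:
        raise PipelineError(f"[elastance] {exc}") from exc

    # --- dynamics --------------------------------------------------------
    try:
        mb_cfg = cfg["mb"]
        mb_protocol = dataclasses.replace(
            protocol, mb_duration=float(mb_cfg.get("duration_s",
                                                   protocol.mb_duration)))
        series, mb_truth = make_mb_series(mb_protocol, params,
                                          mb_cfg["p_baseline"],
                                          mb_cfg["p_target"],
                                          mb_cfg["switch_time_ms"], rng=rng)
        # seed on the frame where lumens are widest (post-step plateau);
        # structures closed at baseline have no frame-0 truth centroid
        seeds_xy = {**mb_truth.seed_points(series.frames.shape[0] - 1),
                    **mb_truth.seed_points(0)}
        seeds = [SeedPoint(lb, x, z, y_or_frame=0)
                 for lb, (x, z) in seeds_xy.items()]
        mb_seg = propagate_mb(series, seeds, seg_params)
        traces = [trace_from_masks(mb_seg.masks[lb], mb_protocol.pitch_z,
                                   series.frame_interval, series.switch_time,
                                   label=lb) for lb in mb_seg.masks]
        _write("height_traces.csv", lambda p: save_traces(traces, p))
        reports = {tr.label: dataclasses.asdict(analyze_trace(tr))
                   for tr in traces}
        detected = [tr for tr in traces
                    if reports[tr.label]["onset_frame"] is not None]
        dyn = {"per_structure": reports}
        if len(detected) >= 2:
            dyn["synchrony"] = synchrony(detected)
            dyn["synchrony"]["lags_ms"] = {f"{a}-{b}": v for (a, b), v in
                                           dyn["synchrony"]["lags_ms"].items()}
        _write("dynamics.json",
               lambda p: p.write_text(json.dumps(dyn, indent=1,
                                                 default=_jsonable)))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"[dynamics] {exc}") from exc

    # --- stats -----------------------------------------------------------
    try:
        groups = {p: a for p, a in area_groups.items() if len(a) >= 2}
        f_stat, p_val = anova_oneway(groups)
        pairs = tukey_pairwise(groups)
        xs = np.concatenate([np.full(a.size, p) for p, a in groups.items()])
        ys = np.concatenate(list(groups.values()))
        _, r2, p_reg = polyfit_r2(xs, ys, degree=2)
        stats_report = {
            "grouping": "SC area samples on the 10 um grid, per pressure",
            "anova": {"F": f_stat, "p": p_val},
            "tukey": [dataclasses.asdict(c) for c in pairs],
            "polyfit": {"degree": 2, "r2": r2, "p": p_reg},
            "boxplots": {str(p): dataclasses.asdict(boxplot_summary(a))
                         for p, a in groups.items()},
        }
        _write("stats.json",
               lambda p: p.write_text(json.dumps(stats_report, indent=1,
                                                 default=_jsonable)))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"[stats] {exc}") from exc

    manifest.finished = datetime.datetime.now().isoformat()
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
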