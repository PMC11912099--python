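"""Plate-level orchestration: simulate -> mask -> trace -> fit -> compare.

:func:`run_simulation` turns a config (YAML/JSON file or dict) into a plate
directory of per-well TIFF stacks plus a ground-truth sidecar.
:func:`run_analysis` consumes such a directory (simulated or real), runs
the mask/trace/fit pipeline per well — isolating failures so one bad well
never aborts the plate — and compares conditions on both readouts.

Both functions are deterministic: the same config and seed reproduce the
same bytes on disk.  The run manifest records config, seeds and per-well
status codes (ok / masked-failed / fit-failed / censored).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .errors import ConfigurationError, MicroclotError
from .intensity import extract_trace
from .kinetics import RANGE_EPSILON, fibrinolysis_amount, fibrinolysis_time, fit_4pl
from .masking import MaskParams, generate_mask
from .stats import compare_conditions
from .synthetic import CONTROL_TRUTH, KineticsTruth, RenderConfig, simulate_plate

__all__ = ["PlateExperiment", "RunManifest", "run_simulation", "run_analysis"]

__version__ = "0.1.0"

_SIM_KEYS = {"seed", "n_replicates", "conditions", "render", "jitter_frac", "baseline"}
_RENDER_KEYS = {
    "image_size", "clot_center", "clot_radius", "background_level", "clot_contrast",
    "vignette_gain", "drift_rate", "noise_sigma", "speck_count", "speck_radius",
    "frame_interval_h", "duration_h",
}


@dataclass
class PlateExperiment:
    """A plate ready for analysis: well -> condition map plus image sources."""

    plate_map: pd.DataFrame
    image_sources: dict[str, Path]
    frame_interval_h: float = 1.0
    mask_params: MaskParams = field(default_factory=MaskParams)
    range_epsilon: float = RANGE_EPSILON
    alpha: float = 0.05

    def __post_init__(self) -> None:
        wells = set(self.plate_map["well_id"])
        missing = wells - set(self.image_sources)
        if missing:
            raise ConfigurationError(f"wells without an image source: {sorted(missing)}")

    @classmethod
    def from_dir(cls, plate_dir: Path, frame_interval_h: float | None = None,
                 **kwargs) -> "PlateExperiment":
        plate_dir = Path(plate_dir)
        plate_map = mio.read_platemap(plate_dir / "platemap.csv")
        if frame_interval_h is None:
            meta = plate_dir / "simulation.json"
            frame_interval_h = 1.0
            if meta.exists():
                frame_interval_h = float(
                    json.loads(meta.read_text()).get("frame_interval_h", 1.0))
        sources: dict[str, Path] = {}
        wells_dir = plate_dir / "wells"
        for wid in plate_map["well_id"]:
            tif = wells_dir / f"{wid}.tif"
            sub = wells_dir / wid
            if tif.exists():
                sources[wid] = tif
            elif sub.is_dir():
                sources[wid] = sub
            else:
                raise ConfigurationError(f"no image source for well {wid} under {wells_dir}")
        return cls(plate_map=plate_map, image_sources=sources,
                   frame_interval_h=frame_interval_h, **kwargs)


@dataclass
class RunManifest:
    """Machine-parsable record of one analysis run (no wall-clock state, so
    identical runs produce identical manifests)."""

    config: dict
    version: str
    seed: int | None
    well_status: dict[str, str]

    def to_json(self, path: Path) -> Path:
        path = Path(path)
        payload = {
            "version": self.version,
            "seed": self.seed,
            "config": self.config,
            "config_sha256": hashlib.sha256(
                json.dumps(self.config, sort_keys=True).encode()).hexdigest(),
            "well_status": dict(sorted(self.well_status.items())),
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        return path


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        path = Path(config)
        if not path.exists():
            raise ConfigurationError(f"config file {path} does not exist")
        text = path.read_text()
        cfg = yaml.safe_load(text)
    elif isinstance(config, Mapping):
        cfg = dict(config)
    else:
        raise ConfigurationError(f"unsupported config type {type(config)!r}")
    if not isinstance(cfg, dict):
        raise ConfigurationError("config must be a mapping")
    return cfg


def run_simulation(config, out_dir: Path) -> Path:
    """Render a simulated plate into a directory :func:`run_analysis` can read.

    The config requires ``seed`` (simulation runs must be reproducible),
    ``conditions`` mapping label -> kinetic overrides (c, d, optionally a,
    b, degrading), and accepts ``n_replicates`` (default 8), ``jitter_frac``
    (default 0.05), ``baseline`` (a, b defaults for all conditions) and a
    ``render`` block of RenderConfig fields.
    """
    cfg = _load_config(config)
    unknown = set(cfg) - _SIM_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in cfg:
        raise ConfigurationError("config must set an integer 'seed'")
    if "conditions" not in cfg or not cfg["conditions"]:
        raise ConfigurationError("config must define at least one condition")

    seed = int(cfg["seed"])
    n_replicates = int(cfg.get("n_replicates", 8))
    jitter_frac = float(cfg.get("jitter_frac", 0.05))
    baseline = cfg.get("baseline", {})
    a0 = float(baseline.get("a", CONTROL_TRUTH.a_true))
    b0 = float(baseline.get("b", CONTROL_TRUTH.b_true))

    render_cfg = cfg.get("render", {})
    unknown_render = set(render_cfg) - _RENDER_KEYS
    if unknown_render:
        raise ConfigurationError(f"unknown render keys: {sorted(unknown_render)}")
    render_kwargs = dict(render_cfg)
    if "image_size" in render_kwargs:
        render_kwargs["image_size"] = tuple(render_kwargs["image_size"])
    if render_kwargs.get("clot_center") is not None:
        render_kwargs["clot_center"] = tuple(render_kwargs["clot_center"])
    render = RenderConfig(**render_kwargs)

    conditions: dict[str, KineticsTruth] = {}
    for name, spec in cfg["conditions"].items():
        spec = spec or {}
        conditions[str(name)] = KineticsTruth(
            a_true=float(spec.get("a", a0)),
            b_true=float(spec.get("b", b0)),
            c_true=float(spec.get("c", CONTROL_TRUTH.c_true)),
            d_true=float(spec.get("d", CONTROL_TRUTH.d_true)),
            degrading=bool(spec.get("degrading", True)),
        )

    stacks, truths, platemap = simulate_plate(
        conditions, n_replicates=n_replicates, cfg=render, seed=seed,
        jitter_frac=jitter_frac,
    )

    out_dir = Path(out_dir)
    (out_dir / "wells").mkdir(parents=True, exist_ok=True)
    for wid, stack in stacks.items():
        mio.write_stack(stack, out_dir / "wells" / f"{wid}.tif")
    mio.write_platemap(platemap, out_dir / "platemap.csv")
    mio.write_truth(truths, out_dir / "truth.json")
    (out_dir / "simulation.json").write_text(json.dumps(
        {"seed": seed, "n_replicates": n_replicates,
         "frame_interval_h": render.frame_interval_h,
         "duration_h": render.duration_h,
         "config": _jsonable(cfg)},
        indent=2, sort_keys=True))
    return out_dir


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _analyze_well(stack, experiment: PlateExperiment) -> tuple[str, dict, pd.DataFrame | None]:
    """Mask, trace and fit one well; returns (status, fit row, trace table)."""
    row: dict[str, Any] = {}
    try:
        mask = generate_mask(stack.frames[0], experiment.mask_params)
    except MicroclotError as exc:
        return "masked-failed", {"error": str(exc)}, None
    try:
        trace = extract_trace(stack, mask)
        fit = fit_4pl(trace, range_epsilon=experiment.range_epsilon)
        if not fit.converged:
            return "fit-failed", {"error": "fit did not converge"}, trace.to_frame()
        ftime = fibrinolysis_time(fit)
        row = {
            "a": fit.a, "b": fit.b, "c": fit.c, "d": fit.d,
            "rss": fit.rss, "converged": fit.converged,
            "degrading": fit.degrading, "censored": ftime.censored,
            "fibrinolysis_time_h": ftime.hours,
            "fibrinolysis_amount_pct": fibrinolysis_amount(fit),
            "mask_area_px": mask.area_px,
        }
    except MicroclotError as exc:
        return "fit-failed", {"error": str(exc)}, None
    status = "censored" if ftime.censored else "ok"
    return status, row, trace.to_frame()


def run_analysis(experiment: PlateExperiment, out_dir: Path,
                 stacks: Mapping[str, Any] | None = None,
                 seed: int | None = None) -> dict[str, Path]:
    """Analyze every well of a plate and compare conditions.

    ``stacks`` may supply in-memory FrameStacks keyed by well id (used by
    tests and the simulation front-end); otherwise wells are read from
    ``experiment.image_sources``.  Writes traces.csv, fits.csv,
    comparison.csv, pairwise.csv and manifest.json under ``out_dir`` and
    returns their paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    status: dict[str, str] = {}
    fit_rows = []
    trace_tables = []
    for rec in experiment.plate_map.sort_values("well_id").itertuples():
        wid = rec.well_id
        try:
            stack = (stacks[wid] if stacks is not None
                     else mio.read_stack(experiment.image_sources[wid],
                                         experiment.frame_interval_h, well_id=wid))
        except (MicroclotError, KeyError, OSError) as exc:
            status[wid] = "masked-failed"
            fit_rows.append({"well_id": wid, "condition": rec.condition,
                             "replicate": rec.replicate, "status": "masked-failed",
                             "error": str(exc)})
            continue
        well_status, row, trace_tbl = _analyze_well(stack, experiment)
        status[wid] = well_status
        fit_rows.append({"well_id": wid, "condition": rec.condition,
                         "replicate": rec.replicate, "status": well_status, **row})
        if trace_tbl is not None:
            trace_tables.append(trace_tbl)

    fits = pd.DataFrame(fit_rows)
    traces = (pd.concat(trace_tables, ignore_index=True)
              if trace_tables else pd.DataFrame())

    comparison_rows = []
    pairwise_rows = []
    ok = fits[fits["status"].isin(["ok", "censored"])]
    for readout, column, exclude_censored in (
        ("fibrinolysis_time_h", "fibrinolysis_time_h", True),
        ("fibrinolysis_amount_pct", "fibrinolysis_amount_pct", False),
    ):
        censored_mask = ok["censored"].astype(bool)
        usable = ok[~censored_mask] if exclude_censored else ok
        groups = {
            cond: sub[column].to_numpy()
            for cond, sub in usable.groupby("condition")
            if sub.shape[0] >= 2
        }
        if len(groups) < 2:
            continue
        try:
            result = compare_conditions(groups, alpha=experiment.alpha)
        except MicroclotError:
            continue
        n_censored = ok[censored_mask].groupby("condition").size()
        for row in result.summary.itertuples():
            comparison_rows.append({
                "readout": readout, "condition": row.condition, "n": row.n,
                "mean": row.mean, "sd": row.sd,
                "letter": result.letters[row.condition],
                "n_censored": int(n_censored.get(row.condition, 0)),
                "anova_p": result.p_value,
            })
        for g1 in result.pairwise.index:
            for g2 in result.pairwise.columns:
                if g1 < g2:
                    pairwise_rows.append({"readout": readout, "condition_1": g1,
                                          "condition_2": g2,
                                          "p_adj": float(result.pairwise.loc[g1, g2])})

    paths = {
        "traces": out_dir / "traces.csv",
        "fits": out_dir / "fits.csv",
        "comparison": out_dir / "comparison.csv",
        "pairwise": out_dir / "pairwise.csv",
        "manifest": out_dir / "manifest.json",
    }
    traces.to_csv(paths["traces"], index=False)
    fits.to_csv(paths["fits"], index=False)
    pd.DataFrame(comparison_rows).to_csv(paths["comparison"], index=False)
    pd.DataFrame(pairwise_rows).to_csv(paths["pairwise"], index=False)
    manifest = RunManifest(
        config={
            "frame_interval_h": experiment.frame_interval_h,
            "alpha": experiment.alpha,
            "range_epsilon": experiment.range_epsilon,
            "mask_params": {
                "threshold_method": experiment.mask_params.threshold_method,
                "fixed_threshold": experiment.mask_params.fixed_threshold,
                "closing_radius": experiment.mask_params.closing_radius,
                "opening_radius": experiment.mask_params.opening_radius,
                "connectivity": experiment.mask_params.connectivity,
                "min_mask_fraction": experiment.mask_params.min_mask_fraction,
            },
        },
        version=__version__,
        seed=seed,
        well_status=status,
    )
    manifest.to_json(paths["manifest"])
    return paths
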