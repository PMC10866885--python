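"""Readers, writers and run configuration.

File conventions: comma-separated CSV with a header row and "." decimals;
times carry their unit in the column name; pixel coordinates are 0-based;
physical units enter through ``pixel_size_um`` metadata. Every CLI run
writes the resolved configuration next to its results so runs are
reproducible from the output directory alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .datatypes import FrapSeries, RoiPair, TimeCourse
from .exceptions import RtkQuantError, ValidationError

__all__ = [
    "load_image_stack",
    "load_rois",
    "save_rois",
    "write_results",
    "save_frap_traces",
    "load_frap_traces",
    "load_timecourses",
    "load_config",
]


def load_image_stack(path, pixel_size_um: float | None = None,
                     frame_interval_s: float | None = None):
    """Read a single- or multi-page TIFF as a (frames, H, W) float array.

    Returns ``(stack, metadata)`` where metadata echoes the declared pixel
    size and frame interval. Single-page files come back with a leading
    frame axis of length 1 so per-file and per-page channel layouts share
    one in-memory form.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        stack = tifffile.imread(path)
    except Exception as exc:
        raise IOError(f"unreadable TIFF {path}: {exc}") from exc
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None, ...]
    if stack.ndim != 3:
        raise ValidationError(f"{path}: expected 2-D or 3-D TIFF, got {stack.ndim}-D")
    meta = {"pixel_size_um": pixel_size_um, "frame_interval_s": frame_interval_s,
            "n_frames": stack.shape[0], "shape": stack.shape[1:]}
    return stack, meta


def load_rois(path) -> list[RoiPair]:
    """Read ROI pairs from JSON: [{cell_id, roi1: [[x,y],...], roi2: ...}].

    Polygon validity (simple rings, roi2 strictly inside roi1) is enforced;
    violations raise :class:`ValidationError` naming the cell.
    """
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, list):
        raise ValidationError("ROI file must be a JSON list of cell records")
    rois = []
    for rec in data:
        missing = {"cell_id", "roi1", "roi2"} - set(rec)
        if missing:
            raise ValidationError(f"ROI record missing fields: {sorted(missing)}")
        rois.append(RoiPair(cell_id=str(rec["cell_id"]),
                            roi1=np.asarray(rec["roi1"], dtype=float),
                            roi2=np.asarray(rec["roi2"], dtype=float)))
    return rois


def save_rois(rois: list[RoiPair], path) -> None:
    data = [
        {"cell_id": r.cell_id, "roi1": r.roi1.tolist(), "roi2": r.roi2.tolist()}
        for r in rois
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(data, fh, indent=1)


def write_results(tables: dict[str, pd.DataFrame], path_prefix,
                  summary: dict | None = None) -> list[Path]:
    """Write each table as ``<prefix>_<name>.csv`` plus a JSON summary.

    Column order and row order are preserved as given, so identical inputs
    produce byte-identical files.
    """
    if not tables:
        raise ValidationError("no tables to write")
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        if table is None or len(table) == 0:
            raise ValidationError(f"table {name!r} is empty")
        out = prefix.parent / f"{prefix.name}_{name}.csv"
        table.to_csv(out, index=False, lineterminator="\n", encoding="utf-8")
        written.append(out)
    if summary is not None:
        out = prefix.parent / f"{prefix.name}_summary.json"
        with open(out, "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True, default=_json_default)
        written.append(out)
    return written


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def save_frap_traces(series: FrapSeries, path) -> None:
    """Write a FRAP series as a 4-column CSV (t_s, f_roi, f_total, f_bg).

    Prebleach frames carry negative times at the acquisition spacing.
    """
    pre_t = -series.frame_interval * np.arange(series.n_pre, 0, -1)
    df = pd.DataFrame({
        "t_s": np.concatenate([pre_t, series.times]),
        "f_roi": np.concatenate([series.pre_roi, series.f_roi]),
        "f_total": np.concatenate([series.pre_total, series.f_total]),
        "f_bg": np.concatenate([series.pre_bg, series.f_bg]),
    })
    df.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")


def load_frap_traces(path, frame_interval: float | None = None,
                     nominal_radius: float = 1.2) -> FrapSeries:
    """Read a 4-column trace CSV; rows with t_s < 0 are prebleach frames."""
    df = pd.read_csv(path)
    required = {"t_s", "f_roi", "f_total", "f_bg"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    pre = df[df["t_s"] < 0]
    post = df[df["t_s"] >= 0]
    if pre.empty:
        raise ValidationError(f"{path}: no prebleach rows (t_s < 0)")
    if frame_interval is None:
        t = post["t_s"].to_numpy()
        frame_interval = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    return FrapSeries(
        times=post["t_s"].to_numpy(),
        f_roi=post["f_roi"].to_numpy(),
        f_total=post["f_total"].to_numpy(),
        f_bg=post["f_bg"].to_numpy(),
        pre_roi=pre["f_roi"].to_numpy(),
        pre_total=pre["f_total"].to_numpy(),
        pre_bg=pre["f_bg"].to_numpy(),
        frame_interval=frame_interval,
        nominal_radius=nominal_radius,
    )


def load_timecourses(path) -> list[TimeCourse]:
    """Read densitometry tables: columns construct, replicate, time_min, intensity."""
    df = pd.read_csv(path)
    required = {"construct", "replicate", "time_min", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    courses = []
    for construct, group in df.groupby("construct", sort=True):
        reps = {}
        for rep, sub in group.groupby("replicate", sort=True):
            sub = sub.sort_values("time_min")
            reps[str(rep)] = (sub["time_min"].to_numpy(dtype=float),
                              sub["intensity"].to_numpy(dtype=float))
        t0, y0 = next(iter(reps.values()))
        courses.append(TimeCourse(construct_id=str(construct), times=t0,
                                  intensity=y0, replicates=reps))
    return courses


def load_config(path) -> dict:
    """Read a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise RtkQuantError(f"{path}: configuration must be a mapping")
    return cfg
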