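"""File formats: trajectory CSV, detections CSV, multi-page TIFF stacks.

Trajectory tables use the schema ``trajectory_id,frame,x_um,y_um[,truth_label]``
with positions in micrometers at full precision; movies are multi-page
grayscale TIFFs with an optional sidecar ground-truth CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .trajsim import Trajectory

TRAJ_COLUMNS = ["trajectory_id", "frame", "x_um", "y_um"]


class ParseError(ValueError):
    """Malformed input file."""


def write_trajectories(trajs: list[Trajectory], path) -> None:
    """Write trajectories to CSV (full float precision, lossless round trip)."""
    rows = []
    for t in trajs:
        for k in range(len(t)):
            row = {"trajectory_id": t.id, "frame": int(t.frames[k]),
                   "x_um": repr(float(t.xy[k, 0])), "y_um": repr(float(t.xy[k, 1]))}
            if t.truth_labels is not None:
                row["truth_label"] = t.truth_labels[k]
            rows.append(row)
    cols = TRAJ_COLUMNS + (["truth_label"] if trajs and trajs[0].truth_labels else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_trajectories(path, dt: float = 0.1) -> list[Trajectory]:
    """Read a trajectory CSV; validates schema and frame monotonicity."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        return []
    for col in ("x_um", "y_um"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            line = int(df.index[vals.isna()][0]) + 2  # header + 1-based
            raise ParseError(f"{path}: non-numeric {col} at line {line}")
        df[col] = vals
    has_labels = "truth_label" in df.columns
    out = []
    for tid, grp in df.groupby("trajectory_id", sort=False):
        frames = grp["frame"].to_numpy(dtype=int)
        if len(frames) > 1 and not np.all(np.diff(frames) > 0):
            raise ParseError(f"{path}: non-monotonic frames for trajectory {tid!r}")
        labels = grp["truth_label"].tolist() if has_labels else None
        out.append(Trajectory(id=tid, frames=frames,
                              xy=grp[["x_um", "y_um"]].to_numpy(dtype=float),
                              dt=dt, truth_labels=labels))
    return out


def write_stack(stack: np.ndarray, path) -> None:
    """Write an image stack as multi-page grayscale TIFF (dtype preserved)."""
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be 3D (frames, y, x)")
    tifffile.imwrite(path, stack, photometric="minisblack")


def read_stack(path) -> np.ndarray:
    """Read a multi-page grayscale TIFF into (frames, y, x)."""
    try:
        arr = tifffile.imread(path)
    except Exception as exc:
        raise ParseError(f"{path}: cannot read TIFF ({exc})") from exc
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ParseError(f"{path}: expected grayscale pages, got shape {arr.shape}")
    return arr


def write_detections(detections: pd.DataFrame, path) -> None:
    detections.to_csv(path, index=False)


def read_detections(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("frame", "x_px", "y_px"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col}")
    return df


def write_classifications(results, path) -> None:
    """Per-trajectory classification + segment fits to CSV."""
    rows = []
    for res in results:
        for seg in res.segments:
            fit = seg.fit
            rows.append({
                "trajectory_id": res.traj_id, "category": res.category,
                "whole_traj_D": res.whole_traj_D,
                "segment_start": seg.start, "segment_end": seg.end,
                "mode": seg.mode,
                "D": fit.D if fit else np.nan,
                "v": (fit.v if fit and fit.v is not None else np.nan),
                "L": (fit.L if fit and fit.L is not None else np.nan),
                "conf_diameter": (fit.conf_diameter if fit and fit.conf_diameter
                                  is not None else np.nan),
                "fit_error": seg.fit_error or "",
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def classification_table(results) -> pd.DataFrame:
    """Per-trajectory summary table (D = whole-trajectory D1-4, category)."""
    return pd.DataFrame(
        [{"trajectory_id": r.traj_id, "D": r.whole_traj_D, "category": r.category}
         for r in results])


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
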