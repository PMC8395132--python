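"""Frame-per-frame trajectory building from localized spots.

Linking is greedy globally-nearest-neighbor per frame transition: candidate
(previous, next) pairs are sorted by distance and accepted in increasing
order, each spot used at most once; links beyond ``max_disp`` are forbidden
and unmatched spots start new trajectories. Short tracks are removed by the
minimum-length filter (default: at least 41 localized points).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajsim import Trajectory


@dataclass(frozen=True)
class LinkConfig:
    """Linking parameters.

    max_disp: maximum per-frame displacement (um); default 1.0 um per 100 ms
    covers free diffusion up to roughly D = 0.6 um^2/s at the 99.9th
    percentile single-frame step.
    max_gap: frames an emitter may vanish and still be re-linked (default 0).
    min_points: minimum number of localized points per retained trajectory
    (default 41, boundary inclusive).
    """

    max_disp: float = 1.0
    max_gap: int = 0
    min_points: int = 41

    def __post_init__(self) -> None:
        if self.max_disp <= 0:
            raise ValueError("max_disp must be > 0")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if self.min_points < 2:
            raise ValueError("min_points must be >= 2")


def link_spots(detections: pd.DataFrame, config: LinkConfig, *, dt: float = 0.1,
               pixel_size: float | None = None) -> list[Trajectory]:
    """Link a detections table (frame, x, y) into trajectories.

    Positions are taken from ``x_um``/``y_um`` columns, or from
    ``x_px``/``y_px`` scaled by ``pixel_size``. Gaps up to ``max_gap`` frames
    are bridged, with the missing frames recorded as absent from
    ``Trajectory.frames``.
    """
    if {"x_um", "y_um"}.issubset(detections.columns):
        xcol, ycol, scale = "x_um", "y_um", 1.0
    elif {"x_px", "y_px"}.issubset(detections.columns):
        if pixel_size is None:
            raise ValueError("pixel_size required to convert px detections to um")
        xcol, ycol, scale = "x_px", "y_px", pixel_size
    else:
        raise ValueError("detections must contain x_um/y_um or x_px/y_px columns")
    if "frame" not in detections.columns:
        raise ValueError("detections must contain a 'frame' column")
    if not detections["frame"].is_monotonic_increasing:
        raise ValueError("detections must be sorted by frame")

    # active track: (last_frame, last_xy, [frames], [xys])
    tracks: list[dict] = []
    finished: list[dict] = []
    for frame, grp in detections.groupby("frame", sort=True):
        frame = int(frame)
        pts = grp[[xcol, ycol]].to_numpy(dtype=float) * scale
        # retire tracks that can no longer be extended
        still = []
        for tr in tracks:
            if frame - tr["last_frame"] > config.max_gap + 1:
                finished.append(tr)
            else:
                still.append(tr)
        tracks = still
        # candidate links, globally sorted by distance; stable tie-break on
        # (track index, spot index) for determinism
        cands = []
        for ti, tr in enumerate(tracks):
            d = np.linalg.norm(pts - tr["last_xy"], axis=1)
            for si in np.flatnonzero(d <= config.max_disp):
                cands.append((d[si], ti, int(si)))
        cands.sort(key=lambda c: (c[0], c[1], c[2]))
        used_t: set[int] = set()
        used_s: set[int] = set()
        for dist, ti, si in cands:
            if ti in used_t or si in used_s:
                continue
            used_t.add(ti)
            used_s.add(si)
            tracks[ti]["frames"].append(frame)
            tracks[ti]["xy"].append(pts[si])
            tracks[ti]["last_frame"] = frame
            tracks[ti]["last_xy"] = pts[si]
        for si in range(len(pts)):
            if si not in used_s:
                tracks.append({"last_frame": frame, "last_xy": pts[si],
                               "frames": [frame], "xy": [pts[si]]})
    finished.extend(tracks)
    out = []
    for k, tr in enumerate(sorted(finished, key=lambda t: (t["frames"][0], t["frames"][-1]))):
        out.append(Trajectory(id=k, frames=np.array(tr["frames"]),
                              xy=np.array(tr["xy"]), dt=dt))
    return out


def filter_min_length(trajs: list[Trajectory], min_points: int = 41) -> tuple[list[Trajectory], int]:
    """Keep trajectories with at least ``min_points`` localized points
    (boundary inclusive); returns (retained, n_discarded)."""
    kept = [t for t in trajs if len(t) >= min_points]
    return kept, len(trajs) - len(kept)
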