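"""Frame-to-frame linking of detections into persistent particle tracks.

Linking is greedy nearest-neighbour in xy (score-ordered, same class
required, depth deliberately excluded from the cost since depth is the
quantity under validation); a globally optimal per-frame assignment is
available behind a flag. Utilities validate a track's z-trace against a
commanded piezo-stage step profile and compute mean squared displacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .codec import Detection

__all__ = ["Track", "StageProfile", "link_frames", "z_trace_vs_stage", "msd"]


@dataclass
class Track:
    id: int
    points: list[tuple[int, Detection]] = field(default_factory=list)
    state: str = "active"  # active | lost
    misses: int = 0

    @property
    def last(self) -> Detection:
        return self.points[-1][1]

    @property
    def frames(self) -> list[int]:
        return [f for f, _ in self.points]

    def add(self, frame: int, det: Detection) -> None:
        if self.points and frame <= self.points[-1][0]:
            raise ValueError("frame indices must be strictly increasing within a track")
        self.points.append((frame, det))
        self.misses = 0


@dataclass
class StageProfile:
    """Commanded z offsets: list of (first_frame, last_frame, offset_um)."""

    levels: list[tuple[int, int, float]]

    def __post_init__(self):
        prev_end = None
        for f0, f1, _ in self.levels:
            if f1 < f0:
                raise ValueError("level frame range reversed")
            if prev_end is not None and f0 != prev_end + 1:
                raise ValueError("level frame ranges must be contiguous and non-overlapping")
            prev_end = f1

    def offset_at(self, frame: int) -> float | None:
        for f0, f1, off in self.levels:
            if f0 <= frame <= f1:
                return off
        return None


def link_frames(
    tracks: list[Track],
    detections: list[Detection],
    frame: int,
    max_disp: float,
    max_misses: int = 3,
    global_assignment: bool = False,
    next_id: int | None = None,
) -> list[Track]:
    """Extend ``tracks`` with one frame of detections.

    Greedy: detections in score order claim the nearest unclaimed active
    track of the same class within ``max_disp`` px. With
    ``global_assignment`` the per-frame assignment minimizes total xy
    distance instead. Unassigned detections spawn new tracks; tracks
    unmatched for more than ``max_misses`` frames are marked lost.
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be positive")
    active = [t for t in tracks if t.state == "active"]
    claimed: dict[int, Detection] = {}
    if active and detections:
        if global_assignment:
            cost = np.full((len(detections), len(active)), max_disp * 1e6)
            for i, d in enumerate(detections):
                for j, t in enumerate(active):
                    if d.bead_class == t.last.bead_class:
                        dist = np.hypot(d.x_px - t.last.x_px, d.y_px - t.last.y_px)
                        if dist <= max_disp:
                            cost[i, j] = dist
            rows, cols = linear_sum_assignment(cost)
            for i, j in zip(rows, cols):
                if cost[i, j] <= max_disp:
                    claimed[j] = detections[i]
        else:
            taken: set[int] = set()
            for d in sorted(detections, key=lambda d: -d.score):
                best_j, best_dist = None, max_disp
                for j, t in enumerate(active):
                    if j in taken or d.bead_class != t.last.bead_class:
                        continue
                    dist = np.hypot(d.x_px - t.last.x_px, d.y_px - t.last.y_px)
                    if dist <= best_dist:
                        best_j, best_dist = j, dist
                if best_j is not None:
                    taken.add(best_j)
                    claimed[best_j] = d
    assigned = set()
    for j, t in enumerate(active):
        if j in claimed:
            t.add(frame, claimed[j])
            assigned.add(id(claimed[j]))
        else:
            t.misses += 1
            if t.misses > max_misses:
                t.state = "lost"
    nid = next_id if next_id is not None else (max((t.id for t in tracks), default=-1) + 1)
    for d in detections:
        if id(d) not in assigned:
            t = Track(id=nid)
            nid += 1
            t.add(frame, d)
            tracks.append(t)
    return tracks


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    rows = []
    for t in tracks:
        for f, d in t.points:
            rows.append(
                {
                    "track_id": t.id,
                    "frame": f,
                    "class": d.bead_class,
                    "x_px": d.x_px,
                    "y_px": d.y_px,
                    "z_um": d.z_um,
                    "score": d.score,
                }
            )
    return pd.DataFrame(rows, columns=["track_id", "frame", "class", "x_px", "y_px", "z_um", "score"])


def z_trace_vs_stage(track: Track, profile: StageProfile, baseline_z_um: float | None = None) -> pd.DataFrame:
    """Per-level residuals of a track's z-trace against commanded stage steps.

    The baseline is the median tracked z over the first level unless given
    explicitly; per level the residual is median(z) − (baseline + offset).
    Levels the track never visits are flagged absent.
    """
    frames = dict(track.points)
    rows = []
    first_offset = profile.levels[0][2]
    if baseline_z_um is None:
        zs0 = [frames[f].z_um for f in range(profile.levels[0][0], profile.levels[0][1] + 1) if f in frames]
        if not zs0:
            raise ValueError("track does not cover the first stage level; pass baseline_z_um")
        baseline_z_um = float(np.median(zs0)) - first_offset
    for f0, f1, off in profile.levels:
        zs = [frames[f].z_um for f in range(f0, f1 + 1) if f in frames]
        if not zs:
            rows.append({"offset_um": off, "median_z_um": np.nan, "residual_um": np.nan, "n_frames": 0, "absent": True})
            continue
        med = float(np.median(zs))
        rows.append(
            {
                "offset_um": off,
                "median_z_um": med,
                "residual_um": med - (baseline_z_um + off),
                "n_frames": len(zs),
                "absent": False,
            }
        )
    return pd.DataFrame(rows)


def msd(track: Track, pixel_scale_um: float, frame_interval_s: float) -> pd.DataFrame:
    """Mean squared xy displacement vs lag time, overlapping windows.

    MSD(τ) = ⟨‖r(t+τ) − r(t)‖²⟩ in μm², for lags up to a quarter of the
    track length (longer lags average too few pairs to be meaningful).
    """
    if len(track.points) < 2:
        raise ValueError("track too short for an MSD")
    frames = np.array([f for f, _ in track.points])
    if np.any(np.diff(frames) != 1):
        raise ValueError("MSD requires consecutive frames")
    xy = np.array([[d.x_px, d.y_px] for _, d in track.points]) * pixel_scale_um
    n = len(xy)
    max_lag = max(n // 4, 1)
    rows = []
    for lag in range(1, max_lag + 1):
        disp = xy[lag:] - xy[:-lag]
        rows.append(
            {
                "lag_frames": lag,
                "lag_s": lag * frame_interval_s,
                "msd_um2": float((disp**2).sum(axis=1).mean()),
                "n_pairs": len(disp),
            }
        )
    return pd.DataFrame(rows)
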