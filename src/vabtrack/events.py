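"""Behavioral measurements from a clean, calibrated track.

The assay quantifies attraction to a vibrating rod: the number of approaches
(NOA) is the count of head-center entries into a cutoff radius around the
rod (1.3 cm by default), the duration inside the radius (DIR) and outside it
(DOR) partition the session, and each approach is classified left- or
right-sided by whichever lateral head marker is closer to the rod at entry.
The radius itself can be selected by scanning candidate radii for the one
that best discriminates two groups of fish.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .trackio import TrackSet

DEFAULT_RADII = np.round(np.arange(0.5, 2.51, 0.1), 10)


@dataclass
class ApproachEvent:
    """One outside-to-inside excursion of the head-center marker."""

    entry_frame: int
    exit_frame: int
    side: str  # "left" or "right"
    dwell_s: float


@dataclass
class BehaviorSummary:
    noa_left: int
    noa_right: int
    noa_total: int
    dir_left_s: float
    dir_right_s: float
    dir_total_s: float
    dor_s: float
    dor_facing_left_s: float
    dor_facing_right_s: float
    swim_distance_cm: float
    radius_cm: float
    duration_s: float
    arena_id: str = "arena1"

    def to_row(self) -> dict:
        return dict(self.__dict__)


def rod_distances(tracks: TrackSet, marker: str = "head_center") -> np.ndarray:
    """Per-frame Euclidean distance (cm) between a marker and the rod."""
    return np.linalg.norm(tracks.xy_cm(marker) - tracks.xy_cm("rod"), axis=1)


def rod_distance(tracks: TrackSet, frame: int, marker: str = "head_center") -> float:
    """Distance (cm) between one marker and the rod at one frame."""
    if not 0 <= frame < tracks.n_frames:
        raise IndexError(f"frame {frame} out of range 0..{tracks.n_frames - 1}")
    d = tracks.xy_cm(marker)[frame] - tracks.xy_cm("rod")[frame]
    return float(np.hypot(*d))


def classify_sides(tracks: TrackSet) -> np.ndarray:
    """Per-frame side: "left" iff the head-left marker is nearer the rod.

    Exact ties inherit the previous frame's side; a tie with no prior
    classified frame is "left" (a fixed, documented tie-break).
    """
    d_left = rod_distances(tracks, "head_left")
    d_right = rod_distances(tracks, "head_right")
    sides = np.where(d_left < d_right, "left", "right").astype(object)
    ties = d_left == d_right
    prev = "left"
    if ties.any():
        for i in range(len(sides)):
            if ties[i]:
                sides[i] = prev
            prev = sides[i]
    return np.asarray(sides, dtype="U5")


def classify_side(tracks: TrackSet, frame: int) -> str:
    if not 0 <= frame < tracks.n_frames:
        raise IndexError(f"frame {frame} out of range 0..{tracks.n_frames - 1}")
    return str(classify_sides(tracks)[frame])


def _inside_runs(inside: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of inside frames as (first, last) inclusive."""
    if not inside.any():
        return []
    edges = np.diff(np.concatenate(([0], inside.astype(int), [0])))
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1) - 1
    return list(zip(starts.tolist(), stops.tolist()))


def detect_approaches(
    tracks: TrackSet, radius_cm: float = 1.3, min_gap_frames: int = 0
) -> list[ApproachEvent]:
    """Approach events: maximal runs with head-center distance <= radius.

    The boundary is closed (a frame exactly at the radius is inside). A
    session beginning inside the radius contributes one event classified at
    frame 0. ``min_gap_frames > 0`` merges events separated by shorter
    outside gaps (off by default; no debouncing in the standard analysis).
    """
    if radius_cm <= 0:
        raise ValueError("radius_cm must be positive")
    if tracks.n_frames == 0:
        return []
    inside = rod_distances(tracks, "head_center") <= radius_cm
    runs = _inside_runs(inside)
    if min_gap_frames > 0 and len(runs) > 1:
        merged = [runs[0]]
        for start, stop in runs[1:]:
            if start - merged[-1][1] - 1 < min_gap_frames:
                merged[-1] = (merged[-1][0], stop)
            else:
                merged.append((start, stop))
        runs = merged
    if not runs:
        return []
    sides = classify_sides(tracks)
    return [
        ApproachEvent(
            entry_frame=start,
            exit_frame=stop,
            side=str(sides[start]),
            dwell_s=(stop - start + 1) / tracks.fps,
        )
        for start, stop in runs
    ]


def events_to_frame(events: list[ApproachEvent], arena_id: str = "arena1") -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "arena_id": arena_id,
                "entry_frame": e.entry_frame,
                "exit_frame": e.exit_frame,
                "side": e.side,
                "dwell_s": e.dwell_s,
            }
            for e in events
        ],
        columns=["arena_id", "entry_frame", "exit_frame", "side", "dwell_s"],
    )


def summarize(
    tracks: TrackSet, radius_cm: float = 1.3, min_gap_frames: int = 0
) -> BehaviorSummary:
    """Session summary: NOA by side, DIR/DOR with facing split, swim distance.

    NOA sides are taken at each event's entry frame; DIR and DOR are
    attributed per-frame by the instantaneous marker-proximity side and
    converted to seconds at the session frame rate. Swim distance is the
    summed frame-to-frame displacement of the head-center marker.
    """
    events = detect_approaches(tracks, radius_cm, min_gap_frames)
    inside = rod_distances(tracks, "head_center") <= radius_cm
    sides = classify_sides(tracks)
    left = sides == "left"

    fps = tracks.fps
    dir_left = float(np.sum(inside & left)) / fps
    dir_right = float(np.sum(inside & ~left)) / fps
    dor_left = float(np.sum(~inside & left)) / fps
    dor_right = float(np.sum(~inside & ~left)) / fps

    xy = tracks.xy_cm("head_center")
    swim = float(np.sum(np.linalg.norm(np.diff(xy, axis=0), axis=1))) if len(xy) > 1 else 0.0

    noa_left = sum(1 for e in events if e.side == "left")
    return BehaviorSummary(
        noa_left=noa_left,
        noa_right=len(events) - noa_left,
        noa_total=len(events),
        dir_left_s=dir_left,
        dir_right_s=dir_right,
        dir_total_s=dir_left + dir_right,
        dor_s=dor_left + dor_right,
        dor_facing_left_s=dor_left,
        dor_facing_right_s=dor_right,
        swim_distance_cm=swim,
        radius_cm=radius_cm,
        duration_s=tracks.duration_s,
        arena_id=tracks.arena_id,
    )


def scan_radius(
    group_a: list[TrackSet],
    group_b: list[TrackSet],
    radii: np.ndarray | None = None,
    min_gap_frames: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Select the cutoff radius that best separates two groups' NOA.

    For each candidate radius the per-fish NOA is recomputed in both groups
    and scored with the rank-based two-sample AUC: the probability that a
    random group-B fish has a higher NOA than a random group-A fish (ties
    count half). The radius with the maximum AUC wins; ties go to the
    smallest radius. The full per-radius table is returned alongside.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError(
            "each group needs at least 2 sessions to estimate dispersion "
            f"(got {len(group_a)} and {len(group_b)})"
        )
    radii = DEFAULT_RADII if radii is None else np.asarray(radii, float)
    if radii.size == 0 or np.any(radii <= 0):
        raise ValueError("radii must be a non-empty list of positive values")

    dists_a = [rod_distances(t) for t in group_a]
    dists_b = [rod_distances(t) for t in group_b]

    def noa(dist: np.ndarray, r: float) -> int:
        inside = dist <= r
        return len(_inside_runs(inside))

    rows = []
    for r in radii:
        noa_a = np.array([noa(d, r) for d in dists_a])
        noa_b = np.array([noa(d, r) for d in dists_b])
        if np.all(noa_a == noa_a[0]) and np.all(noa_b == noa_b[0]) and noa_a[0] == noa_b[0]:
            auc = 0.5  # no variation at all: chance separation
        else:
            u = mannwhitneyu(noa_b, noa_a, alternative="two-sided").statistic
            auc = float(u) / (len(noa_a) * len(noa_b))
        rows.append(
            {
                "radius_cm": float(r),
                "auc": auc,
                "mean_noa_a": float(noa_a.mean()),
                "mean_noa_b": float(noa_b.mean()),
            }
        )
    table = pd.DataFrame(rows)
    best = float(table.loc[table["auc"].idxmax(), "radius_cm"])
    return best, table
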