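"""Synthetic pose-track sessions with known ground truth.

Emulates the vibration-attraction assay: a fish swimming in a 10-cm circular
arena with a vibrating rod at the center, recorded for 3 minutes. The fish
wanders on smoothed random waypoints outside the approach radius and makes a
scripted number of approach excursions toward the rod, each with a known
side (drawn right with probability ``p_right``), entry/exit frames and dwell
time. Head-left/right markers sit symmetrically about the head-center
heading (heading taken from frame-to-frame displacement), so the
marker-proximity side rule coincides with the scripted approach side by
construction. Likelihoods of good frames lie in [0.95, 1.0]; corrupted
frames get one marker below 0.92, so the standard confidence threshold
separates them exactly.

Everything is a pure function of (parameters, seed): identical seeds give
byte-identical track tables.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .trackio import MARKERS, TrackSet, tracks_from_arrays


@dataclass
class SimParams:
    """Conditions of one simulated assay session.

    Geometry and timing follow the assay: 10-cm cylindrical arena, rod at
    the center, 3-minute recording, 1.3-cm approach radius. The frame rate
    is a free parameter (default 20 fps). ``approach_depth_cm`` is how close
    to the rod each scripted approach penetrates; ``dwell_mean_s`` the mean
    of the (exponential) dwell-time draw per approach.
    """

    arena_diameter_cm: float = 10.0
    session_duration_s: float = 180.0
    fps: float = 20.0
    pixels_per_cm: float = 50.0
    radius_cm: float = 1.3
    n_events: int = 12
    p_right: float = 0.5
    dwell_mean_s: float = 1.5
    approach_depth_cm: float = 0.5
    swim_speed_cms: float = 4.0
    head_halfwidth_cm: float = 0.25
    body_length_cm: float = 1.5
    dropout_rate: float = 0.0
    noise_sd_px: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_right <= 1.0:
            raise ValueError("p_right must lie in [0, 1]")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        for name in ("arena_diameter_cm", "session_duration_s", "fps",
                     "pixels_per_cm", "radius_cm", "dwell_mean_s",
                     "approach_depth_cm", "swim_speed_cms",
                     "head_halfwidth_cm", "body_length_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_events < 0:
            raise ValueError("n_events must be non-negative")
        if self.noise_sd_px < 0:
            raise ValueError("noise_sd_px must be non-negative")
        if self.approach_depth_cm >= self.radius_cm:
            raise ValueError("approach_depth_cm must be smaller than radius_cm")
        if self.radius_cm + 1.0 >= self.arena_diameter_cm / 2 - 0.6:
            raise ValueError("radius_cm leaves no room to wander inside the arena")


@dataclass
class GTEvent:
    entry_frame: int
    exit_frame: int
    side: str


@dataclass
class GroundTruth:
    """Scripted truth of one simulated session."""

    events: list[GTEvent]
    head_center_cm: np.ndarray  # (n_frames, 2), rod at the origin
    radius_cm: float
    fps: float
    params: SimParams | None = field(default=None, repr=False)


def _left_normal(h: np.ndarray) -> np.ndarray:
    """Fish's left-hand normal of a heading in image coords (y down)."""
    return np.array([h[1], -h[0]])


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector has no direction")
    return v / n


def _segment_min_dist(p: np.ndarray, q: np.ndarray) -> float:
    """Minimum distance from the origin to segment p-q."""
    d = q - p
    denom = float(d @ d)
    if denom == 0:
        return float(np.linalg.norm(p))
    t = np.clip(-(p @ d) / denom, 0.0, 1.0)
    return float(np.linalg.norm(p + t * d))


class _PathBuilder:
    """Accumulates head-center positions (cm, rod at origin) frame by frame."""

    def __init__(self, params: SimParams, rng: np.random.Generator):
        self.p = params
        self.rng = rng
        self.step = params.swim_speed_cms / params.fps
        self.inner = params.radius_cm + 0.8
        self.outer = params.arena_diameter_cm / 2 - 0.6
        self.clear = params.radius_cm + 0.6
        self.pts: list[np.ndarray] = []

    @property
    def pos(self) -> np.ndarray:
        return self.pts[-1]

    def start(self) -> None:
        r = self.rng.uniform(self.p.radius_cm + 1.0, self.outer)
        a = self.rng.uniform(0, 2 * math.pi)
        self.pts.append(np.array([r * math.cos(a), r * math.sin(a)]))

    def _walk_to(self, target: np.ndarray, max_frames: int | None = None) -> int:
        """Constant-speed walk to target; returns frames appended."""
        added = 0
        while True:
            delta = target - self.pos
            dist = float(np.linalg.norm(delta))
            if dist <= 1e-12:
                break
            if max_frames is not None and added >= max_frames:
                break
            if dist <= self.step:
                self.pts.append(target.copy())
            else:
                self.pts.append(self.pos + delta / dist * self.step)
            added += 1
        return added

    def _waypoint(self) -> np.ndarray:
        """Next wander waypoint whose chord stays clear of the radius."""
        p = self.pos
        ang = math.atan2(p[1], p[0])
        for _ in range(100):
            a = ang + self.rng.uniform(-1.2, 1.2)
            r = self.rng.uniform(self.inner, self.outer)
            q = np.array([r * math.cos(a), r * math.sin(a)])
            if _segment_min_dist(p, q) > self.clear and np.linalg.norm(q - p) > self.step:
                return q
        # fallback: a short arc at the current radius is always clear
        a = ang + 0.4
        r = float(np.clip(np.linalg.norm(p), self.inner, self.outer))
        return np.array([r * math.cos(a), r * math.sin(a)])

    def wander(self, n_frames: int) -> None:
        added = 0
        while added < n_frames:
            added += self._walk_to(self._waypoint(), max_frames=n_frames - added)

    def approach_and_dwell(self, side: str, dwell_frames: int) -> None:
        """Scripted excursion: enter the radius with the given side, orbit
        the rod for the dwell, leave radially."""
        p0 = self.pos
        u = _unit(-p0)  # toward the rod
        depth = self.p.approach_depth_cm
        target = None
        for cand in (depth * _left_normal(u), -depth * _left_normal(u)):
            h = _unit(cand - p0)
            # the rod's side of the path is constant along the straight leg
            cand_side = "left" if float(_left_normal(h) @ (-p0)) > 0 else "right"
            if cand_side == side:
                target = cand
                break
        assert target is not None
        self._walk_to(target)

        # dwell: slow orbit around the rod at the penetration depth, turning
        # the way that keeps the rod on the scripted side
        r_c = float(np.linalg.norm(self.pos))
        ang = math.atan2(self.pos[1], self.pos[0])
        dtheta = min(self.p.swim_speed_cms, 1.0) / self.p.fps / r_c
        tangent = np.array([-math.sin(ang), math.cos(ang)])
        if ("left" if float(_left_normal(tangent) @ (-self.pos)) > 0 else "right") != side:
            dtheta = -dtheta
        for _ in range(dwell_frames):
            ang += dtheta
            self.pts.append(np.array([r_c * math.cos(ang), r_c * math.sin(ang)]))

        # radial exit back past the wander margin; the first step is a
        # fractional (irrational) multiple so no frame lands exactly on the
        # radius boundary
        out_dir = _unit(self.pos)
        r_now = float(np.linalg.norm(self.pos))
        self.pts.append(out_dir * (r_now + 0.61803 * self.step))
        self._walk_to(out_dir * (self.p.radius_cm + 1.0))


def _headings(path: np.ndarray) -> np.ndarray:
    """Per-frame unit heading from frame-to-frame displacement.

    A frame with no displacement keeps the previous heading; frame 0 takes
    the first movement's direction.
    """
    n = len(path)
    h = np.tile(np.array([1.0, 0.0]), (n, 1))
    last = np.array([1.0, 0.0])
    for i in range(1, n):
        d = path[i] - path[i - 1]
        norm = np.linalg.norm(d)
        if norm > 1e-12:
            last = d / norm
        h[i] = last
    if n > 1:
        h[0] = h[1]
    return h


def _scan_events(dist: np.ndarray, radius: float) -> list[tuple[int, int]]:
    inside = dist <= radius
    if not inside.any():
        return []
    edges = np.diff(np.concatenate(([0], inside.astype(int), [0])))
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1) - 1
    return list(zip(starts.tolist(), stops.tolist()))


def simulate_session(params: SimParams) -> tuple[TrackSet, GroundTruth]:
    """Simulate one assay session; returns tracks plus scripted ground truth.

    Raises if the requested events and dwell times cannot fit into the
    session duration.
    """
    rng = np.random.default_rng(params.seed)
    n_frames = int(round(params.session_duration_s * params.fps))
    step = params.swim_speed_cms / params.fps
    arena_r = params.arena_diameter_cm / 2

    sides = np.where(rng.random(params.n_events) < params.p_right,
                     "right", "left").tolist()
    max_dwell = max(1, int(round(3 * params.dwell_mean_s * params.fps)))
    dwell_frames = [
        min(max_dwell, max(1, int(round(rng.exponential(params.dwell_mean_s)
                                        * params.fps))))
        for _ in range(params.n_events)
    ]

    # conservative per-event frame bound: approach leg + dwell + exit leg
    approach_bound = math.ceil((arena_r + params.radius_cm + 1.0) / step) + 2
    exit_bound = math.ceil((params.radius_cm + 1.5) / step) + 2
    budget = sum(approach_bound + d + exit_bound for d in dwell_frames)
    leftover = n_frames - 1 - budget
    if leftover < 0:
        raise ValueError(
            f"infeasible session: {params.n_events} approaches with the "
            f"drawn dwell times need up to {budget} frames but the session "
            f"has only {n_frames} "
            f"({params.session_duration_s} s at {params.fps} fps)"
        )

    if params.n_events:
        wander_alloc = rng.multinomial(
            leftover, [1.0 / (params.n_events + 1)] * (params.n_events + 1)
        )
    else:
        wander_alloc = np.array([leftover])

    builder = _PathBuilder(params, rng)
    builder.start()
    for i in range(params.n_events):
        builder.wander(int(wander_alloc[i]))
        builder.approach_and_dwell(sides[i], dwell_frames[i])
    builder.wander(n_frames - len(builder.pts))
    path = np.asarray(builder.pts[:n_frames])
    assert len(path) == n_frames

    head = _headings(path)
    left_n = np.stack([head[:, 1], -head[:, 0]], axis=1)
    w = params.head_halfwidth_cm
    markers_cm = {
        "head_center": path,
        "head_left": path + w * left_n,
        "head_right": path - w * left_n,
        "caudal": path - params.body_length_cm * head,
        "rod": np.zeros_like(path),
    }

    # ground truth from the clean geometry
    dist = np.linalg.norm(path, axis=1)
    runs = _scan_events(dist, params.radius_cm)
    events = []
    for start, stop in runs:
        d_l = np.linalg.norm(markers_cm["head_left"][start])
        d_r = np.linalg.norm(markers_cm["head_right"][start])
        events.append(GTEvent(start, stop, "left" if d_l < d_r else "right"))
    truth = GroundTruth(events=events, head_center_cm=path,
                        radius_cm=params.radius_cm, fps=params.fps,
                        params=params)

    ppc = params.pixels_per_cm
    markers_px = {}
    likelihoods = {}
    for m in MARKERS:
        px = (markers_cm[m] + arena_r) * ppc
        if params.noise_sd_px > 0:
            px = px + rng.normal(0.0, params.noise_sd_px, size=px.shape)
        markers_px[m] = px
        likelihoods[m] = rng.uniform(0.95, 1.0, size=n_frames)

    tracks = tracks_from_arrays(markers_px, likelihoods, fps=params.fps,
                                pixels_per_cm=ppc)
    if params.dropout_rate > 0:
        tracks = corrupt_confidence(
            tracks, params.dropout_rate,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    return tracks, truth


def corrupt_confidence(
    tracks: TrackSet, dropout_rate: float, seed: int
) -> TrackSet:
    """Degrade a track the way pose estimation fails on real video.

    Each frame is independently corrupted with probability ``dropout_rate``:
    one randomly chosen marker gets a likelihood below 0.92 and its
    coordinates jump by a large random offset. The frame count is unchanged;
    ``dropout_rate = 0`` returns the input unchanged.
    """
    if not 0.0 <= dropout_rate < 1.0:
        raise ValueError("dropout_rate must lie in [0, 1)")
    if dropout_rate == 0.0 or tracks.n_frames == 0:
        return tracks
    rng = np.random.default_rng(seed)
    flags = rng.random(tracks.n_frames) < dropout_rate
    data = tracks.data.copy()
    marker_idx = rng.integers(0, len(MARKERS), size=tracks.n_frames)
    for i in np.flatnonzero(flags):
        m = MARKERS[marker_idx[i]]
        data.loc[i, (m, "likelihood")] = rng.uniform(0.0, 0.92)
        data.loc[i, (m, "x")] += rng.normal(0.0, 25.0)
        data.loc[i, (m, "y")] += rng.normal(0.0, 25.0)
    return tracks.with_data(data)


def simulate_cohort(
    params: SimParams, n_fish: int, seed: int | None = None
) -> list[tuple[TrackSet, GroundTruth]]:
    """Independent sessions for a cohort; per-fish seeds derive from one seed."""
    base = params.seed if seed is None else seed
    seeds = np.random.SeedSequence(base).generate_state(n_fish) % (2**31 - 1)
    out = []
    for s in seeds:
        p = SimParams(**{**asdict(params), "seed": int(s)})
        out.append(simulate_session(p))
    return out


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Line-delimited JSON event log: one meta line, then one line/event."""
    with open(path, "w") as fh:
        meta = {"record": "meta", "radius_cm": truth.radius_cm,
                "fps": truth.fps, "n_frames": len(truth.head_center_cm),
                "n_events": len(truth.events)}
        fh.write(json.dumps(meta) + "\n")
        for e in truth.events:
            fh.write(json.dumps({"record": "event",
                                 "entry_frame": e.entry_frame,
                                 "exit_frame": e.exit_frame,
                                 "side": e.side}) + "\n")


def read_ground_truth(path: str | Path) -> GroundTruth:
    events = []
    meta = {}
    with open(path) as fh:
        for line in fh:
            obj = json.loads(line)
            if obj.get("record") == "meta":
                meta = obj
            elif obj.get("record") == "event":
                events.append(GTEvent(obj["entry_frame"], obj["exit_frame"],
                                      obj["side"]))
    return GroundTruth(events=events,
                       head_center_cm=np.empty((0, 2)),
                       radius_cm=meta.get("radius_cm", math.nan),
                       fps=meta.get("fps", math.nan))
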