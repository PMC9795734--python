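"""Reading and writing markerless pose-estimator track files.

Tracks come from a DeepLabCut-style export: a table with three stacked
header rows (scorer / bodyparts / coords) and, per body part, three columns
``x``, ``y``, ``likelihood``. The first column is the 0-based frame index.
One video may contain one or two Petri-dish arenas; each arena carries its
own set of the five tracked markers (three head markers, caudal fin, rod
center) and is analyzed independently.

Coordinates are image pixels (origin top-left, y increasing downward).
All downstream distances are computed in centimeters after calibration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Roles every arena must provide, in canonical order.
MARKERS = ("head_left", "head_center", "head_right", "caudal", "rod")

COORDS = ("x", "y", "likelihood")

DEFAULT_SCORER = "vabtrack"


class PoseDialectError(ValueError):
    """Raised when a track file does not follow the three-header dialect."""


def _identity_mapping() -> dict[str, dict[str, str]]:
    return {"arena1": {m: m for m in MARKERS}}


@dataclass
class SessionConfig:
    """Analysis settings for one recording session.

    Parameters
    ----------
    confidence_threshold:
        Per-marker likelihood below which a frame is flagged for repair.
    radius_cm:
        Cutoff radius around the rod defining an approach (the zone whose
        entries are counted as NOA and whose occupancy is DIR).
    fps:
        Video frame rate, frames per second.
    pixels_per_cm:
        Direct spatial calibration; if absent it can be derived from
        ``arena_diameter_cm`` plus the arena extent in pixels.
    arenas:
        Mapping ``arena_id -> {role -> bodypart label}`` assigning the file's
        bodypart labels to the five marker roles of each arena.
    """

    confidence_threshold: float = 0.92
    radius_cm: float = 1.3
    fps: float = 20.0
    pixels_per_cm: float | None = None
    arena_diameter_cm: float | None = None
    arena_span_px: float | None = None
    arenas: dict[str, dict[str, str]] = field(default_factory=_identity_mapping)
    min_gap_frames: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.confidence_threshold < 1.0:
            raise ValueError("confidence_threshold must be in (0, 1)")
        if self.radius_cm <= 0:
            raise ValueError("radius_cm must be positive")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        for arena_id, mapping in self.arenas.items():
            missing = [m for m in MARKERS if m not in mapping]
            if missing:
                raise ValueError(
                    f"arena {arena_id!r} mapping lacks roles: {missing}"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SessionConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "confidence_threshold": self.confidence_threshold,
            "radius_cm": self.radius_cm,
            "fps": self.fps,
            "pixels_per_cm": self.pixels_per_cm,
            "arena_diameter_cm": self.arena_diameter_cm,
            "arena_span_px": self.arena_span_px,
            "arenas": self.arenas,
            "min_gap_frames": self.min_gap_frames,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class TrackSet:
    """Per-frame (x, y, likelihood) records for one arena's five markers.

    ``data`` has a two-level column index ``(marker role, coord)`` with the
    roles of :data:`MARKERS` and coords x / y / likelihood; rows are frames,
    indexed 0..n-1.
    """

    data: pd.DataFrame
    fps: float
    pixels_per_cm: float | None = None
    arena_id: str = "arena1"

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.pixels_per_cm is not None and self.pixels_per_cm <= 0:
            raise ValueError("pixels_per_cm must be positive")
        cols = self.data.columns
        if cols.nlevels != 2:
            raise ValueError("TrackSet data needs (marker, coord) columns")
        for m in MARKERS:
            for c in COORDS:
                if (m, c) not in cols:
                    raise ValueError(f"missing column ({m}, {c})")
        lik = self.data.loc[:, (list(MARKERS), "likelihood")].to_numpy()
        if len(lik) and (np.nanmin(lik) < 0 or np.nanmax(lik) > 1):
            raise ValueError("likelihood values must lie in [0, 1]")
        self.data = self.data.reset_index(drop=True)

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def xy_px(self, marker: str) -> np.ndarray:
        """(n_frames, 2) pixel coordinates of one marker."""
        return self.data.loc[:, [(marker, "x"), (marker, "y")]].to_numpy(float)

    def xy_cm(self, marker: str) -> np.ndarray:
        if self.pixels_per_cm is None:
            raise ValueError(
                "TrackSet is uncalibrated: set pixels_per_cm (directly or via "
                "derive_calibration) before computing distances in cm"
            )
        return self.xy_px(marker) / self.pixels_per_cm

    def likelihood(self, marker: str) -> np.ndarray:
        return self.data.loc[:, (marker, "likelihood")].to_numpy(float)

    def min_likelihood(self) -> np.ndarray:
        """Per-frame minimum likelihood over the arena's five markers."""
        lik = self.data.loc[:, (list(MARKERS), "likelihood")].to_numpy(float)
        return lik.min(axis=1) if len(lik) else np.empty(0)

    def with_data(self, data: pd.DataFrame) -> "TrackSet":
        return replace(self, data=data)


def _empty_frame() -> pd.DataFrame:
    cols = pd.MultiIndex.from_product([MARKERS, COORDS])
    return pd.DataFrame(columns=cols, dtype=float)


def tracks_from_arrays(
    markers_xy: Mapping[str, np.ndarray],
    likelihoods: Mapping[str, np.ndarray],
    fps: float,
    pixels_per_cm: float | None = None,
    arena_id: str = "arena1",
) -> TrackSet:
    """Assemble a TrackSet from per-marker (n, 2) arrays and likelihoods."""
    frame = _empty_frame()
    n = None
    for m in MARKERS:
        xy = np.asarray(markers_xy[m], float)
        lik = np.asarray(likelihoods[m], float)
        if n is None:
            n = len(xy)
            frame = frame.reindex(range(n))
        if len(xy) != n or len(lik) != n:
            raise ValueError("all markers must share the same frame count")
        frame[(m, "x")] = xy[:, 0]
        frame[(m, "y")] = xy[:, 1]
        frame[(m, "likelihood")] = lik
    return TrackSet(frame, fps=fps, pixels_per_cm=pixels_per_cm,
                    arena_id=arena_id)


def read_tracks(path: str | Path, config: SessionConfig) -> list[TrackSet]:
    """Read a pose track file and split it into per-arena TrackSets.

    Both the comma-separated text dialect and its pandas-HDF5 equivalent are
    accepted; arenas are separated using ``config.arenas``, which maps each
    arena's five marker roles onto the bodypart labels found in the file.
    Markers for each arena are treated independently downstream.
    """
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        raw = pd.read_hdf(path)
        if not isinstance(raw, pd.DataFrame):
            raise PoseDialectError(f"{path}: HDF5 object is not a table")
    else:
        try:
            raw = pd.read_csv(path, header=[0, 1, 2], index_col=0)
        except pd.errors.EmptyDataError:
            raise PoseDialectError(f"{path}: file is empty") from None
        except (pd.errors.ParserError, ValueError) as exc:
            raise PoseDialectError(
                f"{path}: malformed header — expected three stacked header "
                f"rows (scorer / bodyparts / coords) ({exc})"
            ) from None
    if raw.columns.nlevels != 3:
        raise PoseDialectError(
            f"{path}: expected 3 column header levels "
            f"(scorer / bodyparts / coords), found {raw.columns.nlevels}"
        )
    # Collapse the scorer level; bodypart labels are what configs refer to.
    table = raw.copy()
    table.columns = pd.MultiIndex.from_tuples(
        [(bp, coord) for _, bp, coord in raw.columns]
    )
    coords_seen = {c for _, c in table.columns}
    if not {"x", "y", "likelihood"} <= coords_seen:
        raise PoseDialectError(
            f"{path}: coords header must contain x, y and likelihood; "
            f"found {sorted(coords_seen)}"
        )

    out: list[TrackSet] = []
    for arena_id, mapping in config.arenas.items():
        frame = _empty_frame().reindex(range(len(table)))
        counts = set()
        for role, bodypart in mapping.items():
            for coord in COORDS:
                if (bodypart, coord) not in table.columns:
                    raise PoseDialectError(
                        f"{path}: marker column {bodypart!r}/{coord} for role "
                        f"{role!r} (arena {arena_id!r}) is missing"
                    )
                col = table[(bodypart, coord)].astype(float)
                counts.add(int(col.notna().sum()))
                frame[(role, coord)] = col.to_numpy()
        if len(counts) > 1:
            raise PoseDialectError(
                f"{path}: ragged frame counts across markers of arena "
                f"{arena_id!r}: {sorted(counts)}"
            )
        out.append(
            TrackSet(frame, fps=config.fps,
                     pixels_per_cm=config.pixels_per_cm, arena_id=arena_id)
        )
    return out


def write_tracks(
    tracks: TrackSet | Sequence[TrackSet],
    path: str | Path,
    scorer: str = DEFAULT_SCORER,
) -> None:
    """Write one or more TrackSets as a three-header pose CSV.

    A single TrackSet keeps the canonical role names as bodypart labels; when
    several arenas share a file each label is suffixed ``_<arena_id>``.
    Coordinates round-trip losslessly through :func:`read_tracks`.
    """
    sets = [tracks] if isinstance(tracks, TrackSet) else list(tracks)
    ids = [t.arena_id for t in sets]
    if len(set(ids)) != len(ids):
        raise ValueError(f"ambiguous merge: duplicate arena_id in {ids}")
    pieces = []
    for ts in sets:
        suffix = "" if len(sets) == 1 else f"_{ts.arena_id}"
        piece = ts.data.copy()
        piece.columns = pd.MultiIndex.from_tuples(
            [(scorer, f"{m}{suffix}", c) for m, c in ts.data.columns],
            names=["scorer", "bodyparts", "coords"],
        )
        pieces.append(piece)
    merged = pd.concat(pieces, axis=1)
    merged.index.name = None
    merged.to_csv(path)


def arena_mapping_for_file(
    arena_ids: Sequence[str], single: bool | None = None
) -> dict[str, dict[str, str]]:
    """Mapping matching :func:`write_tracks` naming for the given arenas."""
    if single is None:
        single = len(arena_ids) == 1
    return {
        aid: {m: (m if single else f"{m}_{aid}") for m in MARKERS}
        for aid in arena_ids
    }


def derive_calibration(config: SessionConfig, tracks: TrackSet) -> float:
    """Resolve the pixels-per-cm scale for one arena.

    An explicit ``pixels_per_cm`` wins. Otherwise the arena's physical
    diameter (``arena_diameter_cm``) is combined with its pixel extent —
    either ``arena_span_px`` from the config or, as a fallback, the span of
    the fish markers' coordinates (a slight underestimate of the true arena
    diameter, since the fish does not touch the wall). When both sources are
    available and disagree by more than 5 % a warning is logged and the
    explicit value wins.
    """
    derived = None
    if config.arena_diameter_cm is not None:
        span = config.arena_span_px
        if span is None and tracks.n_frames > 0:
            xy = np.concatenate(
                [tracks.xy_px(m) for m in MARKERS if m != "rod"]
            )
            span = float(max(np.ptp(xy[:, 0]), np.ptp(xy[:, 1])))
        if span and span > 0:
            derived = span / config.arena_diameter_cm
    if config.pixels_per_cm is not None:
        if derived is not None:
            rel = abs(derived - config.pixels_per_cm) / config.pixels_per_cm
            if rel > 0.05:
                warnings.warn(
                    f"calibration sources disagree by {rel:.1%} "
                    f"(explicit {config.pixels_per_cm:.3g} px/cm vs derived "
                    f"{derived:.3g} px/cm); using the explicit value",
                    stacklevel=2,
                )
        return float(config.pixels_per_cm)
    if derived is not None:
        return float(derived)
    raise ValueError(
        "no calibration source: provide pixels_per_cm, or arena_diameter_cm "
        "together with arena_span_px (or tracks to estimate the span from)"
    )
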