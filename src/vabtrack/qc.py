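"""Confidence-based frame flagging and whole-frame linear interpolation.

A frame is unreliable when any of the arena's five markers falls below the
pose estimator's confidence threshold (default 0.92). For every maximal run
of such frames, every marker's x and y are linearly interpolated between the
last reliable frame before the run and the first reliable frame after it —
the whole frame is replaced, not just the failing marker. Runs touching the
session boundary have a single anchor and are filled with that anchor's
values (constant extrapolation), which is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .trackio import COORDS, MARKERS, TrackSet

logger = logging.getLogger(__name__)


def flag_low_confidence(tracks: TrackSet, threshold: float = 0.92) -> np.ndarray:
    """Boolean mask, true where any marker's likelihood is below threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    if tracks.n_frames == 0:
        return np.zeros(0, dtype=bool)
    return tracks.min_likelihood() < threshold


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) with stop exclusive."""
    if mask.size == 0 or not mask.any():
        return []
    padded = np.diff(np.concatenate(([0], mask.astype(int), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return list(zip(starts.tolist(), stops.tolist()))


@dataclass
class QCReport:
    n_frames: int
    n_flagged: int
    runs: list[tuple[int, int]]
    boundary_runs: int

    @property
    def run_lengths(self) -> list[int]:
        return [stop - start for start, stop in self.runs]


def qc_report(mask: np.ndarray) -> QCReport:
    runs = _runs(np.asarray(mask, bool))
    n = len(mask)
    boundary = sum(1 for s, e in runs if s == 0 or e == n)
    return QCReport(n_frames=n, n_flagged=int(np.sum(mask)), runs=runs,
                    boundary_runs=boundary)


def interpolate_frames(
    tracks: TrackSet,
    mask: np.ndarray,
    repaired_likelihood: float | None = None,
) -> TrackSet:
    """Repair flagged frames by linear interpolation of all markers.

    Every marker's x and y in a flagged run are interpolated between the
    anchor frames immediately before and after the run; unflagged frames are
    untouched. Leading/trailing runs are filled from their single anchor.
    Repaired frames' likelihoods are set to ``repaired_likelihood`` (when
    given) so their provenance survives a round-trip through track files.
    """
    mask = np.asarray(mask, bool)
    if mask.shape != (tracks.n_frames,):
        raise ValueError("mask length must equal the TrackSet frame count")
    if not mask.any():
        return tracks.with_data(tracks.data.copy())
    if mask.all():
        raise ValueError(
            "every frame is below the confidence threshold: no reliable "
            "anchor frames to interpolate between"
        )

    idx = np.arange(len(mask))
    good = idx[~mask]
    bad = idx[mask]
    data = tracks.data.copy()
    for m in MARKERS:
        for coord in ("x", "y"):
            col = data[(m, coord)].to_numpy(float).copy()
            # np.interp holds the nearest anchor constant beyond the ends,
            # which is exactly the single-anchor boundary rule.
            col[bad] = np.interp(bad, good, col[good])
            data[(m, coord)] = col
        if repaired_likelihood is not None:
            lik = data[(m, "likelihood")].to_numpy(float).copy()
            lik[bad] = repaired_likelihood
            data[(m, "likelihood")] = lik

    report = qc_report(mask)
    if report.boundary_runs:
        lengths = [e - s for s, e in report.runs
                   if s == 0 or e == len(mask)]
        logger.warning(
            "%d boundary run(s) of flagged frames (lengths %s) filled by "
            "constant extrapolation from the nearest reliable frame",
            report.boundary_runs, lengths,
        )
    logger.info(
        "interpolated %d/%d frames in %d run(s)",
        report.n_flagged, report.n_frames, len(report.runs),
    )
    return tracks.with_data(data)


def clean_tracks(
    tracks: TrackSet, threshold: float = 0.92
) -> tuple[TrackSet, QCReport]:
    """Flag sub-threshold frames and repair them; returns tracks + report."""
    mask = flag_low_confidence(tracks, threshold)
    report = qc_report(mask)
    if mask.any():
        tracks = interpolate_frames(tracks, mask,
                                    repaired_likelihood=threshold)
    return tracks, report
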