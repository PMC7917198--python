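"""Per-track migration statistics and wound-relative classification.

The scalar track measures are the standard ones of wound-recruitment
assays:

* net displacement  d_net = d(p_1, p_N)                    (μm)
* total displacement d_tot = Σ_i d(p_i, p_{i+1})           (μm)
* meandering index  M.I. = d_net / d_tot                   (unitless, [0, 1])
* mean speed        v̄ = d_tot / elapsed time               (μm/min)

together with the wound-relative rules: shortest Euclidean distance to the
wound-edge polyline, the distant (> 200 μm at the first frame) versus
local-resident split, arrival/retention within 20 μm of the wound, and
recruited-cell counting within a 200 μm band.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracks import Cohort, Track, WoundFrame

__all__ = [
    "net_displacement",
    "total_displacement",
    "meandering_index",
    "mean_speed",
    "distance_to_wound",
    "classify_track",
    "arrival_status",
    "count_recruited",
    "ArrivalStatus",
    "TrackSummary",
    "summarize_track",
    "summarize_cohort",
]

logger = logging.getLogger(__name__)

DISTANT_THRESHOLD_UM = 200.0
ARRIVAL_RADIUS_UM = 20.0
RECRUITMENT_BAND_UM = 200.0


def net_displacement(track: Track) -> float:
    """Euclidean distance between the first and final position, μm."""
    return float(np.linalg.norm(track.positions[-1] - track.positions[0]))


def total_displacement(track: Track) -> float:
    """Sum of Euclidean step lengths between successive recorded frames, μm.

    When a cell was undetected for some frames the step spans the gap; no
    interpolation is invented, so this is a lower bound on path length.
    """
    steps = np.diff(track.positions, axis=0)
    return float(np.linalg.norm(steps, axis=1).sum())


def meandering_index(track: Track) -> float:
    """d_net / d_tot; 1 for straight runs, → 0 for confined wandering.

    Undefined for a perfectly stationary cell (d_tot = 0): returns NaN and
    logs, so the track can be excluded from group statistics rather than
    coerced to 0 or 1.
    """
    d_tot = total_displacement(track)
    if d_tot == 0.0:
        logger.warning(
            "track %r is stationary; meandering index undefined", track.track_id
        )
        return math.nan
    return net_displacement(track) / d_tot


def mean_speed(track: Track) -> float:
    """Total displacement divided by elapsed time, μm/min.

    Elapsed time uses true frame indices, so gaps count toward time; for
    contiguous frames this equals the mean of per-step speeds.
    """
    return total_displacement(track) / track.duration


def distance_to_wound(points: np.ndarray, wound: WoundFrame) -> np.ndarray | float:
    """Shortest Euclidean distance from point(s) to the wound-edge polyline, μm.

    For each point, the minimum over segments of the distance to the
    orthogonal projection onto the segment, clamped to its endpoints.
    Accepts a single ``(2,)`` point (returns a float) or ``(n, 2)`` points
    (returns an ``(n,)`` array).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    a = wound.wound_edge[:-1]  # (m, 2) segment starts
    b = wound.wound_edge[1:]  # (m, 2) segment ends
    ab = b - a  # (m, 2)
    denom = np.einsum("md,md->m", ab, ab)  # squared segment lengths, > 0
    ap = pts[:, None, :] - a[None, :, :]  # (n, m, 2)
    t = np.clip(np.einsum("nmd,md->nm", ap, ab) / denom, 0.0, 1.0)
    foot = a[None, :, :] + t[..., None] * ab[None, :, :]
    d = np.linalg.norm(pts[:, None, :] - foot, axis=2).min(axis=1)
    if np.asarray(points).ndim == 1:
        return float(d[0])
    return d


def classify_track(
    track: Track, wound: WoundFrame, threshold: float = DISTANT_THRESHOLD_UM
) -> str:
    """Classify by the starting location in the first frame of the movie.

    Distance strictly greater than ``threshold`` → ``"distant"``; within a
    distance of up to ``threshold`` (inclusive) → ``"local_resident"``.
    Only the first-frame position matters, so cells that later travel far
    keep their starting category.
    """
    d0 = distance_to_wound(track.positions[0], wound)
    return "distant" if d0 > threshold else "local_resident"


@dataclass(frozen=True)
class ArrivalStatus:
    """Whether a cell reached the wound band, when, and whether it stayed."""

    arrived: bool
    first_arrival_time: float | None  # minutes from the first movie frame
    stayed: bool


def arrival_status(
    track: Track, wound: WoundFrame, radius: float = ARRIVAL_RADIUS_UM
) -> ArrivalStatus:
    """Arrival = any frame with wound distance ≤ ``radius`` (inclusive).

    ``first_arrival_time`` is the time of the earliest such frame in
    minutes; ``stayed`` requires every subsequent frame to remain within
    the radius (retention at the wound).
    """
    d = distance_to_wound(track.positions, wound)
    within = d <= radius
    if not within.any():
        return ArrivalStatus(False, None, False)
    first = int(np.argmax(within))
    stayed = bool(within[first:].all())
    return ArrivalStatus(True, float(track.frames[first] * track.frame_interval), stayed)


def count_recruited(
    points: np.ndarray, wound: WoundFrame, band: float = RECRUITMENT_BAND_UM
) -> int:
    """Number of cells within ``band`` μm of the wound edge (inclusive)."""
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return 0
    d = distance_to_wound(np.atleast_2d(pts), wound)
    return int(np.count_nonzero(d <= band))


@dataclass(frozen=True)
class TrackSummary:
    track_id: str
    group: str
    cell_type: str
    n_frames: int
    d_net: float
    d_tot: float
    meandering_index: float
    mean_speed: float
    mean_v_ap: float
    category: str
    arrived: bool
    first_arrival_time: float | None
    stayed_at_wound: bool


def summarize_track(
    track: Track,
    wound: WoundFrame,
    *,
    distant_threshold: float = DISTANT_THRESHOLD_UM,
    arrival_radius: float = ARRIVAL_RADIUS_UM,
) -> TrackSummary:
    """All scalar metrics for one track."""
    from .kinetics import v_ap  # local import: kinetics depends on tracks only

    arr = arrival_status(track, wound, radius=arrival_radius)
    return TrackSummary(
        track_id=track.track_id,
        group=track.group,
        cell_type=str(track.cell_type.value),
        n_frames=track.n_frames,
        d_net=net_displacement(track),
        d_tot=total_displacement(track),
        meandering_index=meandering_index(track),
        mean_speed=mean_speed(track),
        mean_v_ap=v_ap(track, wound).mean_v_ap,
        category=classify_track(track, wound, threshold=distant_threshold),
        arrived=arr.arrived,
        first_arrival_time=arr.first_arrival_time,
        stayed_at_wound=arr.stayed,
    )


def summarize_cohort(
    cohort: Cohort,
    wound: WoundFrame,
    *,
    distant_threshold: float = DISTANT_THRESHOLD_UM,
    arrival_radius: float = ARRIVAL_RADIUS_UM,
) -> pd.DataFrame:
    """Per-track summary table for a whole cohort (one row per track)."""
    rows = [
        summarize_track(
            t,
            wound,
            distant_threshold=distant_threshold,
            arrival_radius=arrival_radius,
        ).__dict__
        for t in cohort
    ]
    return pd.DataFrame(rows)
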