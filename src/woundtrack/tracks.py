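"""Core data model for leukocyte migration analysis.

Internal canonical units are micrometres (positions, distances) and minutes
(time).  A :class:`Track` is one cell's time-ordered 2D positions; a
:class:`WoundFrame` fixes the wound-edge geometry and the anteroposterior
(AP) body axis that give distances and axial velocities their meaning; a
:class:`Cohort` is a group of tracks imaged together (one genotype, one
wound, one frame rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

import numpy as np

__all__ = ["CellType", "Track", "WoundFrame", "Cohort"]


class CellType(str, Enum):
    NEUTROPHIL = "neutrophil"
    MACROPHAGE = "macrophage"


@dataclass(frozen=True)
class Track:
    """One cell's trajectory: strictly increasing frame indices and 2D
    positions in μm.

    Parameters
    ----------
    track_id
        Opaque identifier (kept as given; compared as a string).
    frames
        Integer frame indices, strictly increasing.  Gaps are allowed: a
        cell undetected for some frames simply has no row there.
    positions
        ``(n, 2)`` array of positions in μm, same order as ``frames``.
    cell_type
        ``"neutrophil"`` or ``"macrophage"``.
    group
        Free experimental label (e.g. genotype).
    frame_interval
        Minutes per frame (default 1.0, i.e. one image per minute).
    """

    track_id: str
    frames: np.ndarray
    positions: np.ndarray
    cell_type: CellType = CellType.NEUTROPHIL
    group: str = ""
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.int64)
        positions = np.asarray(self.positions, dtype=np.float64)
        if frames.ndim != 1 or frames.size < 2:
            raise ValueError(
                f"track {self.track_id!r}: needs >=2 frames, got {frames.size}"
            )
        if positions.shape != (frames.size, 2):
            raise ValueError(
                f"track {self.track_id!r}: positions must be ({frames.size}, 2), "
                f"got {positions.shape}"
            )
        if np.any(np.diff(frames) <= 0):
            raise ValueError(f"track {self.track_id!r}: frames not strictly increasing")
        if not np.all(np.isfinite(positions)):
            raise ValueError(f"track {self.track_id!r}: non-finite positions")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "positions", positions)
        object.__setattr__(self, "cell_type", CellType(self.cell_type))
        frames.setflags(write=False)
        positions.setflags(write=False)

    @property
    def n_frames(self) -> int:
        return int(self.frames.size)

    @property
    def times(self) -> np.ndarray:
        """Time of each frame in minutes, relative to frame 0 of the movie."""
        return self.frames * self.frame_interval

    @property
    def duration(self) -> float:
        """Elapsed time from first to last frame, minutes."""
        return float((self.frames[-1] - self.frames[0]) * self.frame_interval)


@dataclass(frozen=True)
class WoundFrame:
    """Wound-edge geometry plus the anteroposterior axis.

    The wound edge is a polyline in the same μm coordinate system as the
    tracks (commonly a single near-vertical segment at the cut).  The AP
    axis is a unit vector along the larval body axis, oriented so that its
    positive direction points toward the wound; with the spine taken as the
    ordinate this fixes the sign of axial velocities (positive = woundward).
    """

    wound_edge: np.ndarray
    ap_axis: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        edge = np.asarray(self.wound_edge, dtype=np.float64)
        axis = np.asarray(self.ap_axis, dtype=np.float64)
        origin = np.asarray(self.origin, dtype=np.float64)
        if edge.ndim != 2 or edge.shape[0] < 2 or edge.shape[1] != 2:
            raise ValueError("wound_edge must be an (m>=2, 2) polyline")
        seg_len = np.linalg.norm(np.diff(edge, axis=0), axis=1)
        if np.any(seg_len == 0):
            raise ValueError("wound_edge has zero-length segments")
        norm = np.linalg.norm(axis)
        if axis.shape != (2,) or norm == 0:
            raise ValueError("ap_axis must be a nonzero 2-vector")
        object.__setattr__(self, "wound_edge", edge)
        object.__setattr__(self, "ap_axis", axis / norm)
        object.__setattr__(self, "origin", origin)
        edge.setflags(write=False)
        origin.setflags(write=False)


@dataclass(frozen=True)
class Cohort:
    """Tracks sharing one wound frame, one group label and one frame rate.

    ``t_start`` is the experiment start in minutes post wounding; imaging in
    the assay this package quantifies begins at 1 hour post wounding, hence
    the default of 60.
    """

    tracks: tuple[Track, ...]
    t_start: float = 60.0

    def __init__(self, tracks: Iterable[Track], t_start: float = 60.0) -> None:
        tracks = tuple(tracks)
        if not tracks:
            raise ValueError("cohort must contain at least one track")
        intervals = {t.frame_interval for t in tracks}
        if len(intervals) != 1:
            raise ValueError(f"tracks mix frame intervals: {sorted(intervals)}")
        object.__setattr__(self, "tracks", tracks)
        object.__setattr__(self, "t_start", float(t_start))

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    @property
    def frame_interval(self) -> float:
        return self.tracks[0].frame_interval

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(sorted({t.group for t in self.tracks}))

    def select(self, group: str | None = None, cell_type: str | None = None) -> "Cohort":
        """Sub-cohort by group label and/or cell type."""
        keep = [
            t
            for t in self.tracks
            if (group is None or t.group == group)
            and (cell_type is None or t.cell_type == CellType(cell_type))
        ]
        return Cohort(keep, t_start=self.t_start)
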