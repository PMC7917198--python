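"""Reading and writing track tables and experiment configuration.

All unit conversion happens here: files may carry pixel coordinates and
1-based frame numbers (the Fiji manual-tracking export does both); the
in-memory model is always μm, minutes and 0-based frames.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from .tracks import Cohort, Track, WoundFrame

__all__ = [
    "DIALECTS",
    "ExperimentConfig",
    "load_config",
    "read_tracks",
    "write_summary",
    "read_summary",
    "write_curve",
]

logger = logging.getLogger(__name__)

#: Known CSV dialects: candidate column names (matched case-insensitively,
#: first hit wins) and the frame-index base of the file format.  The Fiji
#: manual-tracking plugin exports ``Track n°/Slice n°/X/Y`` with 1-based
#: slices; ``generic_csv`` covers plain ``track_id,frame,x,y`` exports.
DIALECTS: dict[str, dict] = {
    "manual_tracking_csv": {
        "track": ("track n°", "track no", "track n", "track"),
        "frame": ("slice n°", "slice no", "slice n", "slice", "frame"),
        "x": ("x",),
        "y": ("y",),
        "frame_base": 1,
    },
    "generic_csv": {
        "track": ("track_id", "track", "id"),
        "frame": ("frame", "t", "time"),
        "x": ("x", "position_x"),
        "y": ("y", "position_y"),
        "frame_base": 0,
    },
}


def _resolve_column(df: pd.DataFrame, candidates: Sequence[str], what: str) -> str:
    lowered = {c.strip().lower(): c for c in df.columns}
    for cand in candidates:
        if cand in lowered:
            return lowered[cand]
    raise ValueError(
        f"could not find a {what!r} column among {list(df.columns)}; "
        f"tried {list(candidates)}"
    )


def read_tracks(
    path: str | Path,
    dialect: str = "manual_tracking_csv",
    scale: float = 1.0,
    *,
    cell_type: str = "neutrophil",
    group: str = "",
    frame_interval: float = 1.0,
    t_start: float = 60.0,
    column_map: Mapping[str, str] | None = None,
    frame_base: int | None = None,
) -> Cohort:
    """Read a per-cell, per-frame position table into a :class:`Cohort`.

    Parameters
    ----------
    path
        CSV file, comma- or tab-delimited (auto-detected), UTF-8.
    dialect
        ``"manual_tracking_csv"`` (Fiji manual-tracking export, 1-based
        slices) or ``"generic_csv"`` (0-based frames).
    scale
        μm per coordinate unit; pixel coordinates are multiplied by this.
        The pixel size is never inferable from the table, so it must be
        supplied whenever the file is in pixels.
    column_map
        Optional overrides ``{"track": ..., "frame": ..., "x": ..., "y": ...}``
        naming the actual file columns.
    frame_base
        Override the dialect's frame-index base.

    Tracks with fewer than two usable frames are dropped with a logged
    warning; a duplicated (track, frame) pair is a hard error.  Returned
    tracks are ordered by their identifier so the result is independent of
    row order in the file.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; options: {sorted(DIALECTS)}")
    if not scale > 0:
        raise ValueError("scale must be > 0 μm per unit")
    spec = DIALECTS[dialect]
    df = pd.read_csv(path, sep=None, engine="python", encoding="utf-8")
    cols = {}
    for key in ("track", "frame", "x", "y"):
        if column_map and key in column_map:
            if column_map[key] not in df.columns:
                raise ValueError(f"column {column_map[key]!r} not in file")
            cols[key] = column_map[key]
        else:
            cols[key] = _resolve_column(df, spec[key], key)
    lowered = [c.strip().lower() for c in df.columns]
    if "z" in lowered:
        logger.warning("%s: z column present; 2D analysis ignores it", path)

    base = spec["frame_base"] if frame_base is None else frame_base
    table = pd.DataFrame(
        {
            "track": df[cols["track"]].astype(str),
            "frame": pd.to_numeric(df[cols["frame"]]).astype(np.int64) - base,
            "x": pd.to_numeric(df[cols["x"]]) * scale,
            "y": pd.to_numeric(df[cols["y"]]) * scale,
        }
    )
    dup = table.duplicated(subset=["track", "frame"], keep=False)
    if dup.any():
        row = table[dup].iloc[0]
        raise ValueError(
            f"duplicate (track, frame) row: track={row['track']!r} frame={row['frame']}"
        )

    tracks: list[Track] = []
    n_dropped = 0
    for tid, sub in table.groupby("track", sort=True):
        sub = sub.sort_values("frame")
        if len(sub) < 2:
            n_dropped += 1
            logger.warning("dropping track %r: only %d frame(s)", tid, len(sub))
            continue
        tracks.append(
            Track(
                track_id=str(tid),
                frames=sub["frame"].to_numpy(),
                positions=sub[["x", "y"]].to_numpy(),
                cell_type=cell_type,
                group=group,
                frame_interval=frame_interval,
            )
        )
    if n_dropped:
        logger.warning("dropped %d track(s) with <2 frames", n_dropped)
    if not tracks:
        raise ValueError(f"{path}: no usable tracks (>=2 frames each)")
    return Cohort(tracks, t_start=t_start)


#: Stable column order of the per-track summary table.
SUMMARY_COLUMNS = [
    "track_id",
    "group",
    "cell_type",
    "n_frames",
    "d_net",
    "d_tot",
    "meandering_index",
    "mean_speed",
    "mean_v_ap",
    "category",
    "arrived",
    "first_arrival_time",
    "stayed_at_wound",
]


def write_summary(summaries: pd.DataFrame, path: str | Path) -> None:
    """Write a per-track metrics table to CSV with a stable column order.

    Floats are written at full precision, so a write → read round trip is
    lossless.  An empty table produces a header-only file.
    """
    df = summaries.copy()
    cols = [c for c in SUMMARY_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, index=False)


def read_summary(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_summary`."""
    return pd.read_csv(path)


def write_curve(curve: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort curve (MSD or axial velocity over time) as CSV with
    columns ``(lag_or_time, mean, sem, n)``."""
    expected = ["lag_or_time", "mean", "sem", "n"]
    missing = [c for c in expected if c not in curve.columns]
    if missing:
        raise ValueError(f"curve table lacks columns {missing}")
    curve[expected].to_csv(path, index=False)


class ExperimentConfig(BaseModel):
    """Validated experiment configuration (JSON or YAML file).

    Carries the wound geometry, AP axis, unit scale, frame interval and the
    analysis thresholds.  Distances are μm, times minutes.
    """

    wound_edge: list[tuple[float, float]] = Field(min_length=2)
    ap_axis: tuple[float, float]
    origin: tuple[float, float] = (0.0, 0.0)
    scale: float = Field(1.0, gt=0, description="μm per coordinate unit")
    frame_interval: float = Field(1.0, gt=0, description="minutes per frame")
    t_start: float = Field(60.0, ge=0, description="minutes post wounding at frame 0")
    distant_threshold: float = Field(200.0, gt=0, description="distant/local split, μm")
    arrival_radius: float = Field(20.0, gt=0, description="arrival band at the wound, μm")
    recruitment_band: float = Field(200.0, gt=0, description="recruited-cell count band, μm")
    near_wound_band: float = Field(50.0, gt=0, description="auxiliary near-wound band, μm")

    @field_validator("ap_axis")
    @classmethod
    def _nonzero_axis(cls, v: tuple[float, float]) -> tuple[float, float]:
        if float(np.hypot(*v)) == 0.0:
            raise ValueError("ap_axis must be nonzero")
        return v

    def wound_frame(self) -> WoundFrame:
        return WoundFrame(
            wound_edge=np.asarray(self.wound_edge, dtype=float),
            ap_axis=np.asarray(self.ap_axis, dtype=float),
            origin=np.asarray(self.origin, dtype=float),
        )


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate a JSON/YAML experiment configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return ExperimentConfig.model_validate(data)
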