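"""Cohort-level time series: wound distance and anteroposterior velocity.

The anteroposterior (AP) velocity V_AP is the per-step velocity projected
on the larval body axis after rotating all tracks so the spines align —
operationally a dot product with the unit AP axis of the wound frame, with
the positive direction toward the wound.  The cohort time course pools the
per-step values of all cells and averages them over three consecutive time
frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import distance_to_wound
from .tracks import Cohort, Track, WoundFrame

__all__ = ["APProjection", "distance_series", "v_ap", "vap_over_time", "cohort_distance"]

VAP_WINDOW_FRAMES = 3


def distance_series(track: Track, wound: WoundFrame) -> pd.Series:
    """Distance to the wound edge at every recorded frame, μm.

    Indexed by time in minutes (frame × frame interval); the raw material
    of per-cell "spaghetti" distance plots and of the cohort mean distance.
    """
    d = distance_to_wound(track.positions, wound)
    return pd.Series(d, index=track.times, name=track.track_id)


@dataclass(frozen=True)
class APProjection:
    """Per-step AP-axis velocity of one track, μm/min, positive woundward.

    ``step_frames`` holds the frame index at which each step starts;
    ``step_times`` the corresponding time in minutes.
    """

    step_frames: np.ndarray
    v_ap_steps: np.ndarray
    frame_interval: float

    @property
    def step_times(self) -> np.ndarray:
        return self.step_frames * self.frame_interval

    @property
    def mean_v_ap(self) -> float:
        return float(self.v_ap_steps.mean())


def v_ap(track: Track, wound: WoundFrame) -> APProjection:
    """Project per-step velocities on the AP axis.

    Each step's v_AP is (displacement · AP unit vector) / elapsed time;
    steps spanning detection gaps use the true elapsed time.  The magnitude
    of each value is bounded by the step speed, with equality only for
    motion along the axis.
    """
    disp = np.diff(track.positions, axis=0)
    dt = np.diff(track.frames) * track.frame_interval
    vap_steps = (disp @ wound.ap_axis) / dt
    return APProjection(
        step_frames=track.frames[:-1].copy(),
        v_ap_steps=vap_steps,
        frame_interval=track.frame_interval,
    )


def vap_over_time(
    cohort: Cohort,
    wound: WoundFrame,
    *,
    window: int = VAP_WINDOW_FRAMES,
    sliding: bool = False,
) -> pd.DataFrame:
    """Cohort V_AP time course: pooled steps, 3-frame-window mean ± SEM.

    All cells' per-step v_AP values are pooled by the frame at which the
    step starts, then averaged over non-overlapping windows of ``window``
    consecutive frames (each cell-step weighted equally).  Returns columns
    ``(lag_or_time, mean, sem, n)`` with time at the window centre in
    minutes; a window containing no observation is reported as a gap
    (NaN mean, n=0), never as zero.

    ``sliding=True`` switches to a centred moving window of the same width
    (off by default; the non-overlapping binning is the canonical one).
    """
    if window < 1:
        raise ValueError("window must be >= 1 frame")
    frames_all, vals_all = [], []
    for tr in cohort:
        proj = v_ap(tr, wound)
        frames_all.append(proj.step_frames)
        vals_all.append(proj.v_ap_steps)
    frames = np.concatenate(frames_all)
    vals = np.concatenate(vals_all)
    dt = cohort.frame_interval
    f_min, f_max = int(frames.min()), int(frames.max())

    rows = []
    if not sliding:
        for start in range(f_min, f_max + 1, window):
            sel = (frames >= start) & (frames < start + window)
            centre = (start + (window - 1) / 2.0) * dt
            rows.append(_window_row(centre, vals[sel]))
    else:
        half = window // 2
        for f in range(f_min, f_max + 1):
            sel = (frames >= f - half) & (frames <= f + half)
            rows.append(_window_row(f * dt, vals[sel]))
    return pd.DataFrame(rows, columns=["lag_or_time", "mean", "sem", "n"])


def _window_row(time: float, v: np.ndarray) -> tuple[float, float, float, int]:
    n = int(v.size)
    if n == 0:
        return (time, np.nan, np.nan, 0)
    mean = float(v.mean())
    sem = float(v.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
    return (time, mean, sem, n)


def cohort_distance(cohort: Cohort, wound: WoundFrame) -> pd.DataFrame:
    """Mean ± SEM distance to the wound across cells at each frame time.

    The cohort average drawn through per-cell distance trajectories; cells
    without a recorded frame at a time point are excluded there.
    """
    series = [distance_series(t, wound) for t in cohort]
    wide = pd.concat(series, axis=1)
    n = wide.notna().sum(axis=1)
    mean = wide.mean(axis=1)
    sem = wide.std(axis=1, ddof=1) / np.sqrt(n.where(n > 0))
    out = pd.DataFrame(
        {"lag_or_time": wide.index, "mean": mean.values, "sem": sem.values, "n": n.values}
    )
    return out.reset_index(drop=True)
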