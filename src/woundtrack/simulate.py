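"""Synthetic leukocyte cohorts: persistent random walks with optional
wound-directed bias and retention at the wound.

The walker is a discrete correlated random walk.  Each minute the heading
angle receives a Gaussian turn of standard deviation √(2·dt/τ), so the
step-to-step heading correlation is exactly e^(−dt/τ) and the walk's MSD
converges to Fürth's formula for dt ≪ τ.  Step length is v·dt, optionally
modulated by per-step gamma noise of unit mean.  With bias b > 0 the
heading relaxes toward the woundward direction with weight b each step
(vector blend), producing chemotactic runs; cells that reach the arrest
radius are retained there.

Retention ("arrest") keeps a cell within the arrest radius while it keeps
stepping at full speed (its heading is reflected toward the wound whenever
a step would leave the band).  Wound-retained leukocytes keep crawling
along the margin — which is why chemotactic and control cohorts show the
same mean speed in this assay — so a zero-motion stop would distort every
speed statistic downstream.  ``arrest_mode="stop"`` provides the absorbing
full stop for comparison, and ``"none"`` disables arrest.

The generated cohorts use the same geometry conventions as the analysis:
a near-vertical wound edge, cells seeded in a band anterior to it, and the
AP axis pointing toward the wound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .metrics import distance_to_wound
from .tracks import Cohort, Track, WoundFrame

__all__ = [
    "SimulationConfig",
    "default_wound",
    "simulate_cohort",
    "DetectionMovie",
    "simulate_detection_movie",
]


def default_wound() -> WoundFrame:
    """Default geometry: vertical wound edge at x = 0 (spanning ±300 μm),
    cells anterior at x > 0, AP axis (−1, 0) pointing toward the wound."""
    return WoundFrame(
        wound_edge=np.array([[0.0, -300.0], [0.0, 300.0]]),
        ap_axis=np.array([-1.0, 0.0]),
        origin=np.array([0.0, 0.0]),
    )


class SimulationConfig(BaseModel):
    """Generative parameters for one synthetic cohort.

    Defaults emulate the quantified assay: 2 h movies at 1 min frame
    interval, ~25 tracked cells per group starting 250–500 μm from the
    wound, intrinsic speed 10 μm/min and persistence 5 min (diffusivity
    v²τ/2 = 250 μm²/min, the order measured for zebrafish leukocytes), and
    a 20 μm retention band at the wound.
    """

    model_config = ConfigDict(arbitrary_types_allowed=True)

    n_cells: int = Field(25, ge=1)
    duration: float = Field(120.0, gt=0, description="movie length, min")
    dt: float = Field(1.0, gt=0, description="frame interval, min")
    v_true: float = Field(10.0, gt=0, description="intrinsic speed, μm/min")
    tau_true: float = Field(5.0, gt=0, description="persistence time, min")
    bias: float = Field(0.0, ge=0.0, le=1.0, description="woundward heading weight")
    speed_cv: float = Field(
        0.0, ge=0.0, le=1.0, description="per-step speed CV (0 = canonical PRW)"
    )
    arrest_radius: float = Field(20.0, gt=0, description="retention band, μm")
    arrest_mode: Literal["confine", "stop", "none"] = "confine"
    leave_prob: float = Field(
        0.0, ge=0.0, le=1.0, description="per-frame probability of leaving retention"
    )
    start_band: tuple[float, float] = Field(
        (250.0, 500.0), description="initial wound distance range, μm"
    )
    start_spread: float = Field(250.0, ge=0, description="lateral seeding half-width, μm")
    seed: int = 0
    cell_type: str = "neutrophil"
    group: str = "simulated"
    t_start: float = Field(60.0, ge=0, description="minutes post wounding at frame 0")
    wound: WoundFrame = Field(default_factory=default_wound)

    @field_validator("start_band")
    @classmethod
    def _ordered_band(cls, v: tuple[float, float]) -> tuple[float, float]:
        if not (0 <= v[0] <= v[1]):
            raise ValueError("start_band must satisfy 0 <= lo <= hi")
        return v

    @property
    def n_frames(self) -> int:
        n = int(round(self.duration / self.dt)) + 1
        if n < 2:
            raise ValueError("duration/dt must give at least 2 frames")
        return n


def _woundward_units(points: np.ndarray, wound: WoundFrame) -> np.ndarray:
    """Unit vectors from each point toward its nearest wound-edge point."""
    a, b = wound.wound_edge[:-1], wound.wound_edge[1:]
    ab = b - a
    denom = np.einsum("md,md->m", ab, ab)
    ap = points[:, None, :] - a[None, :, :]
    t = np.clip(np.einsum("nmd,md->nm", ap, ab) / denom, 0.0, 1.0)
    foot = a[None, :, :] + t[..., None] * ab[None, :, :]
    diff = foot - points[:, None, :]
    d = np.linalg.norm(diff, axis=2)
    nearest = np.argmin(d, axis=1)
    vec = diff[np.arange(points.shape[0]), nearest]
    norm = np.linalg.norm(vec, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return vec / norm


def _unit(v: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(v, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return v / norm


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Simulate one cohort of correlated random walkers.

    Fully reproducible from ``config.seed``: the same configuration yields
    bit-identical cohorts.  Returns a :class:`Cohort` whose tracks share
    ``config.wound`` for analysis.
    """
    rng = np.random.default_rng(config.seed)
    n, n_frames, dt = config.n_cells, config.n_frames, config.dt
    wound = config.wound
    sigma_turn = np.sqrt(2.0 * dt / config.tau_true)

    # seed positions: wound distance in start_band along the AP axis,
    # lateral spread along the wound edge direction
    lateral = _unit(np.array([[-wound.ap_axis[1], wound.ap_axis[0]]]))[0]
    d0 = rng.uniform(config.start_band[0], config.start_band[1], size=n)
    off = rng.uniform(-config.start_spread, config.start_spread, size=n)
    pos = wound.origin - np.outer(d0, wound.ap_axis) + np.outer(off, lateral)

    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    retained = np.zeros(n, dtype=bool)
    # departed cells left the wound for good: no bias, no re-retention
    departed = np.zeros(n, dtype=bool)
    positions = np.empty((n_frames, n, 2))
    positions[0] = pos

    for k in range(1, n_frames):
        theta = theta + rng.normal(0.0, sigma_turn, size=n)
        heading = np.column_stack([np.cos(theta), np.sin(theta)])
        if config.bias > 0:
            toward = _woundward_units(pos, wound)
            free = ~retained & ~departed
            heading[free] = _unit(
                (1.0 - config.bias) * heading[free] + config.bias * toward[free]
            )
        if config.speed_cv > 0:
            shape = 1.0 / config.speed_cv**2
            speed = config.v_true * np.clip(
                rng.gamma(shape, 1.0 / shape, size=n), 0.2, 2.0
            )
        else:
            speed = np.full(n, config.v_true)

        step = heading * (speed * dt)[:, None]
        new_pos = pos + step

        if config.arrest_mode != "none" and config.bias > 0:
            if config.leave_prob > 0:
                leaving = retained & (rng.uniform(size=n) < config.leave_prob)
                retained[leaving] = False
                departed[leaving] = True
            if config.arrest_mode == "stop":
                new_pos[retained] = pos[retained]
            else:  # confine: reflect woundward any step that would exit the band
                exiting = retained & (
                    distance_to_wound(new_pos, wound) > config.arrest_radius
                )
                if exiting.any():
                    toward = _woundward_units(pos[exiting], wound)
                    new_pos[exiting] = pos[exiting] + toward * (speed[exiting] * dt)[:, None]
                    # realign heading with the actual motion
                    theta[exiting] = np.arctan2(toward[:, 1], toward[:, 0])
            newly = distance_to_wound(new_pos, wound) <= config.arrest_radius
            retained = retained | (newly & ~departed)

        pos = new_pos
        positions[k] = pos

    frames = np.arange(n_frames, dtype=np.int64)
    tracks = [
        Track(
            track_id=f"sim{i:03d}",
            frames=frames,
            positions=positions[:, i, :],
            cell_type=config.cell_type,
            group=config.group,
            frame_interval=dt,
        )
        for i in range(n)
    ]
    return Cohort(tracks, t_start=config.t_start)


@dataclass(frozen=True)
class DetectionMovie:
    """Per-frame detections with ground-truth cell identity.

    ``detections[t]`` is an ``(k_t, 2)`` μm array; ``ids[t]`` the matching
    ground-truth cell indices.  ``n_true_links`` counts consecutive-frame
    pairs of the same cell present in both frames — the denominator of link
    accuracy.
    """

    detections: tuple[np.ndarray, ...]
    ids: tuple[np.ndarray, ...]
    n_cells: int

    @property
    def n_frames(self) -> int:
        return len(self.detections)

    @property
    def n_true_links(self) -> int:
        total = 0
        for t in range(self.n_frames - 1):
            total += np.intersect1d(self.ids[t], self.ids[t + 1]).size
        return total


def simulate_detection_movie(
    config: SimulationConfig, miss_rate: float = 0.0
) -> DetectionMovie:
    """Turn a simulated cohort into per-frame detection sets with dropouts.

    Each cell is independently missed at each frame with probability
    ``miss_rate`` (≤ 0.3); ground-truth identities are retained so tracker
    output can be scored for link accuracy.  The dropout pattern is drawn
    from a stream derived from ``config.seed``, so it is reproducible and
    independent of the walk noise.
    """
    if not 0.0 <= miss_rate <= 0.3:
        raise ValueError("miss_rate must be in [0, 0.3]")
    cohort = simulate_cohort(config)
    drop_rng = np.random.default_rng([config.seed, 9173])
    detections, ids = [], []
    n_frames = cohort.tracks[0].n_frames
    all_pos = np.stack([t.positions for t in cohort.tracks], axis=1)  # (T, n, 2)
    for t in range(n_frames):
        keep = drop_rng.uniform(size=config.n_cells) >= miss_rate
        detections.append(all_pos[t][keep].copy())
        ids.append(np.flatnonzero(keep))
    return DetectionMovie(
        detections=tuple(detections), ids=tuple(ids), n_cells=config.n_cells
    )
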