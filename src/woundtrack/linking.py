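"""Minimal Viterbi global-linking tracker.

Joins per-frame detection sets into tracks with a global linking strategy:
tracks are created one at a time, each as the highest-scoring path through
the detection graph found by dynamic programming over frames (states are
the still-unused detections plus a birth/death state).  Scores are
log-likelihood-style: each claimed detection earns ``det_logp``, each link
pays a Gaussian motion cost −‖Δx‖²/(2kσ²) for a k-frame step (plus a
per-missed-frame gap penalty), and every track pays ``appear_logp`` and
``disappear_logp`` once.  Track creation stops when the best remaining
path no longer beats the appear+disappear floor.  Mitosis and apoptosis
are not modelled.

A "swaps" pass then repairs earlier links: for every pair of tracks and
every frame boundary it exchanges the tails when doing so raises the total
score, repeating to a fixed point, so the total score never decreases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .tracks import Track

__all__ = [
    "LinkScoreModel",
    "LinkedTrack",
    "link_detections",
    "swap_pass",
    "total_score",
    "link_accuracy",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LinkScoreModel:
    """Scoring parameters of the linker.

    ``sigma`` is the expected frame-to-frame movement in μm (the Gaussian
    motion model's scale); ``appear_logp``/``disappear_logp`` the
    log-probabilities of a track entering/leaving the field (≤ 0);
    ``det_logp`` the reward for explaining a detection as part of a track
    rather than noise (> 0, otherwise no track is ever worth creating);
    ``max_gap`` the longest detection gap a link may span, with
    ``gap_logp`` charged per missed frame.
    """

    sigma: float = 10.0
    appear_logp: float = -3.5
    disappear_logp: float = -3.5
    det_logp: float = 2.5
    max_gap: int = 2
    gap_logp: float = -2.5

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        if self.appear_logp > 0 or self.disappear_logp > 0:
            raise ValueError("appear_logp and disappear_logp must be <= 0")
        if self.max_gap < 1:
            raise ValueError("max_gap must be >= 1")

    def motion_score(self, p: np.ndarray, q: np.ndarray, k: int = 1) -> float:
        """Log-score of a k-frame step p→q: Gaussian with variance kσ² per
        axis, plus the gap penalty for the k−1 missed frames."""
        d2 = float(np.sum((np.asarray(q) - np.asarray(p)) ** 2))
        return -d2 / (2.0 * k * self.sigma**2) + (k - 1) * self.gap_logp


@dataclass(frozen=True)
class LinkedTrack:
    """A linked path: (frame, detection-index) pairs plus positions."""

    frames: tuple[int, ...]
    det_indices: tuple[int, ...]
    positions: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.frames)

    def path_score(self, model: LinkScoreModel) -> float:
        s = model.appear_logp + model.disappear_logp + model.det_logp * len(self.frames)
        for i in range(len(self.frames) - 1):
            k = self.frames[i + 1] - self.frames[i]
            s += model.motion_score(self.positions[i], self.positions[i + 1], k)
        return s

    def to_track(self, track_id: str, frame_interval: float = 1.0, **kwargs) -> Track:
        return Track(
            track_id=track_id,
            frames=np.asarray(self.frames, dtype=np.int64),
            positions=np.asarray(self.positions, dtype=float),
            frame_interval=frame_interval,
            **kwargs,
        )


def total_score(tracks: Sequence[LinkedTrack], model: LinkScoreModel) -> float:
    """Total model score of a track set (unused detections score 0)."""
    return float(sum(t.path_score(model) for t in tracks))


def _best_path(
    detections: Sequence[np.ndarray],
    used: list[np.ndarray],
    model: LinkScoreModel,
) -> tuple[float, list[tuple[int, int]]]:
    """Highest-scoring single path over unused detections (DP over frames).

    Returns the interior score (det + motion + gap terms, *excluding* the
    appear/disappear constants) and the path as (frame, index) pairs.
    """
    n_frames = len(detections)
    score: list[np.ndarray] = []
    back: list[list[tuple[int, int] | None]] = []
    for t in range(n_frames):
        pts = detections[t]
        s_t = np.full(pts.shape[0], -np.inf)
        b_t: list[tuple[int, int] | None] = [None] * pts.shape[0]
        free = ~used[t]
        for j in np.flatnonzero(free):
            best = model.det_logp  # start the path here (appear is constant)
            best_prev: tuple[int, int] | None = None
            for k in range(1, model.max_gap + 1):
                tp = t - k
                if tp < 0:
                    break
                prev_scores = score[tp]
                if prev_scores.size == 0:
                    continue
                for i in np.flatnonzero(np.isfinite(prev_scores)):
                    cand = (
                        prev_scores[i]
                        + model.motion_score(detections[tp][i], pts[j], k)
                        + model.det_logp
                    )
                    if cand > best:
                        best = cand
                        best_prev = (tp, i)
            s_t[j] = best
            b_t[j] = best_prev
        score.append(s_t)
        back.append(b_t)

    best_val, best_end = -np.inf, None
    for t in range(n_frames):
        if score[t].size and np.isfinite(score[t]).any():
            j = int(np.argmax(score[t]))
            if score[t][j] > best_val:
                best_val, best_end = float(score[t][j]), (t, j)
    if best_end is None:
        return -np.inf, []
    path = []
    node: tuple[int, int] | None = best_end
    while node is not None:
        path.append(node)
        node = back[node[0]][node[1]]
    path.reverse()
    return best_val, path


def link_detections(
    detections: Sequence[np.ndarray],
    model: LinkScoreModel | None = None,
    *,
    apply_swaps: bool = True,
) -> list[LinkedTrack]:
    """Link per-frame detections into tracks, one global path at a time.

    Each iteration runs the Viterbi DP over the remaining detections and
    commits the best path as a new track; iteration stops when the best
    path has fewer than two detections or falls below the
    appear+disappear floor: the detections and links it collects must
    outscore the cost of a track appearing and disappearing, i.e. its full
    path score must be positive (a zero-or-negative path is better
    explained as noise).  The swap-repair pass runs afterwards unless
    disabled.
    """
    if model is None:
        model = LinkScoreModel()
    detections = [np.atleast_2d(np.asarray(d, dtype=float)) if np.asarray(d).size else
                  np.empty((0, 2)) for d in detections]
    if len(detections) < 2:
        raise ValueError("need at least 2 frames of detections")
    used = [np.zeros(d.shape[0], dtype=bool) for d in detections]
    tracks: list[LinkedTrack] = []
    floor = -(model.appear_logp + model.disappear_logp)
    while True:
        interior, path = _best_path(detections, used, model)
        # path score = appear + interior + disappear must be > 0
        if len(path) < 2 or interior <= floor:
            break
        frames = tuple(t for t, _ in path)
        idx = tuple(j for _, j in path)
        pos = np.array([detections[t][j] for t, j in path])
        tracks.append(LinkedTrack(frames=frames, det_indices=idx, positions=pos))
        for t, j in path:
            used[t][j] = True
    if apply_swaps and len(tracks) > 1:
        tracks = swap_pass(tracks, model)
    return tracks


def _splice(a: LinkedTrack, b: LinkedTrack, t: int) -> tuple[LinkedTrack, LinkedTrack]:
    """Exchange the parts of two tracks after frame t."""
    ia = next((i for i, f in enumerate(a.frames) if f > t), len(a))
    ib = next((i for i, f in enumerate(b.frames) if f > t), len(b))
    new_a = LinkedTrack(
        frames=a.frames[:ia] + b.frames[ib:],
        det_indices=a.det_indices[:ia] + b.det_indices[ib:],
        positions=np.concatenate([a.positions[:ia], b.positions[ib:]])
        if (ia or len(b) - ib)
        else np.empty((0, 2)),
    )
    new_b = LinkedTrack(
        frames=b.frames[:ib] + a.frames[ia:],
        det_indices=b.det_indices[:ib] + a.det_indices[ia:],
        positions=np.concatenate([b.positions[:ib], a.positions[ia:]])
        if (ib or len(a) - ia)
        else np.empty((0, 2)),
    )
    return new_a, new_b


def swap_pass(
    tracks: Sequence[LinkedTrack], model: LinkScoreModel, max_sweeps: int = 50
) -> list[LinkedTrack]:
    """Exchange track tails across every frame boundary while the total
    score improves; repeats to a fixed point, so the score never decreases.

    A swap at boundary t hands everything after frame t of track A to
    track B and vice versa; one side may be empty, which turns the swap
    into a tail transfer.  A spliced remnant with fewer than two
    detections, or whose path score is no longer positive, is worth zero:
    it is dissolved back to noise at the end, which cannot lower the
    score.
    """

    def value(tr: LinkedTrack) -> float:
        if len(tr) < 2:
            return 0.0
        return max(tr.path_score(model), 0.0)

    current = list(tracks)
    if not current:
        return current
    boundaries = sorted({f for tr in current for f in tr.frames})
    for _ in range(max_sweeps):
        improved = False
        for ai in range(len(current)):
            for bi in range(ai + 1, len(current)):
                a, b = current[ai], current[bi]
                for t in boundaries:
                    new_a, new_b = _splice(a, b, t)
                    if value(new_a) + value(new_b) > value(a) + value(b) + 1e-12:
                        current[ai], current[bi] = new_a, new_b
                        a, b = new_a, new_b
                        improved = True
        if not improved:
            break
    out = [tr for tr in current if len(tr) >= 2 and tr.path_score(model) > 0]
    if len(out) < len(current):
        logger.info("swap pass dissolved %d degenerate track(s)", len(current) - len(out))
    return out


def link_accuracy(tracks: Sequence[LinkedTrack], movie) -> float:
    """Fraction of ground-truth consecutive-frame links recovered.

    ``movie`` is a :class:`~woundtrack.simulate.DetectionMovie`.  A true
    link (cell present at frames t and t+1) counts as recovered when some
    track joins exactly those two detections consecutively.
    """
    truth = set()
    for t in range(movie.n_frames - 1):
        ids_now = {cid: j for j, cid in enumerate(movie.ids[t])}
        ids_next = {cid: j for j, cid in enumerate(movie.ids[t + 1])}
        for cid in ids_now:
            if cid in ids_next:
                truth.add((t, ids_now[cid], t + 1, ids_next[cid]))
    if not truth:
        return 1.0
    found = set()
    for tr in tracks:
        for i in range(len(tr) - 1):
            if tr.frames[i + 1] == tr.frames[i] + 1:
                found.add(
                    (tr.frames[i], tr.det_indices[i], tr.frames[i + 1], tr.det_indices[i + 1])
                )
    return len(truth & found) / len(truth)
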