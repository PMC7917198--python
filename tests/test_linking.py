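"""Viterbi global linker: DP path search, swap repair, oracle equivalence."""

import itertools

import numpy as np
import pytest

from woundtrack import (
    LinkScoreModel,
    LinkedTrack,
    SimulationConfig,
    link_accuracy,
    link_detections,
    simulate_detection_movie,
    swap_pass,
    total_score,
)


def enumerate_optimum(dets, model):
    """Exhaustive oracle over all consecutive-frame link assignments.

    Valid only for models with max_gap=1.  Scores a structure as the sum of
    motion terms plus det_logp per linked detection plus appear+disappear
    per chain (chains of ≥2); singletons stay noise at score 0.  The
    per-structure score reduces to local terms via #chains = U − L with U
    linked detections and L links.
    """
    assert model.max_gap == 1

    def matchings(na, nb):
        out = []
        for k in range(0, min(na, nb) + 1):
            for sub_a in itertools.combinations(range(na), k):
                for sub_b in itertools.permutations(range(nb), k):
                    out.append(tuple(zip(sub_a, sub_b)))
        return out

    per_pair = [matchings(len(dets[t]), len(dets[t + 1])) for t in range(len(dets) - 1)]
    best = 0.0
    for combo in itertools.product(*per_pair):
        linked, n_links, motion = set(), 0, 0.0
        for t, m in enumerate(combo):
            for i, j in m:
                motion += model.motion_score(dets[t][i], dets[t + 1][j], 1)
                linked.add((t, i))
                linked.add((t + 1, j))
                n_links += 1
        u = len(linked)
        score = (
            motion
            + model.det_logp * u
            + (model.appear_logp + model.disappear_logp) * (u - n_links)
        )
        best = max(best, score)
    return best


class TestLinkDetections:
    def test_two_separated_cells_match_nearest_neighbour(self):
        # two cells far apart moving smoothly: linking is unambiguous
        left = np.array([[0.0, 0.0], [2.0, 0.0], [4.0, 0.0], [6.0, 0.0]])
        right = np.array([[100.0, 0.0], [100.0, 2.0], [100.0, 4.0], [100.0, 6.0]])
        dets = [np.array([left[t], right[t]]) for t in range(4)]
        tracks = link_detections(dets, LinkScoreModel(sigma=5.0))
        assert len(tracks) == 2
        got = {tuple(tr.det_indices) for tr in tracks}
        assert got == {(0, 0, 0, 0), (1, 1, 1, 1)}  # pure nearest-neighbour result

    def test_missed_frame_spanned_by_gap_link(self):
        # one cell, detection missing at frame 2: cheaper to bridge the gap
        # than to end one track and appear as another
        pos = {0: [0.0, 0.0], 1: [3.0, 0.0], 3: [9.0, 0.0], 4: [12.0, 0.0]}
        dets = [np.array([pos[t]]) if t in pos else np.empty((0, 2)) for t in range(5)]
        model = LinkScoreModel(
            sigma=5.0, appear_logp=-6.0, disappear_logp=-6.0, det_logp=4.0,
            max_gap=2, gap_logp=-1.0,
        )
        tracks = link_detections(dets, model)
        assert len(tracks) == 1
        assert tracks[0].frames == (0, 1, 3, 4)

    def test_expensive_gap_splits_track(self):
        # same geometry, but bridging is made dearer than disappear+appear
        pos = {0: [0.0, 0.0], 1: [3.0, 0.0], 3: [9.0, 0.0], 4: [12.0, 0.0]}
        dets = [np.array([pos[t]]) if t in pos else np.empty((0, 2)) for t in range(5)]
        model = LinkScoreModel(
            sigma=5.0, appear_logp=-1.0, disappear_logp=-1.0, det_logp=3.0,
            max_gap=2, gap_logp=-20.0,
        )
        tracks = link_detections(dets, model)
        assert len(tracks) == 2

    def test_empty_frames_and_no_detections(self):
        dets = [np.empty((0, 2)) for _ in range(4)]
        assert link_detections(dets, LinkScoreModel()) == []

    def test_exclusivity(self):
        rng = np.random.default_rng(0)
        dets = [rng.uniform(0, 50, size=(3, 2)) for _ in range(5)]
        tracks = link_detections(dets, LinkScoreModel(sigma=20.0))
        used = set()
        for tr in tracks:
            for node in zip(tr.frames, tr.det_indices):
                assert node not in used
                used.add(node)

    def test_oracle_equivalence_small_instances(self):
        """Greedy Viterbi + swaps reaches the enumeration optimum on random
        ≤3-cell × ≤4-frame instances."""
        rng = np.random.default_rng(42)
        model = LinkScoreModel(
            sigma=5.0, appear_logp=-4.0, disappear_logp=-4.0, det_logp=3.0, max_gap=1
        )
        for _ in range(30):
            n_frames = int(rng.integers(2, 5))
            dets = [
                rng.uniform(0, 60, size=(int(rng.integers(0, 4)), 2))
                for _ in range(n_frames)
            ]
            opt = enumerate_optimum(dets, model)
            got = total_score(link_detections(dets, model), model)
            assert got == pytest.approx(opt, abs=1e-9)


class TestSwapPass:
    def _crossed_pair(self):
        # two straight horizontal tracks whose links were deliberately crossed
        top = np.array([[0.0, 10.0], [5.0, 10.0], [10.0, 10.0], [15.0, 10.0]])
        bot = np.array([[0.0, 0.0], [5.0, 0.0], [10.0, 0.0], [15.0, 0.0]])
        a = LinkedTrack(
            frames=(0, 1, 2, 3),
            det_indices=(0, 0, 1, 1),
            positions=np.array([top[0], top[1], bot[2], bot[3]]),
        )
        b = LinkedTrack(
            frames=(0, 1, 2, 3),
            det_indices=(1, 1, 0, 0),
            positions=np.array([bot[0], bot[1], top[2], top[3]]),
        )
        return a, b

    def test_uncrosses_crossed_tracks(self):
        a, b = self._crossed_pair()
        model = LinkScoreModel(sigma=5.0)
        before = total_score([a, b], model)
        repaired = swap_pass([a, b], model)
        after = total_score(repaired, model)
        assert after > before
        for tr in repaired:
            ys = tr.positions[:, 1]
            assert np.all(ys == ys[0])  # straight again

    def test_fixed_point_on_optimal_tracks(self):
        a, b = self._crossed_pair()
        model = LinkScoreModel(sigma=5.0)
        repaired = swap_pass([a, b], model)
        again = swap_pass(repaired, model)
        assert {t.frames + t.det_indices for t in repaired} == {
            t.frames + t.det_indices for t in again
        }

    def test_score_never_decreases_on_random_inputs(self):
        rng = np.random.default_rng(17)
        model = LinkScoreModel(sigma=8.0)
        for _ in range(20):
            dets = [rng.uniform(0, 40, size=(3, 2)) for _ in range(5)]
            tracks = link_detections(dets, model, apply_swaps=False)
            if len(tracks) < 2:
                continue
            before = total_score(tracks, model)
            after = total_score(swap_pass(tracks, model), model)
            assert after >= before - 1e-12


class TestOnSyntheticMovies:
    def test_perfect_accuracy_when_well_separated(self):
        for seed in range(5):
            cfg = SimulationConfig(
                seed=seed, n_cells=6, duration=14, start_band=(100.0, 900.0),
                start_spread=900.0,
            )
            movie = simulate_detection_movie(cfg, miss_rate=0.0)
            tracks = link_detections(
                movie.detections, LinkScoreModel(sigma=12.0, det_logp=4.0)
            )
            assert link_accuracy(tracks, movie) == 1.0

    def test_recovers_through_dropout(self):
        cfg = SimulationConfig(
            seed=3, n_cells=4, duration=19, start_band=(200.0, 900.0),
            start_spread=900.0,
        )
        movie = simulate_detection_movie(cfg, miss_rate=0.1)
        tracks = link_detections(
            movie.detections,
            LinkScoreModel(sigma=12.0, det_logp=4.0, max_gap=2, gap_logp=-1.5),
        )
        assert link_accuracy(tracks, movie) >= 0.9
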