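"""Per-track statistics, wound distances and classification rules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from woundtrack import (
    WoundFrame,
    arrival_status,
    classify_track,
    count_recruited,
    distance_to_wound,
    mean_speed,
    meandering_index,
    net_displacement,
    summarize_cohort,
    total_displacement,
    Cohort,
)

from conftest import make_track


class TestScalarMetrics:
    @pytest.mark.parametrize(
        "positions, d_net, d_tot",
        [
            ([(0, 0), (3, 4)], 5.0, 5.0),  # 3-4-5 triangle
            ([(0, 0), (1, 0), (2, 0), (3, 0)], 3.0, 3.0),  # collinear unit steps
            ([(0, 0), (1, 0), (1, 1), (0, 1), (0, 0)], 0.0, 4.0),  # square loop
            ([(0, 0), (1, 0), (1, 1)], math.sqrt(2), 2.0),  # right angle
        ],
    )
    def test_displacements_hand_values(self, positions, d_net, d_tot):
        tr = make_track(positions)
        assert net_displacement(tr) == pytest.approx(d_net, abs=1e-12)
        assert total_displacement(tr) == pytest.approx(d_tot, abs=1e-12)

    def test_meandering_index_hand_values(self):
        straight = make_track([(0, 0), (5, 0), (10, 0)])
        loop = make_track([(0, 0), (1, 0), (1, 1), (0, 1), (0, 0)])
        right_angle = make_track([(0, 0), (1, 0), (1, 1)])
        assert meandering_index(straight) == pytest.approx(1.0)
        assert meandering_index(loop) == pytest.approx(0.0)
        assert meandering_index(right_angle) == pytest.approx(math.sqrt(2) / 2)

    def test_meandering_index_stationary_is_nan(self):
        stat = make_track([(2, 2), (2, 2), (2, 2)])
        assert math.isnan(meandering_index(stat))

    def test_mean_speed(self):
        # 2 μm steps each minute over 3 frames → 2 μm/min
        tr = make_track([(0, 0), (2, 0), (4, 0)])
        assert mean_speed(tr) == pytest.approx(2.0)
        assert mean_speed(make_track([(1, 1), (1, 1)])) == 0.0
        # d_tot = 10 μm over 4 contiguous 1-min intervals → 2.5 μm/min
        tr = make_track([(0, 0), (4, 0), (6, 0), (8, 0), (10, 0)])
        assert mean_speed(tr) == pytest.approx(2.5)

    def test_gap_spans_time_and_distance(self):
        # frames 0 and 3: the single step spans the 3-min gap, no interpolation
        tr = make_track([(0, 0), (6, 0)], frames=[0, 3])
        assert total_displacement(tr) == pytest.approx(6.0)
        assert mean_speed(tr) == pytest.approx(2.0)


class TestDistanceToWound:
    def test_vertical_edge(self):
        wound = WoundFrame(wound_edge=[(500, -300), (500, 300)], ap_axis=(1, 0))
        assert distance_to_wound(np.array([300.0, 100.0]), wound) == pytest.approx(200.0)

    def test_point_on_edge(self, vertical_wound):
        assert distance_to_wound(np.array([0.0, 10.0]), vertical_wound) == pytest.approx(0.0)

    def test_beyond_endpoint_clamps(self):
        wound = WoundFrame(wound_edge=[(0, 0), (0, 10)], ap_axis=(1, 0))
        # point beyond the top endpoint: distance to (0, 10)
        assert distance_to_wound(np.array([3.0, 14.0]), wound) == pytest.approx(5.0)

    def test_matches_shapely_and_dense_sampling(self):
        """Independent cross-checks on random polylines and points."""
        from shapely.geometry import LineString, Point

        rng = np.random.default_rng(7)
        for _ in range(50):
            verts = rng.uniform(-100, 100, size=(rng.integers(2, 6), 2))
            wound = WoundFrame(wound_edge=verts, ap_axis=(1, 0))
            line = LineString(verts)
            pts = rng.uniform(-150, 150, size=(20, 2))
            ours = distance_to_wound(pts, wound)
            ref = np.array([line.distance(Point(*p)) for p in pts])
            np.testing.assert_allclose(ours, ref, atol=1e-6)
            # dense sampling along the polyline can only overestimate slightly
            dense = np.concatenate(
                [
                    verts[i] + np.linspace(0, 1, 2000)[:, None] * (verts[i + 1] - verts[i])
                    for i in range(len(verts) - 1)
                ]
            )
            brute = np.linalg.norm(pts[:, None, :] - dense[None], axis=2).min(axis=1)
            assert np.all(ours <= brute + 1e-9)
            np.testing.assert_allclose(ours, brute, atol=0.2)


class TestClassificationRules:
    def test_distant_vs_local_boundary(self, vertical_wound):
        start = lambda d: make_track([(d, 0), (d - 1, 0)])
        assert classify_track(start(250.0), vertical_wound) == "distant"
        # exactly 200 μm: "within a distance of up to 200 μm" is inclusive
        assert classify_track(start(200.0), vertical_wound) == "local_resident"
        assert classify_track(start(20.0), vertical_wound) == "local_resident"

    def test_only_first_frame_matters(self, vertical_wound):
        # starts local, wanders far: still local_resident
        tr = make_track([(100, 0), (400, 0), (500, 0)])
        assert classify_track(tr, vertical_wound) == "local_resident"
        truncated = make_track(tr.positions[:2], frames=tr.frames[:2])
        assert classify_track(truncated, vertical_wound) == classify_track(tr, vertical_wound)

    def test_arrival_and_retention(self, vertical_wound):
        approach = make_track([(100, 0), (50, 0), (5, 0)])
        st_ = arrival_status(approach, vertical_wound)
        assert st_.arrived and st_.stayed and st_.first_arrival_time == 2.0

        never = make_track([(100, 0), (90, 0), (80, 0)])
        st_ = arrival_status(never, vertical_wound)
        assert not st_.arrived and st_.first_arrival_time is None and not st_.stayed

        touch_and_leave = make_track([(100, 0), (15, 0), (60, 0)])
        st_ = arrival_status(touch_and_leave, vertical_wound)
        assert st_.arrived and not st_.stayed and st_.first_arrival_time == 1.0

    def test_arrival_boundary_inclusive(self, vertical_wound):
        at_radius = make_track([(100, 0), (20, 0)])
        assert arrival_status(at_radius, vertical_wound).arrived

    def test_count_recruited(self, vertical_wound):
        pts = np.array([[50, 0], [150, 10], [300, -5]], dtype=float)
        assert count_recruited(pts, vertical_wound) == 2
        assert count_recruited(np.empty((0, 2)), vertical_wound) == 0
        assert count_recruited(pts[:2], vertical_wound) == 2  # all within band


class TestInvariants:
    @given(
        pos=arrays(
            np.float64,
            (8, 2),
            elements=st.floats(-500, 500, allow_nan=False, width=32),
        )
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_net_le_total_and_mi_bounds(self, pos):
        tr = make_track(pos)
        d_net, d_tot = net_displacement(tr), total_displacement(tr)
        assert d_net <= d_tot + 1e-9 * max(d_tot, 1.0)
        mi = meandering_index(tr)
        if not math.isnan(mi):
            assert -1e-12 <= mi <= 1.0 + 1e-12
        assert mean_speed(tr) >= 0.0

    @given(
        pos=arrays(
            np.float64,
            (6, 2),
            elements=st.floats(-200, 200, allow_nan=False, width=32),
        ),
        angle=st.floats(0, 2 * math.pi),
        shift=st.tuples(st.floats(-100, 100), st.floats(-100, 100)),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_rigid_motion_invariance(self, pos, angle, shift):
        """d_net, d_tot and speed are unchanged by rotation + translation."""
        rot = np.array(
            [[math.cos(angle), -math.sin(angle)], [math.sin(angle), math.cos(angle)]]
        )
        moved = pos @ rot.T + np.asarray(shift)
        a, b = make_track(pos), make_track(moved)
        scale = max(total_displacement(a), 1.0)
        assert net_displacement(a) == pytest.approx(net_displacement(b), abs=1e-8 * scale)
        assert total_displacement(a) == pytest.approx(total_displacement(b), abs=1e-8 * scale)
        assert mean_speed(a) == pytest.approx(mean_speed(b), abs=1e-8 * scale)

    def test_equality_iff_collinear_monotone(self):
        collinear = make_track([(0, 0), (2, 1), (4, 2)])
        assert net_displacement(collinear) == pytest.approx(total_displacement(collinear))
        bent = make_track([(0, 0), (2, 1), (2, 3)])
        assert net_displacement(bent) < total_displacement(bent)


def test_summarize_cohort_table(vertical_wound):
    tracks = [
        make_track([(250, 0), (240, 0), (230, 0)], track_id="a", group="wt"),
        make_track([(100, 0), (60, 0), (15, 0)], track_id="b", group="wt"),
    ]
    df = summarize_cohort(Cohort(tracks), vertical_wound)
    assert list(df["track_id"]) == ["a", "b"]
    assert list(df["category"]) == ["distant", "local_resident"]
    assert df.loc[1, "arrived"] and df.loc[1, "first_arrival_time"] == 2.0
    assert df.loc[0, "d_net"] == pytest.approx(20.0)
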