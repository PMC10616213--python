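"""Gaze-AOI matching: frame mapping, hit tests, visits, dwell metrics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wideaoi.annotate import AoiBox, AoiTrajectory
from wideaoi.geometry import PixelMargins
from wideaoi.match_metrics import (
    MatchParams,
    Visit,
    extract_visits,
    frame_of,
    hit_test,
    merge_and_filter,
    run_batch,
    summarize,
)


def _traj(first, last, xl=-100, yt=-50, xr=100, yb=50, object_id="obj"):
    frames = np.arange(first, last + 1)
    return AoiTrajectory(
        object_id=object_id,
        table=pd.DataFrame(
            {
                "frame": frames,
                "x_left": xl,
                "y_top": yt,
                "x_right": xr,
                "y_bottom": yb,
                "label": "",
            }
        ),
    )


class TestFrameOf:
    def test_start_is_frame_zero(self):
        assert frame_of(0.0, 25.0) == 0

    def test_half_open_frame_boundary(self):
        assert frame_of(0.0399, 25.0) == 0
        assert frame_of(0.0400, 25.0) == 1

    def test_240hz_second_distributes_over_frames(self):
        t = np.arange(240) / 240.0
        f = frame_of(t, 25.0)
        counts = np.bincount(f, minlength=25)
        assert counts.sum() == 240
        assert set(counts.tolist()) <= {9, 10}

    def test_time_before_start_rejected(self):
        with pytest.raises(ValueError):
            frame_of(-0.1, 25.0)


class _Sample:
    def __init__(self, x, y, valid=True):
        self.x, self.y, self.valid = x, y, valid


class TestHitTest:
    BOX = AoiBox(0, -100, -50, 100, 50)
    M = PixelMargins(10, 20, 5, 5)

    def test_expanded_corner_is_a_hit(self):
        assert hit_test(_Sample(120.0, 55.0), self.BOX, self.M)
        assert hit_test(_Sample(-110.0, -55.0), self.BOX, self.M)

    def test_one_pixel_outside_is_a_miss(self):
        assert not hit_test(_Sample(121.0, 55.0), self.BOX, self.M)
        assert not hit_test(_Sample(120.0, 56.0), self.BOX, self.M)

    def test_invalid_sample_rejected(self):
        with pytest.raises(ValueError):
            hit_test(_Sample(0, 0, valid=False), self.BOX, self.M)

    def test_matches_brute_force_point_in_rectangle(self, rng):
        xs = rng.uniform(-200, 200, 10_000)
        ys = rng.uniform(-100, 100, 10_000)
        for x, y in zip(xs[:200], ys[:200]):  # spot-check slice of the draw
            expected = (-110 <= x <= 120) and (-55 <= y <= 55)
            assert hit_test(_Sample(x, y), self.BOX, self.M) == expected
        # vectorized check over the full draw
        inside = (xs >= -110) & (xs <= 120) & (ys >= -55) & (ys <= 55)
        got = np.array(
            [hit_test(_Sample(x, y), self.BOX, self.M) for x, y in zip(xs, ys)]
        )
        assert (got == inside).all()


def _oracle_visits(t, hits):
    """Independent run-length scanner (itertools.groupby)."""
    visits = []
    i = 0
    for key, grp in itertools.groupby(hits):
        n = len(list(grp))
        if key:
            visits.append(Visit(t[i], t[i + n - 1]))
        i += n
    return visits


def _oracle_merge_filter(visits, params):
    """Brute force: restart-scan merging, then the minimum-dwell filter."""
    vs = [(v.t_entry, v.t_exit) for v in sorted(visits, key=lambda v: v.t_entry)]
    changed = True
    while changed:
        changed = False
        for i in range(len(vs) - 1):
            if (vs[i + 1][0] - vs[i][1]) * 1000.0 < params.min_intervisit_gap_ms - 1e-6:
                vs[i : i + 2] = [(vs[i][0], vs[i + 1][1])]
                changed = True
                break
    return [
        Visit(a, b) for a, b in vs if (b - a) * 1000.0 >= params.min_dwell_ms - 1e-6
    ]


class TestExtractVisits:
    def test_all_hits_is_one_visit(self):
        t = np.arange(100) / 240
        visits = extract_visits(t, np.ones(100, bool))
        assert visits == [Visit(t[0], t[-1])]

    def test_no_hits_is_empty(self):
        assert extract_visits(np.arange(10) / 240, np.zeros(10, bool)) == []

    def test_gap_samples_close_visits_like_non_hits(self):
        t = np.arange(6) / 240
        hits = np.ones(6, bool)
        valid = np.array([True, True, False, False, True, True])
        visits = extract_visits(t, hits, valid)
        assert len(visits) == 2

    def test_matches_run_length_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 300))
            t = np.arange(n) / 240
            hits = rng.random(n) > 0.5
            assert extract_visits(t, hits) == _oracle_visits(t, hits)


class TestMergeAndFilter:
    def test_sub_100ms_gap_pools_into_previous_dwell(self):
        visits = [Visit(0.0, 0.50), Visit(0.55, 1.00)]
        out = merge_and_filter(visits)
        assert out == [Visit(0.0, 1.00)]
        assert out[0].duration_s == pytest.approx(1.0)

    def test_lone_80ms_visit_removed(self):
        assert merge_and_filter([Visit(1.0, 1.08)]) == []

    def test_100ms_gap_does_not_merge(self):
        out = merge_and_filter([Visit(0.0, 0.5), Visit(0.6, 1.1)])
        assert len(out) == 2

    def test_overlapping_visits_rejected(self):
        with pytest.raises(ValueError):
            merge_and_filter([Visit(0.0, 0.5), Visit(0.4, 1.0)])

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=0, max_value=30),
                st.floats(min_value=0.001, max_value=0.8),
            ),
            max_size=12,
        )
    )
    def test_matches_brute_force_enumeration(self, raw):
        # build non-overlapping visits from (gap, duration) pairs
        visits = []
        cursor = 0.0
        for gap, dur in raw:
            cursor += gap + 0.0005
            visits.append(Visit(cursor, cursor + dur))
            cursor += dur
        params = MatchParams()
        assert merge_and_filter(visits, params) == _oracle_merge_filter(visits, params)


class TestSummarize:
    def test_perfect_tracking_is_100_percent(self):
        traj = _traj(0, 249)  # 10 s at 25 fps
        m = summarize([Visit(0.0, 10.0)], traj)
        assert m.dwell_pct == pytest.approx(100.0)
        assert m.time_to_first_entry_s == 0.0
        assert m.appearance_s == 10.0

    def test_nine_of_ten_seconds_is_90_percent(self):
        traj = _traj(0, 249)
        m = summarize([Visit(0.5, 9.5)], traj)
        assert m.dwell_pct == pytest.approx(90.0)
        assert m.time_to_first_entry_s == pytest.approx(0.5)
        assert m.t_last_exit_s == pytest.approx(9.5)

    def test_no_visits_reports_missing_entry(self):
        m = summarize([], _traj(0, 249))
        assert m.n_visits == 0
        assert m.total_dwell_s == 0.0
        assert np.isnan(m.time_to_first_entry_s)

    def test_dwell_above_appearance_warns_uncapped(self):
        traj = _traj(0, 24)  # 1 s
        with pytest.warns(UserWarning, match="exceeds 100%"):
            m = summarize([Visit(0.0, 1.05)], traj)
        assert m.dwell_pct > 100.0


class TestRunBatch:
    @staticmethod
    def _gaze_inside_box(duration=2.0):
        t = np.arange(0, duration, 1 / 240)
        return pd.DataFrame(
            {
                "t": t,
                "x": np.zeros_like(t),
                "y": np.zeros_like(t),
                "confidence": 1.0,
                "on_screen": True,
                "valid": True,
            }
        )

    def test_cardinality_is_participants_by_objects_by_margins(self, geom):
        trajectories = [_traj(0, 49, object_id=f"obj{i:02d}") for i in range(13)]
        table = run_batch(
            {"p0": self._gaze_inside_box()}, trajectories, (0, 0.5, 1, 1.5, 2), geom
        )
        assert len(table) == 65
        assert table.groupby(["object_id", "margin_deg"]).size().eq(1).all()

    def test_dwell_pct_non_decreasing_in_margin(self, geom, rng):
        # gaze scattered around the box edge: bigger margins catch more
        t = np.arange(0, 2.0, 1 / 240)
        gaze = pd.DataFrame(
            {
                "t": t,
                "x": 100 + rng.normal(0, 40, len(t)),
                "y": rng.normal(0, 20, len(t)),
                "confidence": 1.0,
                "on_screen": True,
                "valid": True,
            }
        )
        table = run_batch({"p0": gaze}, [_traj(0, 49)], (0, 0.5, 1, 1.5, 2), geom)
        pct = table.sort_values("margin_deg")["dwell_pct"].to_numpy()
        assert (np.diff(pct) >= -1e-9).all()

    def test_retained_dwell_bounded_by_appearance(self, geom, rng):
        t = np.arange(0, 3.0, 1 / 240)
        gaze = pd.DataFrame(
            {
                "t": t,
                "x": rng.normal(0, 120, len(t)),
                "y": rng.normal(0, 60, len(t)),
                "confidence": 1.0,
                "on_screen": True,
                "valid": True,
            }
        )
        table = run_batch({"p0": gaze}, [_traj(10, 59)], (0, 2), geom)
        assert (table["total_dwell_s"] <= table["appearance_s"] + 2 / 240 + 1e-9).all()
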