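"""Gaze cleaning: median filter, gap classification/fill/pad, resampling."""

import numpy as np
import pandas as pd
import pytest

from wideaoi.preprocess import (
    GapStats,
    PreprocessParams,
    classify_gaps,
    extend_gaps,
    gap_stats,
    interpolate_short_gaps,
    median_filter,
    preprocess_pipeline,
    resample_uniform,
)


def _stream(t, x=None, y=None, conf=1.0, on=True, valid=True):
    t = np.asarray(t, dtype=float)
    n = len(t)

    def fill(v, default):
        if v is None:
            return np.full(n, default)
        v = np.asarray(v, dtype=float)
        return v

    return pd.DataFrame(
        {
            "t": t,
            "x": fill(x, 0.0),
            "y": fill(y, 0.0),
            "confidence": np.broadcast_to(np.asarray(conf, dtype=float), (n,)).copy(),
            "on_screen": np.broadcast_to(np.asarray(on, dtype=bool), (n,)).copy(),
            "valid": np.broadcast_to(np.asarray(valid, dtype=bool), (n,)).copy(),
        }
    )


class TestMedianFilter:
    def test_constant_series_unchanged(self):
        s = _stream(np.arange(3) / 240, x=[5, 5, 5])
        out = median_filter(s, 3)
        assert list(out["x"]) == [5, 5, 5]

    def test_one_sample_spike_removed(self):
        s = _stream(np.arange(3) / 240, x=[1, 100, 1])
        out = median_filter(s, 3)
        assert out.loc[1, "x"] == 1

    def test_boundaries_passed_through(self):
        s = _stream(np.arange(5) / 240, x=[9, 1, 2, 3, 9])
        out = median_filter(s, 3)
        assert out.loc[0, "x"] == 9 and out.loc[4, "x"] == 9

    def test_matches_brute_force_sort_and_pick(self, rng):
        x = rng.normal(size=500)
        y = rng.normal(size=500)
        out = median_filter(_stream(np.arange(500) / 240, x=x, y=y), 5)
        for i in range(2, 498):
            assert out.loc[i, "x"] == sorted(x[i - 2 : i + 3])[2]
            assert out.loc[i, "y"] == sorted(y[i - 2 : i + 3])[2]

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            median_filter(_stream([0, 1], x=[0, 0]), 2)


class TestClassifyGaps:
    def test_threshold_is_strict_boundary_kept(self):
        s = _stream([0.0], conf=0.8)
        assert classify_gaps(s, 0.8).loc[0, "valid"]

    def test_off_screen_is_gap_despite_high_confidence(self):
        s = _stream([0.0], conf=0.95, on=False)
        out = classify_gaps(s, 0.8)
        assert not out.loc[0, "valid"]
        assert np.isnan(out.loc[0, "x"])

    def test_gap_fraction_matches_direct_count(self, rng):
        conf = rng.uniform(0.5, 1.0, 1000)
        on = rng.random(1000) > 0.1
        s = _stream(np.arange(1000) / 240, conf=conf, on=on)
        out = classify_gaps(s, 0.8)
        expected = np.sum((conf < 0.8) | ~on)
        assert (~out["valid"]).sum() == expected


class TestInterpolateShortGaps:
    def test_linear_fill_inside_short_gap(self):
        # 50 ms gap between (1.000, x=0) and (1.050, x=12): x(1.025) = 6
        t = np.concatenate([[1.000], 1.000 + np.arange(1, 11) / 240, [1.050]])
        x = np.concatenate([[0.0], np.full(10, np.nan), [12.0]])
        valid = np.concatenate([[True], np.zeros(10, bool), [True]])
        out = interpolate_short_gaps(_stream(t, x=x, valid=valid), 75.0)
        assert out["valid"].all()
        i = int(np.argmin(np.abs(t - 1.025)))
        assert out.loc[i, "x"] == pytest.approx(12 * (t[i] - 1.0) / 0.05)

    def test_gap_at_threshold_untouched(self):
        t = np.array([1.0, 1.02, 1.05, 1.08, 1.10])
        valid = np.array([True, False, False, False, True])
        out = interpolate_short_gaps(_stream(t, valid=valid), 100.0)
        assert not out["valid"][1:4].any()  # 100 ms gap, ties do not fill

    def test_edge_gaps_never_filled(self):
        t = np.arange(6) / 240
        valid = np.array([False, True, True, True, True, False])
        out = interpolate_short_gaps(_stream(t, valid=valid), 75.0)
        assert not out.loc[0, "valid"] and not out.loc[5, "valid"]

    def test_matches_run_length_oracle(self, rng):
        n = 800
        t = np.arange(n) / 240
        valid = rng.random(n) > 0.2
        valid[0] = valid[-1] = True
        out = interpolate_short_gaps(_stream(t, valid=valid), 75.0)
        # independent scan: fill iff flank-to-flank duration < 75 ms
        expect = valid.copy()
        i = 0
        while i < n:
            if not valid[i]:
                j = i
                while j < n and not valid[j]:
                    j += 1
                if i > 0 and j < n and (t[j] - t[i - 1]) * 1000 < 75:
                    expect[i:j] = True
                i = j
            else:
                i += 1
        assert (out["valid"].to_numpy() == expect).all()

    def test_fill_stays_in_convex_hull_of_flanks(self, rng):
        n = 500
        t = np.arange(n) / 240
        x = rng.normal(size=n) * 100
        valid = rng.random(n) > 0.15
        valid[0] = valid[-1] = True
        s = _stream(t, x=x, valid=valid)
        s.loc[~s["valid"], "x"] = np.nan
        out = interpolate_short_gaps(s, 75.0)
        filled = out["valid"].to_numpy() & ~valid
        for i in np.flatnonzero(filled):
            j0 = np.flatnonzero(valid[:i])[-1]
            j1 = i + np.flatnonzero(valid[i:])[0]
            lo, hi = sorted((x[j0], x[j1]))
            assert lo - 1e-9 <= out.loc[i, "x"] <= hi + 1e-9


class TestExtendGaps:
    def test_pad_window_is_inclusive_100ms(self):
        t = np.arange(0, 4.2, 1 / 240)
        valid = ~((t >= 2.0) & (t <= 2.2))
        out = extend_gaps(_stream(t, valid=valid), 100.0)
        inv = ~out["valid"].to_numpy()
        inside = (t >= 1.9 - 1e-9) & (t <= 2.3 + 1e-9)
        assert inv[inside].all()
        assert not inv[~inside].any()

    def test_no_gaps_is_a_no_op(self):
        s = _stream(np.arange(100) / 240)
        pd.testing.assert_frame_equal(extend_gaps(s, 100.0), s)

    def test_two_close_gaps_merge_via_overlapping_pads(self):
        t = np.arange(0, 3.0, 1 / 240)
        valid = np.ones_like(t, dtype=bool)
        valid[(t >= 1.0) & (t < 1.05)] = False
        valid[(t >= 1.2) & (t < 1.25)] = False  # 150 ms apart
        out = extend_gaps(_stream(t, valid=valid), 100.0)
        between = (t >= 1.05) & (t < 1.2)
        assert not out["valid"].to_numpy()[between].any()


class TestResampleUniform:
    def test_linear_input_reproduced_exactly(self):
        t = np.sort(np.random.default_rng(0).uniform(0, 2, 300))
        t[0], t[-1] = 0.0, 2.0
        s = _stream(t, x=3.0 * t + 1.0, y=-2.0 * t)
        out = resample_uniform(s, 240.0)
        assert np.allclose(out["x"], 3.0 * out["t"] + 1.0, atol=1e-9)
        assert np.allclose(out["y"], -2.0 * out["t"], atol=1e-9)

    def test_output_spacing_is_1_over_240(self):
        t = np.sort(np.random.default_rng(1).uniform(0, 5, 600))
        out = resample_uniform(_stream(t), 240.0)
        dt = np.diff(out["t"].to_numpy())
        assert np.abs(dt - 1 / 240).max() < 1e-6 / 1000  # < 1 microsecond

    def test_monotone_segment_has_no_overshoot(self):
        t = np.arange(0, 1, 1 / 120)
        x = np.cumsum(np.abs(np.sin(7 * t))) * 10  # monotone increasing
        out = resample_uniform(_stream(t, x=x), 240.0)
        ox = out.loc[out["valid"], "x"].to_numpy()
        assert (np.diff(ox) >= -1e-9).all()
        assert ox.min() >= x.min() - 1e-9 and ox.max() <= x.max() + 1e-9

    def test_invalid_spans_not_bridged(self):
        t = np.arange(0, 2, 1 / 240)
        valid = ~((t >= 0.8) & (t <= 1.1))
        s = _stream(t, x=np.sin(t), valid=valid)
        s.loc[~s["valid"], ["x", "y"]] = np.nan
        out = resample_uniform(s, 240.0)
        gap = (out["t"] > 0.8) & (out["t"] < 1.1)
        assert not out.loc[gap, "valid"].any()
        assert out.loc[gap, "x"].isna().all()

    def test_single_sample_segment_emitted_invalid(self):
        t = np.arange(0, 1, 1 / 240)
        valid = np.zeros_like(t, dtype=bool)
        valid[:100] = True
        valid[200] = True  # isolated valid sample
        out = resample_uniform(_stream(t, valid=valid), 240.0)
        assert not out.loc[np.argmin(np.abs(out["t"] - t[200])), "valid"]


class TestGapStats:
    def test_fully_valid_stream_is_all_zero(self):
        s = _stream(np.arange(100) / 240)
        stats = gap_stats(s, s, s, s)
        assert stats == GapStats(0.0, 0.0, 0.0, 0.0, 0.0)

    def test_single_blink_percentages(self):
        # one 200 ms blink in 10 s at 240 Hz: 2% after interpolation,
        # 4% once padded by +-100 ms (within one sample of quantization)
        t = np.arange(0, 10, 1 / 240)
        conf = np.where((t >= 4.0005) & (t < 4.2005), 0.3, 0.99)
        s = _stream(t, conf=conf)
        classified = classify_gaps(s, 0.8)
        interped = interpolate_short_gaps(classified, 75.0)
        padded = extend_gaps(interped, 100.0)
        stats = gap_stats(s, classified, interped, padded)
        one_sample_pct = 100.0 / len(t)
        assert stats.pct_nan_after_interp == pytest.approx(2.0, abs=2 * one_sample_pct)
        assert stats.pct_nan_after_pad == pytest.approx(4.0, abs=2 * one_sample_pct)

    def test_padding_never_reduces_gap_fraction(self, rng):
        t = np.arange(0, 5, 1 / 240)
        conf = rng.choice([0.3, 0.99], size=len(t), p=[0.1, 0.9])
        s = _stream(t, conf=conf)
        classified = classify_gaps(s, 0.8)
        interped = interpolate_short_gaps(classified, 75.0)
        padded = extend_gaps(interped, 100.0)
        stats = gap_stats(s, classified, interped, padded)
        assert stats.pct_nan_after_pad >= stats.pct_nan_after_interp

    def test_length_mismatch_rejected(self):
        a = _stream(np.arange(10) / 240)
        b = _stream(np.arange(9) / 240)
        with pytest.raises(ValueError):
            gap_stats(a, a, a, b)


def test_pipeline_is_deterministic():
    rng = np.random.default_rng(7)
    t = np.sort(rng.uniform(0, 5, 1000))
    s = _stream(t, x=rng.normal(size=1000), conf=rng.uniform(0.5, 1, 1000))
    out1, stats1 = preprocess_pipeline(s)
    out2, stats2 = preprocess_pipeline(s)
    pd.testing.assert_frame_equal(out1, out2)
    assert stats1 == stats2


def test_params_validation():
    with pytest.raises(ValueError):
        PreprocessParams(median_window=4)
    with pytest.raises(ValueError):
        PreprocessParams(confidence_threshold=1.5)
    with pytest.raises(ValueError):
        PreprocessParams(target_rate_hz=0)
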