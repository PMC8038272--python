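"""Smoothing filter, staircase quantization, dwell-time scoring, and tables."""

import numpy as np
import pytest

import posturisk as pk
from posturisk import reference
from posturisk.rula_tables import TABLE_B, TABLE_C
from posturisk.scoring import moving_average, moving_average_response

from conftest import make_constant_series

CFG = pk.ScoringConfig()


# ---------------------------------------------------------------------------
# smoothing

class TestSmooth:
    def test_constant_series_unchanged(self):
        series = make_constant_series("spine", flexion=30.0, duration=1.0)
        out = pk.smooth(series, CFG)
        assert np.allclose(out.flexion, 30.0, atol=1e-12)

    def test_rectangular_pulse_attenuation(self):
        # 3-s, 30-degree transient against a zero baseline: the filter caps
        # its peak at 30 * 225/875 ~ 7.71 degrees, inside the +/-10 band.
        n, pulse = 3000, 225
        x = np.zeros(n)
        x[n // 2: n // 2 + pulse] = 30.0
        out = moving_average(x, CFG.filter_len)
        assert out.max() == pytest.approx(30.0 * pulse / CFG.filter_len, abs=1e-9)
        assert out.max() < CFG.twist_bend_band

    def test_sinusoid_at_cutoff_attenuated_3db(self):
        f_c = pk.cutoff_frequency(CFG.filter_len, CFG.fs)
        t = np.arange(int(600 * CFG.fs)) / CFG.fs
        x = np.sin(2 * np.pi * f_c * t)
        y = moving_average(x, CFG.filter_len)
        # least-squares projection onto the quadrature pair, away from edges
        sl = slice(CFG.filter_len, -CFG.filter_len)
        basis = np.column_stack([np.sin(2 * np.pi * f_c * t[sl]), np.cos(2 * np.pi * f_c * t[sl])])
        coef, *_ = np.linalg.lstsq(basis, y[sl], rcond=None)
        assert np.hypot(*coef) == pytest.approx(1 / np.sqrt(2), abs=0.01)

    def test_cutoff_frequency_matches_design(self):
        assert pk.cutoff_frequency(875, 75.0) == pytest.approx(0.038, abs=5e-4)

    def test_linearity(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=500), rng.normal(size=500)
        lhs = moving_average(2.0 * a + 3.0 * b, 75)
        rhs = 2.0 * moving_average(a, 75) + 3.0 * moving_average(b, 75)
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_too_short_series_rejected(self):
        with pytest.raises(pk.DataError):
            pk.smooth(make_constant_series("spine", duration=2 / 75.0), CFG)

    def test_frequency_response_oracle_agreement(self):
        # analytic Dirichlet response vs direct convolution measurement
        f = 0.02
        t = np.arange(int(900 * CFG.fs)) / CFG.fs
        y = moving_average(np.sin(2 * np.pi * f * t), CFG.filter_len)
        sl = slice(CFG.filter_len, -CFG.filter_len)
        basis = np.column_stack([np.sin(2 * np.pi * f * t[sl]), np.cos(2 * np.pi * f * t[sl])])
        coef, *_ = np.linalg.lstsq(basis, y[sl], rcond=None)
        assert np.hypot(*coef) == pytest.approx(
            moving_average_response(f, CFG.filter_len, CFG.fs), abs=5e-3)


# ---------------------------------------------------------------------------
# quantization

class TestQuantizeFlexion:
    @pytest.mark.parametrize("angle,expected", [
        (-20.0, 1), (0.0, 1), (10.0, 2), (20.0, 2), (30.0, 3), (60.0, 3), (61.0, 4), (90.0, 4),
    ])
    def test_spine_staircase(self, angle, expected):
        assert pk.quantize_flexion(angle, "spine", CFG) == expected

    @pytest.mark.parametrize("angle,expected", [
        (-15.0, 4), (-0.001, 4), (0.0, 1), (10.0, 1), (15.0, 2), (20.0, 2), (25.0, 3),
    ])
    def test_neck_staircase_with_extension(self, angle, expected):
        assert pk.quantize_flexion(angle, "neck", CFG) == expected

    def test_vectorized_matches_naive(self):
        rng = np.random.default_rng(3)
        angles = rng.uniform(-90, 120, 500)
        for seg in ("spine", "neck"):
            vec = pk.quantize_flexion(angles, seg, CFG)
            naive = [reference.naive_quantize(a, seg, CFG) for a in angles]
            assert list(vec) == naive

    def test_nan_rejected(self):
        with pytest.raises(pk.DataError):
            pk.quantize_flexion(np.nan, "spine", CFG)


# ---------------------------------------------------------------------------
# dwell times and window scores

class TestDwellAndWindowScore:
    def test_whole_window_one_level(self):
        dwell = pk.dwell_times(np.full(22500, 3), CFG)
        assert dwell == {3: 300.0}
        assert pk.window_flexo_score(dwell, CFG) == 3

    def test_split_window_counting(self):
        scores = np.concatenate([np.full(120 * 75, 4), np.full(180 * 75, 2)])
        dwell = pk.dwell_times(scores, CFG)
        assert dwell == {4: 120.0, 2: 180.0}
        assert pk.window_flexo_score(dwell, CFG) == 4

    def test_alternating_levels(self):
        scores = np.tile([2, 3], 150 * 75)
        assert pk.dwell_times(scores, CFG) == {2: 150.0, 3: 150.0}

    def test_short_dwell_ineligible(self):
        # 50 s at level 4 does not exceed the 60-s threshold
        assert pk.window_flexo_score({4: 50.0, 2: 250.0}, CFG) == 2

    def test_exact_threshold_is_strict(self):
        assert pk.window_flexo_score({4: 60.0, 1: 240.0}, CFG) == 1

    def test_empty_window_rejected(self):
        with pytest.raises(pk.DataError):
            pk.dwell_times(np.array([]), CFG)

    def test_pigeonhole_always_defined_on_full_windows(self):
        rng = np.random.default_rng(8)
        n = CFG.window_samples
        for _ in range(200):
            scores = rng.integers(1, 5, size=n)
            level = pk.window_flexo_score(pk.dwell_times(scores, CFG), CFG)
            assert 1 <= level <= 4


class TestWindowAdjustment:
    def test_sustained_large_twist_adds_one(self):
        assert pk.window_adjustment(np.full(22500, 45.0), CFG) == 1

    def test_inside_band_adds_nothing(self):
        assert pk.window_adjustment(np.full(22500, 5.0), CFG) == 0

    def test_dwell_just_below_threshold(self):
        angles = np.concatenate([np.full(59 * 75, 15.0), np.zeros(241 * 75)])
        assert pk.window_adjustment(angles, CFG) == 0

    def test_negative_angles_count(self):
        assert pk.window_adjustment(np.full(22500, -45.0), CFG) == 1

    def test_nan_rejected(self):
        with pytest.raises(pk.DataError):
            pk.window_adjustment(np.array([np.nan]), CFG)


class TestSegmentScore:
    @pytest.mark.parametrize("args,expected", [((4, 1, 1), 6), ((1, 0, 0), 1), ((3, 1, 0), 4)])
    def test_sum(self, args, expected):
        assert pk.segment_score(*args) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pk.segment_score(5, 0, 0)
        with pytest.raises(ValueError):
            pk.segment_score(3, 2, 0)


# ---------------------------------------------------------------------------
# look-up tables

class TestTableB:
    def test_minimal_cell(self):
        assert pk.table_b(1, 1, 1) == 1

    def test_high_scores_reachable_with_supported_legs(self):
        values = [pk.table_b(n, s, 1) for n in range(1, 7) for s in range(1, 7)]
        assert max(values) >= 7

    def test_monotone_in_every_argument(self):
        for legs in (1, 2):
            grid = TABLE_B[:, :, legs - 1]
            assert np.all(np.diff(grid, axis=0) >= 0)
            assert np.all(np.diff(grid, axis=1) >= 0)
        assert np.all(TABLE_B[:, :, 1] >= TABLE_B[:, :, 0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pk.table_b(7, 1, 1)
        with pytest.raises(ValueError):
            pk.table_b(1, 0, 1)
        with pytest.raises(ValueError):
            pk.table_b(1, 1, 3)

    def test_checksum_pins_transcription(self):
        assert int(TABLE_B.sum()) == 438
        assert TABLE_B.min() == 1 and TABLE_B.max() == 9


class TestGrandScore:
    def test_minimal_cell(self):
        assert pk.grand_score(1, 1) == 1

    def test_section_b_six_constrains_grand_to_five(self):
        assert min(pk.grand_score(a, 6) for a in range(1, 9)) == 5

    def test_section_b_five_constrains_grand_to_four(self):
        assert min(pk.grand_score(a, 5) for a in range(1, 9)) >= 4

    def test_section_b_three_or_four_constrains_grand_to_three(self):
        for b in (3, 4):
            assert min(pk.grand_score(a, b) for a in range(1, 9)) >= 3

    def test_range_and_monotonicity(self):
        assert TABLE_C.min() == 1 and TABLE_C.max() == 7
        assert np.all(np.diff(TABLE_C, axis=0) >= 0)
        assert np.all(np.diff(TABLE_C, axis=1) >= 0)

    def test_plus_rows_clamp(self):
        assert pk.grand_score(12, 9) == pk.grand_score(8, 7)

    def test_below_range_rejected(self):
        with pytest.raises(ValueError):
            pk.grand_score(0, 1)

    def test_checksum_pins_transcription(self):
        assert int(TABLE_C.sum()) == 269


# ---------------------------------------------------------------------------
# pipeline

class TestScorePipeline:
    def test_neutral_window_scores_one(self):
        rs = pk.score_pipeline(make_constant_series("spine"), make_constant_series("neck"))
        assert len(rs) == 1
        assert rs.neck[0].segment_score == 1
        assert rs.spine[0].segment_score == 1
        assert rs.overall[0] == 1

    def test_sustained_neck_extension_scores_four(self):
        neck = make_constant_series("neck", flexion=-15.0)
        rs = pk.score_pipeline(make_constant_series("spine"), neck)
        assert rs.neck[0].flexo_score == 4

    def test_combined_spine_posture_saturates_segment_score(self):
        spine = make_constant_series("spine", flexion=90.0, bending=20.0, twist=20.0)
        rs = pk.score_pipeline(spine, make_constant_series("neck"))
        assert rs.spine[0].segment_score == 6

    def test_trailing_remainder_discarded_with_warning(self, caplog):
        spine = make_constant_series("spine", duration=400.0)
        neck = make_constant_series("neck", duration=400.0)
        with caplog.at_level("WARNING", logger="posturisk.scoring"):
            rs = pk.score_pipeline(spine, neck)
        assert len(rs) == 1
        assert any("partial window" in rec.message for rec in caplog.records)

    def test_no_full_window_rejected(self):
        spine = make_constant_series("spine", duration=200.0)
        neck = make_constant_series("neck", duration=200.0)
        with pytest.raises(pk.DataError):
            pk.score_pipeline(spine, neck)

    def test_mismatched_timestamps_rejected(self):
        spine = make_constant_series("spine")
        neck = make_constant_series("neck")
        neck.t = neck.t + 0.5
        with pytest.raises(pk.DataError):
            pk.score_pipeline(spine, neck)

    def test_monotone_in_spine_flexion(self):
        prev = (0, 0)
        for flex in (-10.0, 5.0, 25.0, 45.0, 65.0, 90.0):
            spine = make_constant_series("spine", flexion=flex)
            rs = pk.score_pipeline(spine, make_constant_series("neck"))
            cur = (rs.spine[0].segment_score, int(rs.overall[0]))
            assert cur[0] >= prev[0] and cur[1] >= prev[1]
            prev = cur


def _random_window(rng, n, fs):
    """Piecewise-constant random angles with a few change points."""
    channels = []
    for _ in range(3):
        n_seg = rng.integers(1, 6)
        bounds = np.sort(rng.integers(0, n, size=n_seg - 1)) if n_seg > 1 else np.array([], int)
        values = rng.uniform(-80, 110, size=n_seg)
        x = np.empty(n)
        edges = np.concatenate([[0], bounds, [n]])
        for v, lo, hi in zip(values, edges[:-1], edges[1:]):
            x[lo:hi] = v
        channels.append(x)
    return channels


class TestOracleEquivalence:
    def test_vectorized_window_scorer_matches_bruteforce(self):
        cfg = pk.ScoringConfig(window_len=10.0, dwell_threshold=2.0)
        rng = np.random.default_rng(11)
        n = cfg.window_samples
        for i in range(300):
            seg = "spine" if i % 2 else "neck"
            f, b, tw = _random_window(rng, n, cfg.fs)
            ws = pk.score_window(f, b, tw, seg, cfg)
            naive = reference.naive_window_score(f, b, tw, seg, cfg)
            assert ws.flexo_score == naive["flexo"]
            assert ws.twist_adj == naive["twist_adj"]
            assert ws.bend_adj == naive["bend_adj"]

    def test_full_size_windows_match_bruteforce(self):
        rng = np.random.default_rng(12)
        n = CFG.window_samples
        for i in range(10):
            seg = "spine" if i % 2 else "neck"
            f, b, tw = _random_window(rng, n, CFG.fs)
            ws = pk.score_window(f, b, tw, seg, CFG)
            naive = reference.naive_window_score(f, b, tw, seg, CFG)
            assert (ws.flexo_score, ws.twist_adj, ws.bend_adj) == \
                (naive["flexo"], naive["twist_adj"], naive["bend_adj"])


class TestSummarize:
    def test_single_window(self):
        rs = pk.score_pipeline(make_constant_series("spine", flexion=90.0, twist=20.0, bending=20.0),
                               make_constant_series("neck", flexion=-15.0))
        summary = pk.summarize(rs)
        overall = int(rs.overall[0])
        assert summary["overall"][overall] == {"windows": 1, "fraction": 1.0, "minutes": 5.0}

    def test_two_level_split(self):
        import pandas as pd
        df = pd.DataFrame({
            "window_start_s": [0.0, 300.0], "window_end_s": [300.0, 600.0],
            "neck_flexo": [1, 1], "neck_adj": [0, 0], "neck_score": [1, 1],
            "spine_flexo": [1, 1], "spine_adj": [0, 0], "spine_score": [1, 1],
            "legs": [1, 1], "overall_score": [5, 7],
        })
        summary = pk.summarize(df)
        assert summary["overall"][5]["fraction"] == 0.5
        assert summary["overall"][7]["fraction"] == 0.5

    def test_fractions_sum_to_one(self):
        rs = pk.score_pipeline(make_constant_series("spine", duration=900.0, flexion=30.0),
                               make_constant_series("neck", duration=900.0))
        summary = pk.summarize(rs)
        for key in ("neck", "spine", "overall"):
            assert sum(v["fraction"] for v in summary[key].values()) == pytest.approx(1.0, abs=1e-12)

    def test_empty_rejected(self):
        import pandas as pd
        with pytest.raises(pk.DataError):
            pk.summarize(pd.DataFrame(columns=list(pk.imu_io.SCORE_COLUMNS)))
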