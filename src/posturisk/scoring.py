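"""RULA-derived ergonomic risk index for spine and neck angle series.

The scoring chain, applied independently to each body segment:

1. *Smoothing* — a centered moving-average low-pass filter (default 875
   samples at 75 Hz, i.e. ~11.7 s, with a -3 dB cutoff of 0.038 Hz)
   suppresses postures held only briefly; a 3-s, 30-degree transient is
   attenuated to well below every decision threshold.
2. *Windowing* — the filtered series is divided into consecutive,
   non-overlapping (tumbling) 5-minute windows; a trailing partial window
   is discarded with a logged warning, because the dwell-time rule is only
   guaranteed well-defined on full windows.
3. *Quantization* — per-sample staircase mapping of the flexion angle to a
   score 1-4 (spine thresholds 0/20/60 degrees; neck thresholds 0/10/20,
   with any neck extension scored 4).
4. *Dwell-time selection* — the window's flexion score is the highest
   level held for a cumulative time longer than the dwell threshold
   (default 60 s).  With four levels and a 300-s window some level always
   accumulates >= 75 s, so the rule is always defined.
5. *Adjustments* — +1 each for twist and for lateral bending whenever the
   angle stays outside the [-10, +10]-degree band for longer than the
   dwell threshold; segment score = flexion score + adjustments (1-6).
6. *Combination* — neck and spine segment scores enter the published
   section-B look-up table together with the legs/feet support score
   (constant by default) to give the overall head-and-trunk score.

A separate grand-score table combines the section-B result (optionally
augmented by muscle-use and force/load terms, which this system never
estimates from data) with an externally supplied arm-and-wrist score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .imu_io import DEFAULT_FS, SCORE_COLUMNS, DataError
from .kinematics import SegmentAngleSeries
from .rula_tables import TABLE_B, TABLE_C

logger = logging.getLogger(__name__)


@dataclass
class ScoringConfig:
    """Tunable parameters of the risk-index algorithm.

    Defaults reproduce the platform's operating point; every threshold is
    adjustable to re-weight postures.
    """

    fs: float = DEFAULT_FS
    filter_len: int = 875            # samples; odd => exactly centered
    window_len: float = 300.0        # seconds per tumbling window
    dwell_threshold: float = 60.0    # seconds; "longer than" is strict
    spine_flexion_thresholds: tuple = (0.0, 20.0, 60.0)   # degrees
    neck_flexion_thresholds: tuple = (0.0, 10.0, 20.0)    # degrees
    twist_bend_band: float = 10.0    # degrees; band is [-band, +band]
    legs_score: int = 1              # 1 = supported/balanced, 2 otherwise
    neck_extension_score: int = 4    # score for any neck flexion < 0
    muscle_score: int = 0            # optional section-B addition (never estimated)
    force_score: int = 0             # optional section-B addition (never estimated)

    def __post_init__(self) -> None:
        self.spine_flexion_thresholds = tuple(float(x) for x in self.spine_flexion_thresholds)
        self.neck_flexion_thresholds = tuple(float(x) for x in self.neck_flexion_thresholds)
        for thr in (self.spine_flexion_thresholds, self.neck_flexion_thresholds):
            if len(thr) != 3 or np.any(np.diff(thr) <= 0):
                raise ValueError("flexion thresholds must be three strictly increasing values")
        if not (self.window_len > self.dwell_threshold > 0):
            raise ValueError("require window_len > dwell_threshold > 0")
        if self.twist_bend_band <= 0:
            raise ValueError("twist_bend_band must be positive")
        if self.filter_len < 1:
            raise ValueError("filter_len must be at least 1")
        if self.legs_score not in (1, 2):
            raise ValueError("legs_score must be 1 or 2")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def window_samples(self) -> int:
        return int(round(self.window_len * self.fs))

    def to_dict(self) -> dict:
        return {
            "fs": self.fs, "filter_len": self.filter_len, "window_len": self.window_len,
            "dwell_threshold": self.dwell_threshold,
            "spine_flexion_thresholds": list(self.spine_flexion_thresholds),
            "neck_flexion_thresholds": list(self.neck_flexion_thresholds),
            "twist_bend_band": self.twist_bend_band, "legs_score": self.legs_score,
            "neck_extension_score": self.neck_extension_score,
            "muscle_score": self.muscle_score, "force_score": self.force_score,
        }

    @classmethod
    def from_file(cls, path) -> "ScoringConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)


# ---------------------------------------------------------------------------
# smoothing

def moving_average(x: np.ndarray, filter_len: int) -> np.ndarray:
    """Centered moving average with renormalized partial windows at the edges.

    DC gain is exactly 1 everywhere (each output is a true mean of the
    samples its window covers), so a constant input is reproduced and block
    edges are not biased toward zero.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    left = (filter_len - 1) // 2
    right = filter_len - 1 - left
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(n)
    lo = np.maximum(idx - left, 0)
    hi = np.minimum(idx + right + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def moving_average_response(freq_hz, filter_len: int, fs: float) -> np.ndarray:
    """Magnitude response of the length-``filter_len`` moving average at ``fs``."""
    f = np.asarray(freq_hz, dtype=float)
    x = np.pi * f / fs
    with np.errstate(invalid="ignore", divide="ignore"):
        H = np.sin(filter_len * x) / (filter_len * np.sin(x))
    return np.abs(np.where(f == 0, 1.0, H))


def cutoff_frequency(filter_len: int, fs: float) -> float:
    """Numerically locate the filter's -3 dB (|H| = 1/sqrt(2)) frequency in Hz."""
    from scipy.optimize import brentq

    target = 1.0 / np.sqrt(2.0)
    upper = fs / filter_len  # first spectral null; the -3 dB point is below it
    return float(brentq(lambda f: moving_average_response(f, filter_len, fs) - target,
                        1e-12, upper * 0.999))


def smooth(series: SegmentAngleSeries, cfg: ScoringConfig) -> SegmentAngleSeries:
    """Low-pass filter all three angle channels of a series."""
    if len(series) < 3:
        raise DataError("series too short to smooth (need at least 3 samples)")
    return SegmentAngleSeries(
        series.segment, series.t.copy(),
        moving_average(series.flexion, cfg.filter_len),
        moving_average(series.bending, cfg.filter_len),
        moving_average(series.twist, cfg.filter_len),
        fs=series.fs,
    )


# ---------------------------------------------------------------------------
# quantization and per-window scoring

def quantize_flexion(angle, segment: str, cfg: ScoringConfig | None = None):
    """Staircase mapping of flexion-extension angle(s) to a score 1-4.

    Spine: (-inf, 0] -> 1, (0, 20] -> 2, (20, 60] -> 3, (60, inf) -> 4.
    Neck:  flexion < 0 (extension) -> 4; [0, 10] -> 1, (10, 20] -> 2,
    (20, inf) -> 3.  Exact-threshold inputs take the lower score.
    """
    cfg = cfg or ScoringConfig()
    a = np.asarray(angle, dtype=float)
    if np.isnan(a).any():
        raise DataError("NaN flexion angle")
    if segment == "spine":
        thr = np.asarray(cfg.spine_flexion_thresholds)
        score = 1 + np.searchsorted(thr, a, side="left")
    elif segment == "neck":
        thr = np.asarray(cfg.neck_flexion_thresholds)
        score = np.where(
            a < thr[0],
            cfg.neck_extension_score,
            1 + np.searchsorted(thr[1:], a, side="left"),
        )
    else:
        raise ValueError(f"unknown segment {segment!r}")
    return int(score) if np.isscalar(angle) else score.astype(int)


def dwell_times(instant_scores, cfg: ScoringConfig) -> dict[int, float]:
    """Seconds accumulated at each score level within one window."""
    s = np.asarray(instant_scores)
    if s.size == 0:
        raise DataError("empty window")
    levels, counts = np.unique(s, return_counts=True)
    return {int(level): float(count) / cfg.fs for level, count in zip(levels, counts)}


def window_flexo_score(dwell: dict[int, float], cfg: ScoringConfig) -> int:
    """Highest score level held strictly longer than the dwell threshold.

    Always defined for full windows: with four levels and a 300-s window
    some level accumulates at least 75 s > 60 s (pigeonhole).
    """
    eligible = [level for level, seconds in dwell.items() if seconds > cfg.dwell_threshold]
    if not eligible:
        raise DataError("no score level held longer than the dwell threshold (partial window?)")
    return max(eligible)


def window_adjustment(angles, cfg: ScoringConfig) -> int:
    """1 if |angle| exceeds the twist/bend band for longer than the dwell threshold.

    The added score is capped at 1 per movement regardless of magnitude.
    """
    a = np.asarray(angles, dtype=float)
    if np.isnan(a).any():
        raise DataError("NaN twist/bend angle")
    seconds_outside = np.count_nonzero(np.abs(a) > cfg.twist_bend_band) / cfg.fs
    return int(seconds_outside > cfg.dwell_threshold)


def segment_score(flexo: int, twist_adj: int, bend_adj: int) -> int:
    """Segment score 1-6: flexion score plus the two adjustment points."""
    if not 1 <= flexo <= 4:
        raise ValueError("flexo score must be 1-4")
    if twist_adj not in (0, 1) or bend_adj not in (0, 1):
        raise ValueError("adjustments must be 0 or 1")
    return flexo + twist_adj + bend_adj


def table_b(neck_score: int, spine_score: int, legs: int = 1) -> int:
    """Section-B look-up: overall head-and-trunk score from segment scores."""
    if not (1 <= neck_score <= 6 and 1 <= spine_score <= 6):
        raise ValueError("neck and spine scores must be 1-6")
    if legs not in (1, 2):
        raise ValueError("legs must be 1 or 2")
    return int(TABLE_B[neck_score - 1, spine_score - 1, legs - 1])


def grand_score(score_a: int, score_b_final: int) -> int:
    """Final RULA score 1-7 from the arm/wrist and neck-trunk-legs sections.

    ``score_b_final`` is the section-B score plus any muscle-use and
    force/load terms.  Values above the printed 8/7 maxima clamp to the
    last row/column per the published "8+" / "7+" convention.
    """
    if score_a < 1 or score_b_final < 1:
        raise ValueError("section scores must be at least 1")
    a = min(int(score_a), TABLE_C.shape[0])
    b = min(int(score_b_final), TABLE_C.shape[1])
    return int(TABLE_C[a - 1, b - 1])


@dataclass
class WindowScore:
    """Scores of one body segment over one full analysis window."""

    window_index: int
    segment: str
    flexo_score: int
    twist_adj: int
    bend_adj: int

    def __post_init__(self) -> None:
        # raises on out-of-range components
        segment_score(self.flexo_score, self.twist_adj, self.bend_adj)

    @property
    def segment_score(self) -> int:
        return self.flexo_score + self.twist_adj + self.bend_adj


@dataclass
class RiskIndexSeries:
    """Per-window neck, spine and combined head-and-trunk scores."""

    window_start_s: np.ndarray
    window_end_s: np.ndarray
    neck: list[WindowScore]
    spine: list[WindowScore]
    legs: int
    overall: np.ndarray

    def __len__(self) -> int:
        return len(self.neck)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "window_start_s": np.asarray(self.window_start_s, float),
            "window_end_s": np.asarray(self.window_end_s, float),
            "neck_flexo": [w.flexo_score for w in self.neck],
            "neck_adj": [w.twist_adj + w.bend_adj for w in self.neck],
            "neck_score": [w.segment_score for w in self.neck],
            "spine_flexo": [w.flexo_score for w in self.spine],
            "spine_adj": [w.twist_adj + w.bend_adj for w in self.spine],
            "spine_score": [w.segment_score for w in self.spine],
            "legs": self.legs,
            "overall_score": np.asarray(self.overall, int),
        }, columns=list(SCORE_COLUMNS))


def score_window(flexion, bending, twist, segment: str, cfg: ScoringConfig,
                 window_index: int = 0) -> WindowScore:
    """Score one full window of already-filtered angles for one segment."""
    instant = quantize_flexion(flexion, segment, cfg)
    flexo = window_flexo_score(dwell_times(instant, cfg), cfg)
    return WindowScore(
        window_index, segment, flexo,
        twist_adj=window_adjustment(twist, cfg),
        bend_adj=window_adjustment(bending, cfg),
    )


def score_pipeline(spine: SegmentAngleSeries, neck: SegmentAngleSeries,
                   cfg: ScoringConfig | None = None) -> RiskIndexSeries:
    """Full scoring chain on one contiguous pair of angle series.

    Smooths both series, tiles them into tumbling full windows (trailing
    remainder discarded with a warning), scores each window per segment and
    combines via the section-B table with the configured legs score.
    """
    cfg = cfg or ScoringConfig(fs=spine.fs)
    if len(spine) != len(neck) or not np.array_equal(spine.t, neck.t):
        raise DataError("spine and neck series must share timestamps")
    spine_f = smooth(spine, cfg)
    neck_f = smooth(neck, cfg)
    wlen = cfg.window_samples
    n_win = len(spine_f) // wlen
    if n_win == 0:
        raise DataError(
            f"series of {len(spine_f) / cfg.fs:.1f} s holds no full {cfg.window_len:.0f}-s window"
        )
    remainder = len(spine_f) - n_win * wlen
    if remainder:
        logger.warning("discarding trailing partial window of %.1f s", remainder / cfg.fs)

    starts, ends, neck_scores, spine_scores, overall = [], [], [], [], []
    for w in range(n_win):
        lo, hi = w * wlen, (w + 1) * wlen
        ws_spine = score_window(spine_f.flexion[lo:hi], spine_f.bending[lo:hi],
                                spine_f.twist[lo:hi], "spine", cfg, w)
        ws_neck = score_window(neck_f.flexion[lo:hi], neck_f.bending[lo:hi],
                               neck_f.twist[lo:hi], "neck", cfg, w)
        starts.append(float(spine_f.t[lo]))
        ends.append(float(spine_f.t[lo]) + cfg.window_len)
        spine_scores.append(ws_spine)
        neck_scores.append(ws_neck)
        overall.append(table_b(ws_neck.segment_score, ws_spine.segment_score, cfg.legs_score))
    return RiskIndexSeries(np.asarray(starts), np.asarray(ends),
                           neck_scores, spine_scores, cfg.legs_score,
                           np.asarray(overall, dtype=int))


def summarize(series) -> dict:
    """Time fractions and minutes per score level for neck, spine and overall.

    Accepts a :class:`RiskIndexSeries` or a score DataFrame.  Fractions sum
    to 1 per output.
    """
    df = series.to_frame() if hasattr(series, "to_frame") else series
    if len(df) == 0:
        raise DataError("no windows to summarize")
    minutes = (df["window_end_s"] - df["window_start_s"]).to_numpy() / 60.0
    out = {"n_windows": int(len(df)), "total_minutes": float(minutes.sum())}
    for key, col in (("neck", "neck_score"), ("spine", "spine_score"),
                     ("overall", "overall_score")):
        scores = df[col].to_numpy(dtype=int)
        out[key] = {
            int(level): {
                "windows": int(np.count_nonzero(scores == level)),
                "fraction": float(np.count_nonzero(scores == level) / len(df)),
                "minutes": float(minutes[scores == level].sum()),
            }
            for level in np.unique(scores)
        }
    return out
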