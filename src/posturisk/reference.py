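"""Deliberately naive per-sample reference scorer (oracle pattern).

This module re-implements the smoothing and window-scoring rules with plain
loops and scalar conditionals, independently of the vectorized production
code in :mod:`posturisk.scoring`.  The synthetic generator uses it to attach
expected scores to its ground truth, and equivalence tests compare it
against the production scorer.  Keep it boring: clarity over speed, and no
shared code paths with the implementation under test (the published look-up
table constants are shared data, pinned elsewhere by checksum tests).
"""

from __future__ import annotations

import numpy as np

from .rula_tables import TABLE_B
from .scoring import ScoringConfig


def naive_moving_average(x, filter_len: int) -> np.ndarray:
    """Per-sample centered mean over whatever part of the window is in range."""
    x = np.asarray(x, dtype=float)
    n = x.size
    left = (filter_len - 1) // 2
    right = filter_len - 1 - left
    out = np.empty(n)
    for i in range(n):
        lo = max(i - left, 0)
        hi = min(i + right + 1, n)
        out[i] = float(np.sum(x[lo:hi])) / (hi - lo)
    return out


def naive_quantize(angle: float, segment: str, cfg: ScoringConfig) -> int:
    if segment == "spine":
        t0, t1, t2 = cfg.spine_flexion_thresholds
        if angle <= t0:
            return 1
        if angle <= t1:
            return 2
        if angle <= t2:
            return 3
        return 4
    t0, t1, t2 = cfg.neck_flexion_thresholds
    if angle < t0:
        return cfg.neck_extension_score
    if angle <= t1:
        return 1
    if angle <= t2:
        return 2
    return 3


def naive_window_score(flexion, bending, twist, segment: str, cfg: ScoringConfig) -> dict:
    """Score one full window of already-filtered angles, one sample at a time."""
    # count whole samples and divide once, so a dwell exactly at the
    # threshold stays exact instead of drifting through float accumulation
    samples_at: dict[int, int] = {}
    twist_outside = 0
    bend_outside = 0
    for f, b, tw in zip(flexion, bending, twist):
        level = naive_quantize(float(f), segment, cfg)
        samples_at[level] = samples_at.get(level, 0) + 1
        if abs(float(tw)) > cfg.twist_bend_band:
            twist_outside += 1
        if abs(float(b)) > cfg.twist_bend_band:
            bend_outside += 1
    flexo = None
    for level, count in samples_at.items():
        if count / cfg.fs > cfg.dwell_threshold and (flexo is None or level > flexo):
            flexo = level
    if flexo is None:
        raise ValueError("no level held longer than the dwell threshold")
    twist_adj = 1 if twist_outside / cfg.fs > cfg.dwell_threshold else 0
    bend_adj = 1 if bend_outside / cfg.fs > cfg.dwell_threshold else 0
    return {
        "flexo": flexo,
        "twist_adj": twist_adj,
        "bend_adj": bend_adj,
        "score": flexo + twist_adj + bend_adj,
    }


def naive_score_series(spine_angles, neck_angles, cfg: ScoringConfig) -> list[dict]:
    """Full naive chain: smooth each channel, then score every full window.

    ``spine_angles`` / ``neck_angles`` are (flexion, bending, twist) triples
    of equal-length arrays.  Returns one dict per full window.
    """
    smoothed = {}
    for name, channels in (("spine", spine_angles), ("neck", neck_angles)):
        smoothed[name] = tuple(naive_moving_average(c, cfg.filter_len) for c in channels)
    n = smoothed["spine"][0].size
    wlen = cfg.window_samples
    windows = []
    for w in range(n // wlen):
        lo, hi = w * wlen, (w + 1) * wlen
        per_seg = {}
        for name in ("spine", "neck"):
            f, b, tw = (c[lo:hi] for c in smoothed[name])
            per_seg[name] = naive_window_score(f, b, tw, name, cfg)
        overall = int(TABLE_B[per_seg["neck"]["score"] - 1,
                              per_seg["spine"]["score"] - 1,
                              cfg.legs_score - 1])
        windows.append({
            "window_index": w,
            "neck_flexo": per_seg["neck"]["flexo"],
            "neck_twist_adj": per_seg["neck"]["twist_adj"],
            "neck_bend_adj": per_seg["neck"]["bend_adj"],
            "neck_score": per_seg["neck"]["score"],
            "spine_flexo": per_seg["spine"]["flexo"],
            "spine_twist_adj": per_seg["spine"]["twist_adj"],
            "spine_bend_adj": per_seg["spine"]["bend_adj"],
            "spine_score": per_seg["spine"]["score"],
            "overall": overall,
        })
    return windows
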