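"""Forward simulation of three-sensor recordings from posture scenarios.

The study's recordings are not public, so every pipeline stage is exercised
on synthetic data instead.  A :class:`ScenarioSpec` declares, per segment
(spine, neck) and channel (flexion, bending, twist), piecewise-constant
target angles joined by short linear ramps, plus optional short rectangular
spikes (transients the smoothing filter should absorb), per-sample
orientation noise, and an arbitrary global base orientation of the scene.

The forward model inverts the kinematic chain: the sacral sensor carries the
global base orientation, the thoracic sensor adds the spine rotation
composed from the declared Euler sequence, and the head sensor adds the
neck rotation on top.  Sensor noise is modelled as an independent
axis-angle perturbation of each sample with Gaussian magnitude (default
2 degrees RMS, the stated dynamic accuracy of the sensors); no temporal
noise structure is imposed.

The first seconds of every scenario (default 5 s) are exactly neutral so a
calibration window is always available.  Ground truth carries the noiseless
angle series and the expected per-window scores computed by the naive
reference scorer in :mod:`posturisk.reference`, never by the production
scorer under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .imu_io import DataError, OrientationStream, StreamTriplet
from .kinematics import SegmentAngleSeries, compose_angles
from .reference import naive_score_series
from .scoring import ScoringConfig

SEGMENTS = ("spine", "neck")
CHANNELS = ("flexion", "bending", "twist")

PRESET_NAMES = ("neutral", "laparoscopy_like", "laparotomy_like", "spiky")


@dataclass
class Spike:
    """Short rectangular angle transient (default 3 s, 30 degrees)."""

    t: float
    segment: str
    channel: str
    duration: float = 3.0
    amplitude: float = 30.0


@dataclass
class ScenarioSpec:
    """Declarative synthetic posture scenario.

    ``targets`` maps ``"<segment>.<channel>"`` (e.g. ``"spine.flexion"``)
    to a list of ``(time_s, target_deg)`` steps; the angle starts at 0,
    and at each step ramps linearly over ``ramp_s`` seconds to the new
    target, then holds.  All transitions and spikes must start at or after
    ``calibration_duration`` so the calibration window stays neutral.
    """

    duration: float
    fs: float = 75.0
    targets: dict = field(default_factory=dict)
    ramp_s: float = 2.0
    noise_rms: float = 2.0           # degrees RMS per-sample orientation noise
    spikes: list = field(default_factory=list)
    global_base: np.ndarray | None = None
    calibration_duration: float = 5.0
    seed: int = 0

    def validate(self) -> "ScenarioSpec":
        if self.duration <= self.calibration_duration:
            raise ValueError("duration must exceed the calibration window")
        if self.noise_rms < 0:
            raise ValueError("noise_rms must be non-negative")
        if self.ramp_s < 0:
            raise ValueError("ramp_s must be non-negative")
        for key, steps in self.targets.items():
            seg, _, chan = key.partition(".")
            if seg not in SEGMENTS or chan not in CHANNELS:
                raise ValueError(f"unknown target key {key!r}")
            times = [s[0] for s in steps]
            if times != sorted(times):
                raise ValueError(f"{key}: transition times must be ordered")
            if times and times[0] < self.calibration_duration:
                raise ValueError(f"{key}: transitions must start after the calibration window")
        for spike in self.spikes:
            if spike.segment not in SEGMENTS or spike.channel not in CHANNELS:
                raise ValueError(f"spike targets unknown channel {spike.segment}.{spike.channel}")
            if spike.t < self.calibration_duration or spike.t + spike.duration > self.duration:
                raise ValueError("spike outside the scenario duration")
        return self


@dataclass
class GroundTruth:
    """Noiseless angle series plus reference-scored expectations."""

    spine: SegmentAngleSeries
    neck: SegmentAngleSeries
    windows: list            # expected scores per full post-calibration window
    analysis_start: float    # seconds; end of the calibration window


def _angle_profile(t: np.ndarray, steps, ramp_s: float) -> np.ndarray:
    """Piecewise-constant profile with linear ramps, via interpolation knots."""
    xs = [t[0] - 1.0]
    ys = [0.0]
    prev = 0.0
    for time_s, target in steps:
        xs.extend([time_s, time_s + max(ramp_s, 1e-9)])
        ys.extend([prev, float(target)])
        prev = float(target)
    return np.interp(t, xs, ys)


def synthesize(spec: ScenarioSpec, compute_scores: bool = True) -> tuple[StreamTriplet, GroundTruth]:
    """Forward-simulate a scenario into sensor streams plus ground truth.

    Identical specs (including seed) produce bitwise-identical streams.
    """
    spec.validate()
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs

    angles = {}
    for seg in SEGMENTS:
        for chan in CHANNELS:
            profile = _angle_profile(t, spec.targets.get(f"{seg}.{chan}", []), spec.ramp_s)
            angles[(seg, chan)] = profile
    for spike in spec.spikes:
        mask = (t >= spike.t) & (t < spike.t + spike.duration)
        angles[(spike.segment, spike.channel)] = angles[(spike.segment, spike.channel)].copy()
        angles[(spike.segment, spike.channel)][mask] += spike.amplitude

    gt = {
        seg: SegmentAngleSeries(
            seg, t.copy(),
            angles[(seg, "flexion")], angles[(seg, "bending")], angles[(seg, "twist")],
            fs=spec.fs,
        )
        for seg in SEGMENTS
    }

    R_spine = compose_angles(gt["spine"].flexion, gt["spine"].bending, gt["spine"].twist)
    R_neck = compose_angles(gt["neck"].flexion, gt["neck"].bending, gt["neck"].twist)
    base = np.eye(3) if spec.global_base is None else np.asarray(spec.global_base, float)
    R1 = np.broadcast_to(base, (n, 3, 3)).copy()
    R2 = np.matmul(R1, R_spine)
    R3 = np.matmul(R2, R_neck)

    if spec.noise_rms > 0:
        rng = np.random.default_rng(spec.seed)
        sigma = np.radians(spec.noise_rms)
        for R in (R1, R2, R3):
            axes = rng.normal(size=(n, 3))
            axes /= np.linalg.norm(axes, axis=1, keepdims=True)
            mags = rng.normal(0.0, sigma, size=(n, 1))
            R[:] = np.matmul(R, Rotation.from_rotvec(axes * mags).as_matrix())

    triplet = StreamTriplet(
        OrientationStream("IMU1", spec.fs, t.copy(), R1),
        OrientationStream("IMU2", spec.fs, t.copy(), R2),
        OrientationStream("IMU3", spec.fs, t.copy(), R3),
    )

    windows: list = []
    start_idx = int(round(spec.calibration_duration * spec.fs))
    cfg = ScoringConfig(fs=spec.fs)
    if compute_scores and (n - start_idx) >= cfg.window_samples:
        windows = naive_score_series(
            tuple(angles[("spine", c)][start_idx:] for c in CHANNELS),
            tuple(angles[("neck", c)][start_idx:] for c in CHANNELS),
            cfg,
        )
    truth = GroundTruth(gt["spine"], gt["neck"], windows, spec.calibration_duration)
    return triplet, truth


def preset(name: str, seed: int = 0, duration: float | None = None) -> ScenarioSpec:
    """Named scenario presets.

    * ``neutral`` — upright standing throughout; noiseless so it doubles as
      a deterministic regression baseline (a truly neutral neck sits exactly
      on the extension threshold, where sensor noise would make the filtered
      sign, and hence the neck score, non-reproducible).
    * ``laparoscopy_like`` — sustained neck extension (-15 deg) with spine
      flexion (30 deg) and right lateral bending (15 deg); 2 deg RMS noise.
      Every active channel keeps a >= 5 deg margin from its threshold.
    * ``laparotomy_like`` — prolonged forward flexion of both neck (15 deg)
      and spine (30 deg) with a twisted neck (15 deg); 2 deg RMS noise.
    * ``spiky`` — neutral baseline carrying 3-s, 30-degree transients; the
      smoothing filter absorbs them, so end-to-end scores equal ``neutral``.
    """
    onset = 6.0
    if name == "neutral":
        spec = ScenarioSpec(duration=600.0, noise_rms=0.0, seed=seed)
    elif name == "laparoscopy_like":
        spec = ScenarioSpec(
            duration=600.0,
            targets={
                "neck.flexion": [(onset, -15.0)],
                "spine.flexion": [(onset, 30.0)],
                "spine.bending": [(onset, 15.0)],
            },
            noise_rms=2.0, seed=seed,
        )
    elif name == "laparotomy_like":
        spec = ScenarioSpec(
            duration=600.0,
            targets={
                "neck.flexion": [(onset, 15.0)],
                "spine.flexion": [(onset, 30.0)],
                "neck.twist": [(onset, 15.0)],
            },
            noise_rms=2.0, seed=seed,
        )
    elif name == "spiky":
        spec = ScenarioSpec(
            duration=600.0, noise_rms=0.0, seed=seed,
            spikes=[
                Spike(60.0, "spine", "flexion"),
                Spike(150.0, "neck", "twist"),
                Spike(290.0, "spine", "twist", amplitude=-30.0),
                Spike(420.0, "neck", "flexion"),
                Spike(520.0, "spine", "bending"),
            ],
        )
    else:
        raise ValueError(f"unknown preset {name!r} (choose from {PRESET_NAMES})")
    if duration is not None:
        spec = replace(spec, duration=float(duration))
    return spec.validate()
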