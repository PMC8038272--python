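"""Joint-angle extraction from calibrated IMU orientation streams.

The spine is modelled as a single joint between the sacral (IMU1) and
thoracic (IMU2) sensors, the neck as a joint between the thoracic and head
(IMU3) sensors.  The chain is:

1. *Neutral calibration* — while the subject stands upright in the
   anatomical position for a few seconds, each sensor's neutral orientation
   ``R0`` is estimated as the chordal (projected arithmetic) mean of its
   samples.  Every later sample is re-expressed relative to neutral,
   ``R_new = R0^-1 R``.
2. *Relative segment rotation* — ``R_spine = R_IMU1^-1 R_IMU2`` and
   ``R_neck = R_IMU2^-1 R_IMU3`` on the calibrated streams.  Both are
   invariant to any common global re-orientation of the scene.
3. *Anatomical decomposition* — each relative rotation is split into
   flexion-extension (medio-lateral X axis; forward flexion positive,
   extension negative), lateral bending (antero-posterior Y axis; right
   bend positive) and axial twist (longitudinal Z axis; rightward
   rotation positive), using the intrinsic X-Y-Z Euler sequence

       R = Rx(flexion) @ Ry(bending) @ Rz(twist).

Flexion — the dominant driver of the ergonomic score — is the first, least
distorted angle of the sequence.  Samples whose bending angle falls within
half a degree of ±90° (gimbal band) are flagged but still returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.transform import Rotation

from .imu_io import (
    ANGLE_COLUMNS,
    DEFAULT_FS,
    DataError,
    OrientationStream,
    StreamTriplet,
    detect_gaps,
    orthonormalize,
)

EULER_SEQUENCE = "XYZ"   # intrinsic: flexion -> lateral bending -> twist
GIMBAL_BAND_DEG = 0.5

SEGMENTS = ("spine", "neck")


def compose_angles(flexion, bending, twist, degrees: bool = True) -> np.ndarray:
    """Rotation matrix (or stack) from anatomical angles in the declared sequence."""
    ang = np.stack(np.broadcast_arrays(
        np.asarray(flexion, float), np.asarray(bending, float), np.asarray(twist, float)
    ), axis=-1)
    return Rotation.from_euler(EULER_SEQUENCE, ang, degrees=degrees).as_matrix()


def euler_decompose(R: np.ndarray):
    """Split rotation(s) into (flexion, bending, twist, gimbal_flag), degrees.

    Recomposing the three angles with :func:`compose_angles` reproduces the
    input to numerical precision outside the gimbal band.  Outputs lie in
    [-180, 180].
    """
    ang = Rotation.from_matrix(R).as_euler(EULER_SEQUENCE, degrees=True)
    flexion, bending, twist = ang[..., 0], ang[..., 1], ang[..., 2]
    flag = np.abs(np.abs(bending) - 90.0) < GIMBAL_BAND_DEG
    if np.any(flag):
        warnings.warn(
            "lateral bending within 0.5 deg of +/-90: flexion/twist split unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    return flexion, bending, twist, flag


def chordal_mean(Rs: np.ndarray) -> np.ndarray:
    """Chordal L2 mean: element-wise average projected onto the rotation group.

    Unique and well-conditioned for tightly clustered samples, which is the
    regime of a static calibration pose.
    """
    return orthonormalize(np.asarray(Rs, float).mean(axis=0))


def geodesic_angle_deg(Ra: np.ndarray, Rb: np.ndarray) -> float:
    """Rotation angle between two orientations, in degrees."""
    cos = (np.trace(Ra.T @ Rb) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


@dataclass
class CalibrationPose:
    """Per-sensor neutral reference orientations captured while standing upright."""

    R0: dict[str, np.ndarray]
    capture_start: float
    capture_duration: float = 5.0

    def __post_init__(self) -> None:
        if self.capture_duration <= 0:
            raise ValueError("capture_duration must be positive")
        self.R0 = {k: np.asarray(v, float) for k, v in self.R0.items()}

    def save(self, path) -> None:
        doc = {
            "capture_start": float(self.capture_start),
            "capture_duration": float(self.capture_duration),
            "R0": {k: [float(x) for x in v.ravel()] for k, v in self.R0.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "CalibrationPose":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        R0 = {k: np.asarray(v, float).reshape(3, 3) for k, v in doc["R0"].items()}
        return cls(R0, doc["capture_start"], doc["capture_duration"])


def calibrate(triplet: StreamTriplet, t_start: float = 0.0, duration: float = 5.0) -> CalibrationPose:
    """Estimate each sensor's neutral orientation from a static standing window.

    The window ``[t_start, t_start + duration)`` must lie inside a contiguous
    block of every stream; a window that spans a data gap or falls outside
    the recording raises :class:`DataError`.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    R0: dict[str, np.ndarray] = {}
    for stream in triplet.streams():
        eps = 0.5 / stream.fs
        if t_start < stream.t[0] - eps or t_start + duration > stream.t[-1] + 1.0 / stream.fs + eps:
            raise DataError(f"{stream.sensor_id}: calibration window outside recorded data")
        sel = np.flatnonzero((stream.t >= t_start) & (stream.t < t_start + duration))
        if sel.size == 0:
            raise DataError(f"{stream.sensor_id}: no samples in calibration window")
        if sel.size > 1 and np.max(np.diff(stream.t[sel])) > 3.0 / stream.fs:
            raise DataError(f"{stream.sensor_id}: calibration window spans a data gap")
        R0[stream.sensor_id] = chordal_mean(stream.R[sel])
    return CalibrationPose(R0, t_start, duration)


def apply_calibration(stream: OrientationStream, pose: CalibrationPose) -> OrientationStream:
    """Re-express a stream relative to its neutral pose: ``R_new = R0^-1 R``."""
    try:
        R0 = pose.R0[stream.sensor_id]
    except KeyError:
        raise DataError(f"calibration pose has no entry for {stream.sensor_id}") from None
    return OrientationStream(stream.sensor_id, stream.fs, stream.t.copy(), np.matmul(R0.T, stream.R))


@dataclass
class SegmentRotationSeries:
    """Relative parent-to-child rotations over time for one body segment."""

    segment: str
    t: np.ndarray
    R: np.ndarray

    def __len__(self) -> int:
        return self.t.size


def segment_rotation(parent: OrientationStream, child: OrientationStream, segment: str) -> SegmentRotationSeries:
    """``R_rel = R_parent^-1 R_child`` on the streams' exact-timestamp overlap.

    Spine uses (IMU1, IMU2); neck uses (IMU2, IMU3).  Streams must share a
    clock (the acquisition hub synchronizes sensors), so overlap is by exact
    timestamp equality, never resampling.
    """
    if segment not in SEGMENTS:
        raise ValueError(f"unknown segment {segment!r}")
    common = np.intersect1d(parent.t, child.t)
    if common.size == 0:
        raise DataError(f"{segment}: streams have no common timestamps")
    Rp = parent.R[np.isin(parent.t, common)]
    Rc = child.R[np.isin(child.t, common)]
    R_rel = np.matmul(Rp.transpose(0, 2, 1), Rc)
    return SegmentRotationSeries(segment, common, R_rel)


@dataclass
class SegmentAngleSeries:
    """Flexion / lateral-bending / twist angle time series for one segment."""

    segment: str
    t: np.ndarray
    flexion: np.ndarray   # degrees; forward flexion positive
    bending: np.ndarray   # degrees; right lateral bend positive
    twist: np.ndarray     # degrees; right axial rotation positive
    fs: float = DEFAULT_FS
    gimbal_flag: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.flexion = np.asarray(self.flexion, float)
        self.bending = np.asarray(self.bending, float)
        self.twist = np.asarray(self.twist, float)
        n = self.t.size
        if not (self.flexion.size == self.bending.size == self.twist.size == n):
            raise ValueError("angle channels must share the time base")

    def __len__(self) -> int:
        return self.t.size

    def slice(self, start: int, stop: int) -> "SegmentAngleSeries":
        return SegmentAngleSeries(
            self.segment, self.t[start:stop], self.flexion[start:stop],
            self.bending[start:stop], self.twist[start:stop], self.fs,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t,
            "segment": self.segment,
            "flexion_deg": self.flexion,
            "bending_deg": self.bending,
            "twist_deg": self.twist,
        }, columns=list(ANGLE_COLUMNS))


def angle_pipeline(triplet: StreamTriplet, pose: CalibrationPose) -> dict[str, SegmentAngleSeries]:
    """Full chain: calibrate, form relative rotations, decompose to angles.

    Returns ``{"spine": ..., "neck": ...}`` on the common timestamp overlap.
    All streams constant at the calibration pose yield identically zero
    angles; a global re-orientation of every sensor leaves the output
    unchanged.
    """
    cal = [apply_calibration(s, pose) for s in triplet.streams()]
    out: dict[str, SegmentAngleSeries] = {}
    for parent, child, segment in ((cal[0], cal[1], "spine"), (cal[1], cal[2], "neck")):
        rel = segment_rotation(parent, child, segment)
        flexion, bending, twist, flag = euler_decompose(rel.R)
        out[segment] = SegmentAngleSeries(
            segment, rel.t, flexion, bending, twist, fs=triplet.imu1.fs, gimbal_flag=flag,
        )
    return out
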