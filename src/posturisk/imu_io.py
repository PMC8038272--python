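"""CSV I/O and validation for wearable-IMU orientation streams.

Three body-worn inertial sensors — sacral ``IMU1``, thoracic ``IMU2`` and
head ``IMU3`` — each report a time series of 3-D orientations at a nominal
75 Hz.  Orientations are stored as rotation matrices mapping sensor-frame
vectors to global-frame vectors.  This module reads and writes those streams
in two plain-text dialects (row-major rotation matrices, or scalar-first
unit quaternions), validates that every sample is a proper rotation, and
locates contiguous data blocks so that downstream dwell-time scoring never
spans a wireless dropout.

Dialects (long format, one row per sample per sensor):

* matrix:     ``t,sensor_id,r11,r12,r13,r21,r22,r23,r31,r32,r33``
* quaternion: ``t,sensor_id,qw,qx,qy,qz``

Derived-series schemas:

* angles: ``t,segment,flexion_deg,bending_deg,twist_deg``
* scores: ``window_start_s,window_end_s,neck_flexo,neck_adj,neck_score,
  spine_flexo,spine_adj,spine_score,legs,overall_score``
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

SENSOR_IDS = ("IMU1", "IMU2", "IMU3")
DEFAULT_FS = 75.0

MATRIX_COLUMNS = (
    "t", "sensor_id",
    "r11", "r12", "r13", "r21", "r22", "r23", "r31", "r32", "r33",
)
QUATERNION_COLUMNS = ("t", "sensor_id", "qw", "qx", "qy", "qz")
ANGLE_COLUMNS = ("t", "segment", "flexion_deg", "bending_deg", "twist_deg")
SCORE_COLUMNS = (
    "window_start_s", "window_end_s",
    "neck_flexo", "neck_adj", "neck_score",
    "spine_flexo", "spine_adj", "spine_score",
    "legs", "overall_score",
)

# Orthonormality defect below the first bound is accepted as serialization
# rounding; up to the second bound the sample is repaired by projection onto
# the rotation group; beyond it the sample is treated as corrupt.
ORTHO_PASS_TOL = 1e-6
ORTHO_REPAIR_TOL = 1e-2


class FormatError(ValueError):
    """The file's structure (columns/dialect) does not match the schema."""


class DataError(ValueError):
    """The file parsed, but its content violates a data invariant."""


def orthonormalize(M: np.ndarray) -> np.ndarray:
    """Project a 3x3 matrix (or stack of them) onto the nearest rotation.

    "Nearest" is in the Frobenius norm; the result is the special orthogonal
    polar factor ``U @ Vt`` of the SVD.  Requires ``det(M) > 0`` — a
    non-positive determinant means the sample is a reflection or degenerate
    and cannot be attributed to rounding.

    Idempotent: applying it to an exact rotation returns that rotation.
    """
    M = np.asarray(M, dtype=float)
    if M.shape[-2:] != (3, 3):
        raise ValueError(f"expected trailing 3x3 matrices, got shape {M.shape}")
    det = np.linalg.det(M)
    if np.any(det <= 0):
        raise DataError("matrix with non-positive determinant is not a recoverable rotation")
    U, _, Vt = np.linalg.svd(M)
    # det(M) > 0 guarantees det(U @ Vt) = +1: no sign correction needed.
    return U @ Vt


def _ortho_defect(R: np.ndarray) -> np.ndarray:
    eye = np.eye(3)
    return np.linalg.norm(np.matmul(np.swapaxes(R, -1, -2), R) - eye, axis=(-2, -1))


@dataclass
class OrientationStream:
    """Time series of sensor-to-global rotation matrices for one sensor."""

    sensor_id: str
    fs: float
    t: np.ndarray   # (n,) seconds, strictly increasing
    R: np.ndarray   # (n, 3, 3)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if self.t.ndim != 1 or self.R.shape != (self.t.size, 3, 3):
            raise ValueError("t must be (n,) and R must be (n, 3, 3)")

    def __len__(self) -> int:
        return self.t.size

    def validate(self) -> "OrientationStream":
        """Check invariants, repairing mildly non-orthonormal samples in place."""
        if self.sensor_id not in SENSOR_IDS:
            raise DataError(f"unknown sensor_id {self.sensor_id!r}")
        if len(self) == 0:
            raise DataError(f"{self.sensor_id}: empty stream")
        if not (np.isfinite(self.t).all() and np.isfinite(self.R).all()):
            raise DataError(f"{self.sensor_id}: non-finite values")
        if np.any(np.diff(self.t) <= 0):
            raise DataError(f"{self.sensor_id}: timestamps not strictly increasing")
        if np.any(np.linalg.det(self.R) <= 0):
            raise DataError(f"{self.sensor_id}: improper rotation (det <= 0)")
        defect = _ortho_defect(self.R)
        if np.any(defect > ORTHO_REPAIR_TOL):
            raise DataError(f"{self.sensor_id}: orientation sample too far from a rotation")
        fix = defect > ORTHO_PASS_TOL
        if fix.any():
            self.R[fix] = orthonormalize(self.R[fix])
        return self


@dataclass
class StreamTriplet:
    """The three synchronized sensor streams of one recording."""

    imu1: OrientationStream
    imu2: OrientationStream
    imu3: OrientationStream

    def streams(self) -> tuple[OrientationStream, ...]:
        return (self.imu1, self.imu2, self.imu3)

    def validate(self) -> "StreamTriplet":
        for stream, sid in zip(self.streams(), SENSOR_IDS):
            if stream.sensor_id != sid:
                raise DataError(f"expected {sid} in slot, got {stream.sensor_id}")
            stream.validate()
        if len({s.fs for s in self.streams()}) != 1:
            raise DataError("sensors disagree on sampling frequency")
        return self


@dataclass
class ContiguousBlock:
    """Half-open index range [start_index, end_index) with no internal gap."""

    start_index: int
    end_index: int
    duration: float  # seconds, t[end-1] - t[start]

    def __post_init__(self) -> None:
        if self.end_index <= self.start_index:
            raise ValueError("end_index must exceed start_index")


def detect_gaps(stream: OrientationStream, max_gap: float | None = None) -> list[ContiguousBlock]:
    """Partition a stream into contiguous blocks at inter-sample gaps.

    A gap is any inter-sample interval exceeding ``max_gap`` (default
    ``3/fs``, i.e. two consecutive missing samples).  The returned blocks
    are ordered and cover every sample exactly once.
    """
    if len(stream) == 0:
        raise DataError("cannot detect gaps in an empty stream")
    if max_gap is None:
        max_gap = 3.0 / stream.fs
    if max_gap <= 0:
        raise ValueError("max_gap must be positive")
    breaks = np.flatnonzero(np.diff(stream.t) > max_gap)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks + 1, [len(stream)]))
    return [
        ContiguousBlock(int(s), int(e), float(stream.t[e - 1] - stream.t[s]))
        for s, e in zip(starts, ends)
    ]


def common_blocks(triplet: StreamTriplet, max_gap: float | None = None) -> list[ContiguousBlock]:
    """Contiguous blocks shared by all three sensors.

    The platform's hub synchronizes sensors, so identical timestamps across
    streams are required rather than resampled.
    """
    t1 = triplet.imu1.t
    if not (np.array_equal(t1, triplet.imu2.t) and np.array_equal(t1, triplet.imu3.t)):
        raise DataError("sensor streams are not time-synchronized (timestamps differ)")
    return detect_gaps(triplet.imu1, max_gap)


# ---------------------------------------------------------------------------
# orientation CSV

def read_orientation_csv(path, dialect: str = "matrix", fs: float = DEFAULT_FS) -> StreamTriplet:
    """Read a three-sensor orientation recording from a long-format CSV."""
    if dialect == "matrix":
        expected = MATRIX_COLUMNS
    elif dialect == "quaternion":
        expected = QUATERNION_COLUMNS
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path)
    if tuple(df.columns) != expected:
        raise FormatError(
            f"columns {tuple(df.columns)} do not match the {dialect} dialect {expected}"
        )
    if df.empty:
        raise DataError("orientation file contains no samples")
    value_cols = [c for c in expected if c != "sensor_id"]
    try:
        values = df[value_cols].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise DataError(f"non-numeric value in orientation file: {exc}") from None
    if not np.isfinite(values).all():
        raise DataError("non-finite value in orientation file")
    ids = df["sensor_id"].astype(str).to_numpy()
    unknown = set(ids) - set(SENSOR_IDS)
    if unknown:
        raise DataError(f"unknown sensor_id values {sorted(unknown)}")

    streams = {}
    for sid in SENSOR_IDS:
        sel = ids == sid
        if not sel.any():
            raise DataError(f"no rows for sensor {sid}")
        t = df.loc[sel, "t"].to_numpy(dtype=float)
        if dialect == "matrix":
            R = df.loc[sel, list(MATRIX_COLUMNS[2:])].to_numpy(dtype=float).reshape(-1, 3, 3)
        else:
            q = df.loc[sel, list(QUATERNION_COLUMNS[2:])].to_numpy(dtype=float)
            norm = np.linalg.norm(q, axis=1)
            if np.any(np.abs(norm - 1.0) > ORTHO_REPAIR_TOL):
                raise DataError(f"{sid}: quaternion too far from unit norm")
            R = Rotation.from_quat(q, scalar_first=True).as_matrix()
        streams[sid] = OrientationStream(sid, fs, t, R).validate()
    return StreamTriplet(streams["IMU1"], streams["IMU2"], streams["IMU3"]).validate()


def write_orientation_csv(triplet: StreamTriplet, path, dialect: str = "matrix") -> None:
    """Write a triplet to CSV; the inverse of :func:`read_orientation_csv`."""
    frames = []
    for stream in triplet.streams():
        if dialect == "matrix":
            flat = stream.R.reshape(len(stream), 9)
            frame = pd.DataFrame(flat, columns=list(MATRIX_COLUMNS[2:]))
        elif dialect == "quaternion":
            q = Rotation.from_matrix(stream.R).as_quat(scalar_first=True)
            frame = pd.DataFrame(q, columns=list(QUATERNION_COLUMNS[2:]))
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
        frame.insert(0, "t", stream.t)
        frame.insert(1, "sensor_id", stream.sensor_id)
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["t", "sensor_id"], kind="stable", ignore_index=True)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# derived-series CSV

def write_series_csv(series, path) -> None:
    """Write an angle series or a risk-index series to its CSV schema.

    Values round-trip: reading the file back reproduces the numbers to
    better than 1e-9 (pandas writes shortest-repr float64).
    """
    if hasattr(series, "flexion"):          # SegmentAngleSeries
        if len(series) == 0:
            raise DataError("refusing to write an empty angle series")
        df = series.to_frame()
        if not np.isfinite(df[["flexion_deg", "bending_deg", "twist_deg"]].to_numpy()).all():
            raise DataError("angle series contains non-finite values")
    elif hasattr(series, "overall"):        # RiskIndexSeries
        if len(series) == 0:
            raise DataError("refusing to write an empty score series")
        df = series.to_frame()
    else:
        raise TypeError(f"cannot serialize {type(series).__name__}")
    df.to_csv(path, index=False)


def read_angle_csv(path, fs: float = DEFAULT_FS):
    """Read a single-segment angle series written by :func:`write_series_csv`."""
    from .kinematics import SegmentAngleSeries

    df = pd.read_csv(path)
    if tuple(df.columns) != ANGLE_COLUMNS:
        raise FormatError(f"columns {tuple(df.columns)} do not match the angle schema")
    if df.empty:
        raise DataError("angle file contains no samples")
    segments = df["segment"].unique()
    if len(segments) != 1:
        raise DataError(f"expected a single segment per file, found {list(segments)}")
    return SegmentAngleSeries(
        segment=str(segments[0]),
        t=df["t"].to_numpy(dtype=float),
        flexion=df["flexion_deg"].to_numpy(dtype=float),
        bending=df["bending_deg"].to_numpy(dtype=float),
        twist=df["twist_deg"].to_numpy(dtype=float),
        fs=fs,
    )


def read_score_csv(path) -> pd.DataFrame:
    """Read a per-window score table written by :func:`write_series_csv`."""
    df = pd.read_csv(path)
    if tuple(df.columns) != SCORE_COLUMNS:
        raise FormatError(f"columns {tuple(df.columns)} do not match the score schema")
    return df
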