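import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import posturisk as pk

SEED = 20260924


def make_constant_series(segment, flexion=0.0, bending=0.0, twist=0.0,
                         duration=300.0, fs=75.0):
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    return pk.SegmentAngleSeries(
        segment, t,
        np.full(n, float(flexion)), np.full(n, float(bending)), np.full(n, float(twist)),
        fs=fs,
    )


def end_to_end(name, seed):
    """Synthesize a preset and run the full production pipeline on it."""
    triplet, truth = pk.synthesize(pk.preset(name, seed=seed))
    pose = pk.calibrate(triplet, 0.0, 5.0)
    angles = pk.angle_pipeline(triplet, pose)
    i0 = int(round(truth.analysis_start * triplet.imu1.fs))
    cfg = pk.ScoringConfig(fs=triplet.imu1.fs)
    scores = pk.score_pipeline(
        angles["spine"].slice(i0, len(angles["spine"])),
        angles["neck"].slice(i0, len(angles["neck"])),
        cfg,
    )
    return {"triplet": triplet, "truth": truth, "angles": angles, "scores": scores}


@pytest.fixture(scope="session")
def neutral_run():
    return end_to_end("neutral", SEED)


@pytest.fixture(scope="session")
def spiky_run():
    return end_to_end("spiky", SEED)


@pytest.fixture(scope="session")
def laparoscopy_run():
    return end_to_end("laparoscopy_like", SEED + 1)


@pytest.fixture(scope="session")
def laparotomy_run():
    return end_to_end("laparotomy_like", SEED + 2)


def random_rotations(n, rng):
    return Rotation.random(n, random_state=rng).as_matrix()


def make_stream(sensor_id, t, R, fs=75.0):
    return pk.OrientationStream(sensor_id, fs, np.asarray(t, float), np.asarray(R, float))


def identity_triplet(n=3, fs=75.0):
    t = np.arange(n) / fs
    eye = np.broadcast_to(np.eye(3), (n, 3, 3)).copy()
    return pk.StreamTriplet(
        make_stream("IMU1", t, eye.copy(), fs),
        make_stream("IMU2", t, eye.copy(), fs),
        make_stream("IMU3", t, eye.copy(), fs),
    )
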