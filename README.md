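# posturisk

Wearable-IMU posture monitoring and RULA-derived ergonomic risk scoring for
the spine and neck.

Surgeons — especially during laparoscopic procedures — hold harmful static
postures for long stretches and are unusually prone to musculoskeletal
disorders. `posturisk` implements a sensor-based monitoring pipeline for
exactly that setting: three body-worn inertial measurement units (IMUs) at
the sacrum, mid-thorax and head stream 3-D orientations at 75 Hz, and the
package turns those streams into calibrated spine and neck joint angles and
a time-varying head-and-trunk ergonomic risk index built on the section-B
scoring structure of RULA (Rapid Upper Limb Assessment). Because such
recordings are rarely shareable, a synthetic scenario generator forward
simulates the whole sensor chain with ground truth, so every stage is
testable without hardware.

## Model

With `R_IMUk` the sensor-to-global rotation of sensor *k*, and `R0_k` its
orientation during a 5-s neutral standing calibration (chordal mean of the
window), every sample is first re-expressed relative to neutral,

    R_new = R0⁻¹ · R

and the two body segments are single joints between adjacent sensors:

    R_spine = R_IMU1⁻¹ · R_IMU2        (sacrum → thorax)
    R_neck  = R_IMU2⁻¹ · R_IMU3        (thorax → head)

Each relative rotation is decomposed (intrinsic X–Y–Z Euler sequence) into
flexion–extension, lateral bending and axial twist. The risk index then
applies, per segment:

* moving-average smoothing, 875 samples ≈ 11.7 s (−3 dB at 0.038 Hz), which
  fully absorbs transients shorter than ~3 s;
* tumbling 5-min windows;
* staircase quantization of flexion to a score 1–4 (spine thresholds
  0/20/60°; neck 0/10/20°, any neck extension → 4);
* dwell-time selection: the window's score is the highest level held for
  more than 60 s cumulative;
* +1 each for twist and lateral bending outside ±10° for more than 60 s
  (segment score 1–6);
* the published RULA section-B table combines neck, spine and legs scores
  into the overall head-and-trunk score (with supported legs, scores ≥ 7 are
  reachable and pin the grand RULA score to ≥ 5).

## Worked example

Simulate a laparoscopy-like posture — sustained neck extension (−15°),
spine flexion (30°) with right lateral bending (15°), 2° RMS sensor noise —
then score it:

```sh
posturisk simulate --preset laparoscopy_like --seed 42 --out demo/sim
posturisk score demo/sim/orientations.csv --out demo/scored
```

`demo/scored/scores.csv`:

```
window_start_s,window_end_s,neck_flexo,neck_adj,neck_score,spine_flexo,spine_adj,spine_score,legs,overall_score
5.0,305.0,4,0,4,3,1,4,1,7
```

Reading the one full 5-min window after the 5-s calibration: the extended
neck scores the maximum flexo-extension value 4; spine flexion at 30° falls
in the 20–60° band (score 3) and the sustained 15° lateral bend adds +1
(spine segment score 4); the section-B table maps (neck 4, spine 4, legs 1)
to an overall head-and-trunk score of 7 — the level that flags an urgent
need to change the working setup. The accompanying `summary.json` reports
per-level window counts, time fractions and minutes for neck, spine and
overall scores; `posturisk report demo/scored/scores.csv` prints the same
summary for any score CSV.

The library mirrors the CLI: `synthesize`/`preset`, `read_orientation_csv`,
`calibrate`, `angle_pipeline`, `score_pipeline`, `summarize`.

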