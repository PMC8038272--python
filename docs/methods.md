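# Methods

This note records the model, the conventions the package fixes where the
field leaves them open, the numerical choices, and what the synthetic test
bed does and does not establish about real recordings.

## Sensor and kinematic model

Three IMUs (sacral `IMU1`, thoracic `IMU2`, head `IMU3`) report
sensor-to-global rotation matrices at a nominal 75 Hz; the acquisition hub
time-synchronizes them, so the package requires identical timestamps across
sensors and never resamples. The spine and the neck are each modelled as a
single joint between adjacent sensors — the standard single-segment
biomechanical model of observational ergonomics — so soft-tissue motion,
multi-segment spine curvature and sensor-mounting error are outside the
model (they appear as angle bias, not as a modelled term).

**Calibration.** A static neutral-standing window (default 5 s) defines the
zero of every joint angle. Each sensor's neutral orientation is the chordal
L2 mean of its samples (element-wise average projected to the nearest
rotation by SVD). For a tightly clustered static pose this mean is unique
and agrees with quaternion averaging to well under the sensor noise; it was
chosen for simplicity and numerical transparency. The calibration window
must lie inside one contiguous data block.

**Angles.** Relative rotations `R_spine = R1⁻¹R2`, `R_neck = R2⁻¹R3` on
calibrated streams are decomposed with the intrinsic X–Y–Z Euler sequence:
flexion about the medio-lateral axis first, then lateral bending
(antero-posterior), then axial twist (longitudinal). The sequence is a
package convention: no published convention is fixed for this platform, and
placing flexion first keeps the dominant driver of the risk score least
distorted by the sequence. Signs: forward flexion, right bend and right
twist positive; extension negative — the sign of neck flexion is load-
bearing because neck extension has its own score category. Samples with
lateral bending within 0.5° of ±90° are flagged (gimbal band) but returned;
such postures are far outside the ergonomic envelope of interest.

Both the angle decomposition and the relative rotations are invariant to a
global re-orientation of the scene (operating-room frame, bed rotation):
`(G·Rp)⁻¹(G·Rc) = Rp⁻¹Rc`. This is tested to < 1e-9°.

## Risk-index algorithm

Applied per segment to the angle time series:

1. **Smoothing** — centered moving average of `filter_len = 875` samples
   (11.67 s at 75 Hz). The length was chosen so the −3 dB point of the
   Dirichlet-kernel response, ≈ 0.443·fs/len, lands at 0.038 Hz (verified
   numerically: 0.0380 Hz). Edges and short blocks use renormalized partial
   windows (each output is a true mean of the covered samples), so DC gain
   is exactly 1 everywhere and block edges are not biased toward zero. A
   rectangular transient fully inside the window is attenuated by exactly
   `pulse_samples/filter_len`: a 3-s, 30° spike peaks at 7.71°, inside the
   ±10° twist/bend band and below the upper flexion thresholds.
2. **Windowing** — tumbling (consecutive, non-overlapping) windows of
   `window_len = 300 s`. A trailing remainder is discarded with a logged
   warning: the dwell rule below is only guaranteed well-defined on full
   windows (the pigeonhole argument fails under 4 × 60 s).
3. **Quantization** — per-sample staircase on the filtered flexion angle.
   Spine: (−∞,0]→1, (0,20]→2, (20,60]→3, (60,∞)→4. Neck: flexion < 0
   (extension) → 4; [0,10]→1, (10,20]→2, (20,∞)→3. Boundary inclusivity is
   fixed as listed (exact hits take the lower score); after smoothing,
   boundary hits are measure-zero in practice. Spine extension maps to the
   lowest score — the staircase leaves it unaddressed, and the package
   takes the explicit, conservative choice; the neck extension score is a
   config field (`neck_extension_score`) for sensitivity studies.
4. **Dwell-time selection** — the window's flexo-extension score is the
   highest level whose cumulative dwell exceeds `dwell_threshold = 60 s`
   (strictly "longer than"). With four levels in a 300-s window, some level
   always reaches ≥ 75 s, so the rule is total.
5. **Adjustments** — +1 for twist and +1 for lateral bending whenever the
   filtered angle stays outside ±`twist_bend_band = 10°` for more than the
   dwell threshold, regardless of magnitude; segment score = flexion score
   + adjustments ∈ [1, 6].
6. **Combination** — the published RULA section-B table (neck 1–6 ×
   trunk 1–6 × legs 1–2) yields the overall head-and-trunk score; legs
   defaults to 1 (supported and balanced) and is configurable. The grand
   score table (arm/wrist 1–8+ × section-B 1–7+) is provided for context;
   muscle-use and force/load additions are accepted as config integers
   (default 0) and never estimated from sensor data. Arguments above the
   printed 8/7 maxima clamp to the last row/column per the published "+"
   convention. Checksum tests pin both transcriptions.

All thresholds, the window and dwell lengths, the filter length and the
band half-width are `ScoringConfig` fields, overridable from YAML or CLI
flags.

## Synthetic test bed

`ScenarioSpec` declares piecewise-constant target angles per segment and
channel, joined by 2-s linear ramps (plateaus match the static-posture
regime that dominates the ergonomic question; ramps avoid non-physical
jumps while keeping dwell accounting simple). The forward model inverts
the kinematic chain — `IMU1` carries an arbitrary global base orientation,
`IMU2 = IMU1·R_spine`, `IMU3 = IMU2·R_neck` — composing rotations with the
same declared Euler sequence. Sensor error is an independent per-sample
axis-angle perturbation with Gaussian magnitude, default 2° RMS (the
sensors' stated dynamic accuracy); no temporal correlation or drift is
imposed, because no spectral error model is published for this platform.
Optional rectangular spikes (default 3 s, 30°) emulate brief posture
excursions. The first 5 s of every scenario are exactly neutral so
calibration is always possible; identical seeds give bitwise-identical
output.

Ground truth carries the noiseless angle series and expected window scores
computed by a deliberately naive per-sample reference scorer
(`reference.py`) — loops, scalar conditionals, integer sample counting —
kept independent of the vectorized production scorer (oracle pattern). The
naive scorer counts whole samples and divides by `fs` once, so dwell times
that land exactly on the threshold stay exact.

**Presets.** `laparoscopy_like` (sustained neck extension −15°, spine
flexion 30°, right bend 15°) and `laparotomy_like` (neck and spine flexed
forward, neck twisted 15°) use 2° RMS noise; every active channel keeps at
least 5° of margin from its nearest threshold, which is the regime where
filtering (residual noise ≈ 2/√875 ≈ 0.07° RMS) guarantees exact score
recovery. `neutral` and `spiky` are noiseless by design: a truly neutral
neck sits exactly on the extension threshold, where the sign of the
filtered angle — and hence the neck score — is decided by noise, so these
two presets are defined as deterministic regression baselines (spiky must
reproduce neutral's scores exactly to demonstrate spike absorption).

**What passing tests show — and don't.** The synthetic bed validates the
algorithmic chain: calibration, rotation algebra, decomposition, filtering
and the scoring rules, including their boundary behaviour. It does not
exercise sensor drift, magnetometer disturbance in an operating room,
skin/sensor sliding, or postures near the gimbal band; agreement on
synthetic data therefore bounds algorithmic error, not measurement error,
of a real deployment.

## Numerical choices and degenerate inputs

* Orientation validation: orthonormality defect ≤ 1e-6 accepted, ≤ 1e-2
  repaired by SVD projection (serialization rounding), beyond rejected;
  det ≤ 0 always rejected (reflection ≠ rounding).
* Moving average via prefix sums (float64); exactness of the DC gain and
  of rectangular-pulse attenuation is tested to 1e-9/1e-12.
* Gap tolerance `max_gap = 3/fs` (two missing samples): small enough that
  dwell accounting inside a block is unaffected.
* Angle series are scored only inside contiguous blocks; the CLI iterates
  blocks after the calibration window and discards blocks shorter than one
  window.
* Calibration-neutrality under noise separates two error scales: the
  calibration bias (3σ ≈ 3·rms/√375) and the filtered fluctuation
  (3σ ≈ 3·rms/√875); tests bound each separately.

## Problem sizes used in tests and the acceptance script

Scoring-chain checks use single full 300-s windows at 75 Hz (22 500
samples); end-to-end preset runs use 600-s recordings (one full window
after calibration); the vectorized-vs-naive scorer equivalence uses 1000
randomized 10-s windows (plus full-size spot checks), and decomposition
properties use 2000 random rotations. These sizes make every suite a
seconds-scale desk computation while keeping each statistical bound at 3σ
or better.

## Known limitations

Upper-limb (RULA section A) scores are not estimated — the grand-score
table is exposed but needs an externally supplied arm/wrist score. Legs
support is a constant unless overridden. No sensor-fusion, drift
correction or soft-tissue artifact modelling; the package consumes fused
orientations. Real-time acquisition and alerting are out of scope; the
tool is file-in, file-out.
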