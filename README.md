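# imugait

Bilateral gait feature and asymmetry extraction from dual foot-mounted
inertial measurement units (IMUs).

Gait asymmetry — a systematic difference between the right and left legs'
stride, step, stance and swing parameters — is a clinically useful marker in
fall-risk assessment, orthopaedic follow-up, stroke and Parkinson's
rehabilitation.  Camera-based motion capture measures it accurately but
needs a laboratory.  `imugait` extracts the same bilateral parameters from
two cheap IMUs strapped to the feet: per-leg CSV logs of 3-axis
accelerometer (g) and gyroscope (deg/s) samples at a nominal 50 Hz go in, a
24-variable bilateral gait table with right-left asymmetry comes out.

## Method

For each leg the pipeline runs:

1. **Orientation and gravity removal.**  A gradient-descent (Madgwick-type)
   IMU filter tracks the sensor→Earth quaternion *q*: gyroscope integration
   corrected toward the accelerometer's gravity observation with gain
   β = 0.1, plus an integral estimate of the gyroscope bias with gain
   ς = 0.5.  The correction runs only while the specific-force magnitude is
   near 1 g (foot on the ground), where the accelerometer actually observes
   gravity.  Rotating each sample by *q*, subtracting (0, 0, 1) g and
   scaling by 9.81 gives the movement acceleration **AM** in m/s², so the
   sensors do not need to be mounted upright.
2. **Event detection by minimal prominence.**  The per-axis movement
   acceleration is high-passed (DC removal), rectified into the magnitude
   |AT| = √(amₓ² + am_y² + am_z²), low-passed at 5 Hz and centred.  Heel
   contacts are the *prominent minima* of this envelope — the quietest
   instants of the cycle — found with a prominence threshold of 0.5 × SD of
   the envelope, which makes detection amplitude-invariant: the same
   detector works for brisk young gait and slow older gait where
   fixed-threshold peak pickers fail.  The detector self-tunes its
   DC-removal cutoff to 0.6 × the walker's stride rate (estimated by a
   first pass).  Within each stride the most prominent envelope maximum
   marks the terminal-stance push-off: stance = [Start, SS), swing =
   [SS, End).  Steps interleave the two feet's heel contacts.
3. **ZUPT double integration.**  During stance the foot is stationary, so
   velocity is pinned to zero (zero-velocity update).  Each swing's
   acceleration is integrated (trapezoidal), the residual landing velocity
   is removed as a linear drift ramp, and a second integration gives the
   stride displacement **D**; the travelled distance per stride is
   TD = √(Dₓ² + D_y² + D_z²), and the walk total is the sum over strides.
4. **Features and asymmetry.**  Twelve variables per leg (stride
   length/time/velocity, step length/time/velocity, cadence, step ratio,
   stance time, swing length/time/velocity) with mean/SD/variance/min/max,
   plus right−left differences.  Estimates are scored against a reference
   with the accuracy statistic `100·(1 − |actual − estimated|/actual) %`,
   and reference-vs-estimate tables are summarised by column means/SDs,
   mean accuracy, 95 % CI half-width (1.96·SD/√n) and Pearson r.

A seeded synthetic-gait generator (`imugait.synthetic`) produces bilateral
recordings with exact ground truth — closed-form swing pulses of known
displacement, configurable per-leg asymmetry, mounting rotation, sensor
noise and gyro bias — so the whole pipeline is testable without any
recorded data.

## Worked example

Generate a synthetic slow walk (30 strides per leg, 2.8 s and 0.69 m per
stride, 60:40 stance:swing, accelerometer noise 0.3 m/s², gyro bias
1 deg/s) and extract its gait report:

```sh
imugait synth --seed 42 --out walk
imugait extract walk/left.csv walk/right.csv --out report
```

`report/summary.json` then contains (this exact output, seed 42):

```json
{
  "left":  {"total_distance_m": 19.25, "mean_velocity_mps": 0.229, "n_strides": 30},
  "right": {"total_distance_m": 20.70, "mean_velocity_mps": 0.246, "n_strides": 30},
  "n_steps": 60,
  "walk_time_s": 85.4
}
```

Every one of the 30 strides and 60 steps is found; the true per-leg
distance is 20.70 m, so the right leg is recovered at 100.0 % accuracy and
the left at 93.0 % — inside the validated ≥ 90 % band for these conditions.
`report/features.json` holds the full 24-variable table (e.g. right-leg
cadence 21.08 steps/min here) and `report/asymmetry.json` the right−left
differences: for this symmetric walk the stride-time difference is
4 × 10⁻¹⁶ s and the stride-length difference 0.048 m, i.e. the asymmetry
report is clean at the detector's resolution.

Validation tables of (reference, estimated) pairs can be summarised
directly:

```sh
imugait validate pairs.csv        # accuracy per row, mean, 95% CI, Pearson r
```

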