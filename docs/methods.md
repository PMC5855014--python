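# Methods

This note records the models, parameter choices and known limitations of
the `imugait` pipeline, in the order the data flows.

## Sensor model and ingest

Input recordings are per-foot CSV logs: wall date/time, a millisecond
system clock, 3-axis accelerometer in g (±8 g full scale) and 3-axis
gyroscope in deg/s (±500 deg/s), nominally 50 Hz.  The millisecond clock is
the only time base used; wall time is metadata.  Internally time is float
seconds zeroed at the first retained sample, indices are 0-based, and all
windows are half-open `[start, end)`.  Real wireless links jitter and
occasionally retransmit, so ingest keeps the first of duplicate timestamps,
rejects malformed rows with their index logged, and `resample_uniform`
linearly interpolates onto an exact grid before any filtering.  Two
sensors streaming to one phone share a clock epoch, so `synchronize` trims
both recordings to the overlap of their absolute clock spans and puts them
on one grid; with no overlap it refuses rather than guessing an alignment.

## Orientation

The attitude filter is the gradient-descent IMU quaternion filter:
per sample, the quaternion rate is the gyroscope term
½ q ⊗ (0, ω − ω_b) minus β times the normalised gradient of
f(q) = (predicted sensor-frame gravity − measured accel direction).
Defaults β = 0.1 and ς = 0.5 at 50 Hz.  Three implementation decisions
matter:

* **Bias-loop gain.**  The gyroscope-bias integral is driven by the
  β-scaled angular-error term: ω_b ← ω_b + ς·β·ω_ε·dt.  ς is therefore the
  bias-convergence rate as a *fraction* of the attitude-correction rate,
  giving an effective gain ς·β = 0.05 s⁻¹.  Driving the integral with the
  unscaled error (effective gain 0.5 > β) makes the cascaded loops
  unstable — the bias estimate oscillates by tens of deg/s and the
  unobservable yaw component runs away — which is easy to demonstrate on
  the synthetic data.  With the scaled form a 1 deg/s bias is learned to
  <10 % error within 30 s while attitude stays within ~1–3° of truth
  through continuous walking.
* **Gravity-validity gate.**  The accelerometer observes gravity only when
  the specific-force magnitude stays near 1 g.  The correction and bias
  update run only where |‖a‖ − 1 g| ≤ 0.3 g over a ±2-sample window
  (`gravity_valid_mask`); elsewhere (swing) orientation coasts on the
  gyroscope.  The windowed test matters: a swinging foot's norm crosses
  1 g transiently as the acceleration vector rotates.  Passing
  `accel_gate_tol=None` restores the ungated filter.
* **Initialisation.**  The first quaternion aligns roll/pitch to the first
  accelerometer sample's gravity direction with yaw 0; yaw is unobservable
  without a magnetometer and irrelevant here because every downstream
  quantity is a magnitude or a per-stride displacement norm.

Gravity removal rotates each sample to the Earth frame, subtracts
(0, 0, 1) g and scales by 9.81 m/s² per g.

## Event detection

The stride detector works on a conditioned envelope of the movement
acceleration: per-axis zero-phase 2nd-order Butterworth high-pass →
Euclidean magnitude (the rectification step) → zero-phase low-pass at
5 Hz → mean removal.  Two conditioning details are load-bearing:

* The high-pass runs on the *signed axes*, not the magnitude.  A
  non-negative magnitude sits mostly above zero; high-passing it pushes
  the quiet stance floor below zero and rectification folds it back up,
  relocating the envelope minima from heel contacts to mean-crossings.
* The cutoff must sit below the walker's stride rate (the envelope's
  fundamental) but high enough to remove baseline wander.  A fixed cutoff
  cannot serve 1 s and 3 s strides at once: 0.5 Hz sags a 2.8 s stride
  train's pulses (creating spurious interior minima), while 0.1 Hz leaves
  fast gait's rectified pulse tails filling the contact gaps.  The
  pipeline therefore runs two passes: a 0.12 Hz pass whose minima spacing
  estimates the stride period (spacing is robust even when individual
  minima sit away from the contacts), then a final pass at 0.6 × the
  stride rate (clipped to [0.1, 1.2] Hz).  A numeric `hp_cut` disables the
  self-tuning.

Stride boundaries are the prominent local minima of the centred envelope —
the foot's quietest instants, its heel contacts — with prominence
≥ 0.5 × SD of the envelope and ≥ 0.4 s separation; flat minima resolve to
their lowest index.  SD-relative prominence is what makes detection
amplitude-invariant across gait speeds, the point of the method.  Two
plausibility rules clean up pathological minima: a gap shorter than half
the median inter-minima interval means a stride was split, and the
shallower bounding minimum is discarded; a window whose interior envelope
maximum is below 25 % of the median window maximum contains no swing burst
(quiet standing bounded by noise dips) and is excluded, as are windows
longer than `max_stride_s` (6 s, a turn-around or stop).

Within each window the single most prominent maximum of the *smoothed
envelope* marks the stance→swing transition SS (terminal-stance push-off);
the raw magnitude is too jagged for this — its sample-level excursions
compete with the push-off peak.  Stance is `[Start, SS)`, swing
`[SS, End)`, and the partition is exact by construction.

Steps: every stride Start opens a step that closes at the opposite foot's
next contact (a Start, or that foot's final End).  Final End contacts
close steps but never open one, so each leg contributes exactly one step
per stride; a same-foot Start before any contralateral contact closes the
open step flagged anomalous.  A step is attributed to the foot that swings
during it (the closing contact's foot), and its length is the displacement
that foot accumulated in the window — for foot-worn sensors that is the
full swing displacement, so left + right mean step lengths ≈ 2 × the
stride length rather than the ≈ 1 × a walkway would report; the convention
is recorded as `step_length_mode = lead_foot_swing` and affects no other
variable.

## Kinematics

Velocity is pinned to zero over every stance window (ZUPT): with a
foot-mounted sensor the stance foot is stationary, so integration restarts
from a known initial condition each stride.  Per swing: trapezoidal
integration of the movement acceleration; the residual landing velocity
divided by the window's samples gives a drift rate whose ramp is
subtracted (velocity exactly zero at both swing endpoints); a second
trapezoidal integration gives displacement.  The stride's travelled
distance is the norm of its *net* displacement vector (summing per-sample
path lengths would count vertical oscillation as distance; the
`per_sample` mode is available behind `td_mode`).  Totals are sums of
per-stride values — legitimate because drift removal decouples strides.

The DC-removal high-pass before the first integration (1st-order
Butterworth, 0.1 Hz, zero-phase) runs once over the full record: its
multi-second memory makes per-window filtering of sub-second swings
ill-posed (the filter transient dwarfs the signal).  No high-pass is
applied to the ZUPT velocity before the second integration: the
drift-corrected velocity is already zero at every stride boundary, and a
DC filter there removes the walk's genuine mean forward velocity —
shrinking every stride by mean-velocity × swing-time.

Degenerate strides (swing < 10 samples) are excluded and counted.

## Feature table

Twelve variables per leg.  Distributional variables (stride/step/stance/
swing lengths and times) carry mean, sample SD (n−1), variance, min, max
over the detected strides/steps.  Velocities are ratios of means (mean
length over mean time), matching how a per-trial summary divides totals.
Cadence is the step count over the walk time (first to last detected heel
contact) per minute, step ratio is mean step length over cadence, and
swing length equals stride length identically because stance contributes
zero displacement under ZUPT.  Asymmetry is reported as right/left means
with signed and absolute differences; no clinical cut-off is applied (the
choice of a decision threshold is a clinical question, not a signal-
processing one).  Robinson index, log-ratio and symmetry angle are
available as optional extras via `symmetry_index`.

Validation: accuracy = 100·(1 − |actual − estimated|/actual) %, and
reference-vs-estimate tables are summarised by column means/SDs, mean
accuracy, a 95 % CI half-width of 1.96·SD/√n (normal multiplier,
configurable via `ci_multiplier`) and Pearson r (undefined and reported as
such when a column is constant).

## Synthetic gait generator

The generator emulates what a metatarsal-mounted IMU sees, with every
displacement-bearing term in closed form so ground truth is exact:

* **Swing**: a forward full-period sine pulse a(s) = (2πD/Tp²) sin(2πs/Tp)
  whose double integral is exactly the stride displacement D with zero
  landing velocity; a vertical foot-lift term (cos 2πs/Ts − cos 4πs/Ts
  shape: zero at both contacts, zero net velocity and displacement, default
  peak lift 8 cm); and a sign-alternating medio-lateral filler that raises
  the magnitude to a plateau profile (full height from toe-off, smooth
  0.12 s taper into heel contact) while carrying no net motion — real swing
  |AT| stays high throughout, and without the filler the rectified envelope
  would dip spuriously mid-swing.
* **Stance**: weight-bearing vibration at 9 Hz (same phase on both axes so
  the rectified envelope is flat, with amplitude 0.3 × the swing magnitude
  scale capped at 1.5 m/s²), ending in a quarter-sine push-off build-up
  that peaks exactly at the stance→swing boundary at 1.35 × the swing
  plateau — the cycle's most prominent peak, anchoring SS detection.
  Stance carries no displacement, so the ZUPT assumption is exact.
* **Trial boundaries**: a short starting step (half displacement) lands at
  the first contact; standing before/after the walk carries shuffling
  activity scaled to the walk's vigor (0.12 × the swing scale, ≥ 4/3 of the
  stance vibration) and the record ends in a zero-mean 9 Hz activity
  crescendo.  These give the first and last heel contacts the same deep
  envelope basins as interior ones — otherwise trial-boundary noise dips
  fake or displace contacts.  The crescendo's lack of low-frequency mass
  matters: a smooth burst at the record edge rings the zero-phase filters.
* **Sensor frame**: mounting rotation applied to (motion + gravity), white
  Gaussian accelerometer noise (default 0.3 m/s² per axis), constant
  gyroscope bias (default 1 deg/s per axis) plus white gyro noise
  (0.5 deg/s).  The foot's angular excursion is *not* modelled: the
  synthetic gyroscope reads bias + noise only.  Defaults describe a slow
  older-adult walk (30 strides of 2.8 s / 0.69 m, 60:40 stance:swing,
  50 Hz); specs with per-leg tuples impose asymmetry.  Kinematics needing
  more than ±8 g are rejected as infeasible.

What passing tests on this generator do and do not show: they demonstrate
that the event logic, integration and bookkeeping are correct and robust
to noise, bias, mounting rotation and gait speed within the validated
range; they do not exercise foot rotation during swing (the hardest part
of real orientation tracking), impact transients at heel strike, surface
or footwear variation, or turning.  Real-data accuracy will be lower than
synthetic accuracy for these reasons.

## Validated operating range and limitations

* Stride detection and distance recovery are validated on synthetic walks
  for stride times 1.2–3.2 s at matching displacements (brisk 1.4 s/1.17 m
  and slow 2.8 s/0.69 m conditions: exact stride and step counts over
  20 seeds, distance accuracy ≥ 90 %, stance fraction 0.6 ± 0.05).
  Beyond ~3.5 s stride time with sub-0.7 m strides the swing signal
  approaches the sensor noise floor and detection degrades — consistent
  with slow pathological gait being the hard case for any accelerometry
  method.  Sub-second stride times at metre-scale displacements exceed the
  ±8 g sensor range and are rejected by the generator as infeasible.
* Heading is unobservable (no magnetometer); all outputs are magnitudes or
  norms by design.
* The per-stride drift model is linear in sample index; strongly curved
  intra-swing drift (rapidly changing orientation error) is not removed.
* The two-pass self-tuning assumes one dominant stride rate per recording;
  recordings mixing very different cadences should fix `hp_cut`.
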