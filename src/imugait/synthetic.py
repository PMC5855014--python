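"""Synthetic bilateral foot-IMU recordings with exact ground truth.

The generator emulates the signal structure of walking as seen by a
metatarsal-mounted IMU, with every displacement-bearing component written
in closed form so the ground truth is exact by construction:

* **stance** — the foot is on the ground: gravity plus a low-amplitude
  weight-bearing vibration (~9 Hz, medio-lateral/vertical), ending in a
  push-off build-up whose peak sits exactly at the stance→swing boundary
  (this is the most prominent acceleration-magnitude peak of the cycle,
  which is what anchors the stance/swing split).  Stance motion carries no
  displacement: the pipeline's zero-velocity assumption is exact here.
* **swing** — a forward (x) acceleration pulse, one full sine period,
  whose analytic double integral equals the specified stride displacement
  and whose velocity returns to zero at landing; a closed-form vertical
  foot-lift term (zero net velocity and displacement); and a
  sign-alternating medio-lateral filler that raises the magnitude |AT| to
  a smooth plateau — full height from toe-off, tapering only into heel
  contact — while carrying no net motion.  Real swing |AT| stays high
  throughout, so without the filler the rectified envelope would dip
  spuriously mid-swing.
* **contacts and trial boundaries** — each heel contact is flanked by a
  short quiet guard, so the deepest envelope minima fall at the contacts;
  a starting step lands at the first contact, standing before/after the
  walk carries vigor-scaled shuffling activity, and the record ends in a
  zero-mean activity crescendo, so the first and last contacts sit in
  basins as deep as interior ones and boundary noise dips never fake a
  contact.

Sensor-frame output = mounting rotation applied to (motion + gravity),
plus white accelerometer noise; the gyroscope emits a constant bias plus
white noise (the foot's angular excursion itself is not modelled — see the
methods note).  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import SpecError
from .ingest import ACCEL_RANGE_G, GRAVITY, ImuRecording

SIDES = ("right", "left")


def _per_side(value, side: str) -> float:
    """Resolve a scalar-or-(right, left) spec field for one side."""
    if isinstance(value, dict):
        return float(value[side])
    if isinstance(value, (tuple, list, np.ndarray)):
        return float(value[SIDES.index(side)])
    return float(value)


@dataclass
class SyntheticGaitSpec:
    """Study conditions for one synthetic walk.

    Scalar fields apply to both legs; a ``(right, left)`` pair or a
    ``{"right": ..., "left": ...}`` mapping imposes asymmetry.  Defaults
    describe a slow older-adult walk: 30 strides of 2.8 s and 0.69 m at a
    60:40 stance:swing split, sampled at 50 Hz.
    """

    n_strides: int = 30
    stride_time: float | tuple = 2.8  # s
    stance_fraction: float | tuple = 0.6
    stride_displacement: float | tuple = 0.69  # m
    phase_offset: float = 0.5  # right-leg shift, fraction of its stride
    mounting_rotation: tuple = (0.0, 0.0, 0.0)  # rotvec, rad; or per-side pair
    accel_noise_sd: float = 0.3  # m/s²
    gyro_noise_sd: float = 0.5  # deg/s
    gyro_bias: float | tuple = 1.0  # deg/s, applied to each axis
    fs: float = 50.0
    seed: int = 0
    # morphology (guards and amplitudes; see module docstring)
    lead_in_s: float = 2.0
    vibration_amp: float | None = None  # m/s², stance weight-bearing tremor;
    # None → 0.3 × the swing magnitude scale, capped at 1.5 (stance activity
    # shrinks with gait vigor, and must stay below the swing envelope)
    standing_amp: float | None = None  # m/s², pre/post-walk shuffling and
    # sway; None → 0.12 × the swing magnitude scale (stopping from a brisk
    # walk involves brisker adjustment steps), floored at 2.0
    vibration_freq: float = 9.0  # Hz
    pushoff_len_s: float = 0.24
    pushoff_gain: float = 1.35  # × swing magnitude peak
    foot_lift_m: float = 0.08  # peak vertical excursion of the foot in swing
    swing_start_guard_s: float = 0.06  # pulse onset after the stance→swing point
    swing_end_guard_s: float = 0.08  # pulse offset before the next contact
    first_step_fraction: float = 0.5  # starting-step displacement, × stride

    def __post_init__(self) -> None:
        for side in SIDES:
            sf = _per_side(self.stance_fraction, side)
            st = _per_side(self.stride_time, side)
            if not 0 < sf < 1:
                raise SpecError(f"stance_fraction must be in (0,1), got {sf}")
            if st <= 0 or self.fs <= 0 or self.n_strides < 1:
                raise SpecError("stride_time, fs and n_strides must be positive")
            swing = (1 - sf) * st
            if swing - self.swing_start_guard_s - self.swing_end_guard_s < 6 / self.fs:
                raise SpecError(
                    f"swing phase of {swing:.2f} s too short for the pulse guards"
                )
            if self.lead_in_s < swing + 0.3:
                raise SpecError(
                    f"lead_in_s {self.lead_in_s} too short for the starting step "
                    f"(needs at least swing {swing:.2f} s + 0.3 s)"
                )


@dataclass
class LegTruth:
    """Exact per-leg annotations implied by the generating spec."""

    side: str
    contact_times: np.ndarray  # n_strides + 1 heel contacts, s
    ss_times: np.ndarray  # stance→swing transitions, s
    stride_displacements: np.ndarray  # (n, 3), m
    stride_time: float
    stance_fraction: float

    @property
    def n_strides(self) -> int:
        return len(self.ss_times)

    @property
    def total_distance(self) -> float:
        return float(np.sum(np.linalg.norm(self.stride_displacements, axis=1)))


@dataclass
class GroundTruth:
    legs: dict = field(default_factory=dict)

    def __getitem__(self, side: str) -> LegTruth:
        return self.legs[side]


def forward_pulse(D: float, Tp: float):
    """Closed-form forward swing pulse: acceleration, velocity and position
    functions of time-into-pulse, with ``x(Tp) = D`` and ``v(0)=v(Tp)=0``.

    a(s) = A sin(2πs/Tp) with A = 2πD/Tp²;  v(s) = (D/Tp)(1 − cos(2πs/Tp));
    x(s) = D(s/Tp − sin(2πs/Tp)/2π).
    """
    A = 2.0 * np.pi * D / Tp**2
    w = 2.0 * np.pi / Tp

    def a(s):
        return A * np.sin(w * s)

    def v(s):
        return (D / Tp) * (1.0 - np.cos(w * s))

    def x(s):
        return D * (s / Tp - np.sin(w * s) / (w * Tp))

    return A, a, v, x


def quadrature_component(C: float, Ts: float):
    """Closed-form swing quadrature a(s) = C(cos(2πs/Ts) − cos(4πs/Ts)).

    Zero at both window endpoints (no discontinuity at toe-off or heel
    contact), peak magnitude 2C at mid-swing — which keeps |AT| high where
    the forward pulse crosses zero — and analytically zero net velocity and
    net displacement.  Position p(s) = C[(1−cos 2πs/Ts)/w² − (1−cos
    4πs/Ts)/4w²] ≥ 0 with w = 2π/Ts, peaking at 2C/w².
    """
    w = 2.0 * np.pi / Ts

    def a(s):
        return C * (np.cos(w * s) - np.cos(2.0 * w * s))

    def v(s):
        return (C / w) * np.sin(w * s) - (C / (2.0 * w)) * np.sin(2.0 * w * s)

    def p(s):
        return (C / w**2) * (1.0 - np.cos(w * s)) - (C / (4.0 * w**2)) * (
            1.0 - np.cos(2.0 * w * s)
        )

    return a, v, p


def _leg_motion(spec: SyntheticGaitSpec, side: str, t: np.ndarray, t0: float):
    """Earth-frame motion acceleration (n, 3) in m/s² and the leg's truth."""
    T = _per_side(spec.stride_time, side)
    sf = _per_side(spec.stance_fraction, side)
    D = _per_side(spec.stride_displacement, side)
    n = spec.n_strides
    swing = (1.0 - sf) * T
    Ts = swing - spec.swing_end_guard_s  # quadrature window
    Tp = Ts - spec.swing_start_guard_s  # forward-pulse window
    A, a_fwd, _, _ = forward_pulse(D, Tp)
    # vertical component: closed-form foot-lift trajectory
    Cz = spec.foot_lift_m * 2.0 * np.pi**2 / Ts**2
    a_quad_z, _, _ = quadrature_component(Cz, Ts)

    def swing_xy(s: np.ndarray, scale: float):
        """Forward and vertical closed-form accelerations at swing times s."""
        ax = np.zeros_like(s)
        in_pulse = (s >= spec.swing_start_guard_s) & (
            s < spec.swing_start_guard_s + Tp
        )
        ax[in_pulse] = scale * a_fwd(s[in_pulse] - spec.swing_start_guard_s)
        az = scale * a_quad_z(s)
        return ax, az

    # target swing magnitude profile: full height from toe-off (continuous
    # with the push-off peak just before SS), tapering smoothly only into
    # the heel contact; sized so it envelopes the closed-form components
    ramp = 0.12  # s

    def hump(s: np.ndarray) -> np.ndarray:
        s = np.clip(s, 0.0, Ts)
        return np.clip((Ts - s) / ramp, 0.0, 1.0) ** 0.7

    s_fine = np.linspace(0.0, Ts, 400)
    ax_f, az_f = swing_xy(s_fine, 1.0)
    M0 = 1.05 * float(np.max(np.sqrt(ax_f**2 + az_f**2)))
    P = spec.pushoff_gain * M0
    Lp = spec.pushoff_len_s

    # push-off peak and mid-swing hump never coincide; bound each
    peak_push = np.hypot(0.9 * P, 0.436 * P + GRAVITY + 1.5)
    peak_swing = np.hypot(M0, GRAVITY + 1.5)
    peak = max(peak_push, peak_swing)
    if peak > ACCEL_RANGE_G * GRAVITY:
        raise SpecError(
            f"{side} leg: displacement {D} m in a {swing:.2f} s swing needs "
            f"~{peak / GRAVITY:.1f} g, beyond the ±{ACCEL_RANGE_G:g} g range"
        )

    contacts = t0 + np.arange(n + 1) * T
    ss = contacts[:-1] + sf * T
    # the walk's very first swing: the step from standing into contact 0
    start_swing_t = t0 - swing

    am = np.zeros((t.size, 3))
    # weight-bearing vibration: on while the foot carries load (standing,
    # stance), off while it swings; a short settle after each contact keeps
    # the contact dip quiet
    vib_on = np.ones(t.size, dtype=bool)
    vib_on &= ~((t >= start_swing_t) & (t < t0))
    for k in range(n):
        vib_on &= ~((t >= ss[k]) & (t < contacts[k + 1]))
    for ck in contacts:
        vib_on &= ~((t >= ck) & (t < ck + 0.10))
    # single frequency, common phase on both axes: the rectified envelope
    # is flat (no low-frequency beat that could fake a contact dip).
    # Standing (before the first step and after coming to a stop) carries
    # more activity than quiet stance — shuffling, sway, turn preparation —
    # which keeps trial-boundary noise dips shallower than heel contacts.
    vib = spec.vibration_amp
    if vib is None:
        vib = float(min(1.5, 0.3 * M0))
    standing = spec.standing_amp
    if standing is None:
        standing = float(min(8.0, max(4.0 / 3.0 * vib, 0.12 * M0)))
    amp = np.where(
        (t < start_swing_t) | (t >= contacts[-1] + 0.10),
        standing,
        vib,
    )
    phase = 2.0 * np.pi * spec.vibration_freq * t
    am[vib_on, 2] += amp[vib_on] * np.sin(phase[vib_on])
    am[vib_on, 1] += 0.5 * amp[vib_on] * np.sin(phase[vib_on])

    def add_swing(t_start: float, scale: float) -> None:
        """One swing's motion beginning at ``t_start``: closed-form forward
        pulse and foot lift, plus a sign-alternating medio-lateral filler
        that raises the magnitude to the target hump while carrying no net
        velocity or displacement (alternate-sample cancellation)."""
        m = (t >= t_start) & (t < t_start + Ts)
        idx = np.nonzero(m)[0]
        s = t[idx] - t_start
        ax, az = swing_xy(s, scale)
        # envelope = max(plateau profile, closed-form magnitude): the
        # forward pulse's deceleration lobe is its own terminal-swing wall,
        # so the filler never has to cover the taper region
        target = np.maximum(scale * M0 * hump(s), np.sqrt(ax**2 + az**2))
        q = np.sqrt(np.maximum(target**2 - ax**2 - az**2, 0.0))
        sign = np.where(idx % 2 == 0, 1.0, -1.0)
        am[idx, 0] += ax
        am[idx, 2] += az
        am[idx, 1] += q * sign

    # starting step: a shorter swing from standing that lands at contact 0,
    # so the first contact sits in a deep envelope basin like all others
    add_swing(start_swing_t, spec.first_step_fraction)

    for k in range(n):
        # terminal-stance push-off build-up, peaking exactly at SS
        m = (t >= ss[k] - Lp) & (t < ss[k])
        u = t[m] - (ss[k] - Lp)
        am[m, 1] += P * np.sin(0.5 * np.pi * u / Lp) * 0.9
        am[m, 2] += P * np.sin(0.5 * np.pi * u / Lp) * 0.436
        add_swing(ss[k], 1.0)

    # terminating activity crescendo (stepping off / turning away) at the
    # very end of the record: it closes the lead-out so the final heel
    # contact keeps a deep prominence base while any noise dip between the
    # contact and the crescendo has only the shallow standing floor as its
    # base.  A zero-mean 9 Hz carrier with a rising envelope carries no
    # low-frequency mass, so the zero-phase conditioning filters see a
    # smoothly rising envelope with no ringing or baseline bowl; it runs
    # through the last sample so no quiet tail remains, and sits outside
    # every stride window
    burst_t = max(t[-1] - 0.8, contacts[-1] + 0.3)
    m = t >= burst_t
    u = (t[m] - burst_t) / (t[-1] - burst_t)
    carrier = np.sin(2.0 * np.pi * 9.0 * t[m])
    am[m, 1] += 0.5 * M0 * u * carrier
    am[m, 2] += 0.25 * M0 * u * carrier

    disp = np.zeros((n, 3))
    disp[:, 0] = D
    truth = LegTruth(
        side=side,
        contact_times=contacts,
        ss_times=ss,
        stride_displacements=disp,
        stride_time=T,
        stance_fraction=sf,
    )
    return am, truth


def generate_leg(
    spec: SyntheticGaitSpec,
    side: str = "right",
    phase: float | None = None,
    duration: float | None = None,
) -> tuple[ImuRecording, LegTruth]:
    """Generate one leg's recording.

    ``phase`` shifts the first contact by that fraction of the leg's stride
    time (defaults to 0 for the left leg and ``spec.phase_offset`` for the
    right).  ``duration`` fixes the total record length so a pair shares
    one time grid.
    """
    if side not in SIDES:
        raise SpecError(f"side must be one of {SIDES}, got {side!r}")
    T = _per_side(spec.stride_time, side)
    if phase is None:
        phase = spec.phase_offset if side == "right" else 0.0
    t0 = spec.lead_in_s + phase * T
    walk_end = t0 + spec.n_strides * T
    if duration is None:
        duration = walk_end + spec.lead_in_s
    elif duration < walk_end:
        raise SpecError("requested duration shorter than the walk")
    n_samp = int(round(duration * spec.fs)) + 1
    t = np.arange(n_samp) / spec.fs

    am, truth = _leg_motion(spec, side, t, t0)

    rot = Rotation.from_rotvec(
        np.asarray(
            _per_side_vec(spec.mounting_rotation, side), dtype=float
        )
    )
    f_earth_g = am / GRAVITY
    f_earth_g[:, 2] += 1.0  # specific force includes reaction to gravity
    accel_g = rot.inv().apply(f_earth_g)

    rng = np.random.default_rng([spec.seed % (2**31), SIDES.index(side)])
    accel_g += rng.normal(0.0, spec.accel_noise_sd / GRAVITY, accel_g.shape)
    bias = np.asarray(spec.gyro_bias, dtype=float)
    if bias.ndim == 0:
        bias = np.full(3, float(bias))
    gyro = bias[None, :] + rng.normal(0.0, spec.gyro_noise_sd, (n_samp, 3))

    rec = ImuRecording(
        t=t,
        accel_g=accel_g,
        gyro_dps=gyro,
        side=side,
        fs=spec.fs,
        sys_clock0_ms=0.0,
    )
    rec.validate_range()
    return rec, truth


def _per_side_vec(value, side: str):
    """Resolve a 3-vector-or-per-side-pair-of-3-vectors field."""
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 2:
        return arr[SIDES.index(side)]
    return arr


def generate_pair(
    spec: SyntheticGaitSpec,
) -> tuple[ImuRecording, ImuRecording, GroundTruth]:
    """Generate a synchronized (left, right) recording pair on one grid.

    The right leg is phase-shifted by ``phase_offset`` of its own stride so
    heel contacts interleave (0.5 → strict alternation for symmetric gait).
    """
    t_l = spec.lead_in_s + spec.n_strides * _per_side(spec.stride_time, "left")
    t_r = (
        spec.lead_in_s
        + (spec.n_strides + spec.phase_offset) * _per_side(spec.stride_time, "right")
    )
    duration = max(t_l, t_r) + spec.lead_in_s
    left, lt = generate_leg(spec, "left", duration=duration)
    right, rt = generate_leg(spec, "right", duration=duration)
    return left, right, GroundTruth(legs={"left": lt, "right": rt})
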