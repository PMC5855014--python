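"""Sensor-to-Earth orientation and gravity-free movement acceleration.

Orientation is tracked with the gradient-descent (Madgwick-style) IMU
filter: gyroscope integration corrected toward the accelerometer's gravity
observation with gain ``beta``, plus an integral-feedback estimate of the
slowly varying gyroscope bias with gain ``zeta``.  No magnetometer is used:
heading is unobservable from an IMU alone and every downstream quantity is
either a magnitude or a per-stride displacement norm, so yaw is irrelevant.

Quaternions are stored as ``[w, x, y, z]`` and represent the rotation that
takes sensor-frame vectors to the Earth frame (z up).  With the sensor at
rest in any pose the filter converges so that the rotated accelerometer
reading is ``(0, 0, 1)`` g; subtracting that and scaling by 9.81 yields the
movement acceleration ``AM`` in m/s².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import InputError
from .ingest import GRAVITY, ImuRecording

DEFAULT_BETA = 0.1
DEFAULT_ZETA = 0.5
DEFAULT_GATE_TOL = 0.3  # fraction of 1 g


@dataclass
class OrientationState:
    """Filter state: unit quaternion, bias estimate and the two gains."""

    q: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0]))
    gyro_bias: np.ndarray = field(default_factory=lambda: np.zeros(3))
    beta: float = DEFAULT_BETA
    zeta: float = DEFAULT_ZETA

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.gyro_bias = np.asarray(self.gyro_bias, dtype=float)
        if self.beta < 0 or self.zeta < 0:
            raise InputError("filter gains must be non-negative")
        self.q = self.q / np.linalg.norm(self.q)


def _quat_mult(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    pw, px, py, pz = p
    qw, qx, qy, qz = q
    return np.array(
        [
            pw * qw - px * qx - py * qy - pz * qz,
            pw * qx + px * qw + py * qz - pz * qy,
            pw * qy - px * qz + py * qw + pz * qx,
            pw * qz + px * qy - py * qx + pz * qw,
        ]
    )


def quat_to_rotation(q: np.ndarray) -> Rotation:
    """scipy Rotation from a [w, x, y, z] quaternion."""
    q = np.asarray(q, dtype=float)
    return Rotation.from_quat(np.concatenate([q[1:], q[:1]]))


def madgwick_update(
    state: OrientationState,
    accel_g: np.ndarray,
    gyro_rads: np.ndarray,
    dt: float,
    accel_gate_tol: float | None = DEFAULT_GATE_TOL,
) -> OrientationState:
    """Advance the filter one sample.

    Parameters
    ----------
    accel_g : 3-vector, sensor frame, in g.  If it is (numerically) zero
        the gradient correction and bias update are skipped for this step.
    gyro_rads : 3-vector, sensor frame, rad/s (raw, uncompensated).
    dt : sample interval in s, > 0.
    accel_gate_tol : the accelerometer only observes gravity when the
        specific-force magnitude is close to 1 g; when ``|‖a‖ − 1|``
        exceeds this fraction (foot in swing), the gradient correction and
        bias update are skipped and orientation coasts on the gyroscope.
        ``None`` disables the gate (correction runs on every sample).
    """
    if dt <= 0:
        raise InputError(f"dt must be positive, got {dt}")
    a = np.asarray(accel_g, dtype=float)
    w = np.asarray(gyro_rads, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(w))):
        raise InputError("non-finite accelerometer/gyroscope sample")
    q1, q2, q3, q4 = state.q
    bias = state.gyro_bias.copy()

    a_norm = np.linalg.norm(a)
    s = None
    if a_norm > 1e-12 and (
        accel_gate_tol is None or abs(a_norm - 1.0) <= accel_gate_tol
    ):
        ax, ay, az = a / a_norm
        # objective: predicted sensor-frame gravity minus measurement
        f1 = 2.0 * (q2 * q4 - q1 * q3) - ax
        f2 = 2.0 * (q1 * q2 + q3 * q4) - ay
        f3 = 2.0 * (0.5 - q2 * q2 - q3 * q3) - az
        grad = np.array(
            [
                -2.0 * q3 * f1 + 2.0 * q2 * f2,
                2.0 * q4 * f1 + 2.0 * q1 * f2 - 4.0 * q2 * f3,
                -2.0 * q1 * f1 + 2.0 * q4 * f2 - 4.0 * q3 * f3,
                2.0 * q2 * f1 + 2.0 * q3 * f2,
            ]
        )
        gnorm = np.linalg.norm(grad)
        if gnorm > 1e-12:
            s = grad / gnorm

    if s is not None and state.zeta > 0:
        # angular error = vector part of 2 q* ⊗ s; its integral, driven by
        # the β-scaled correction, tracks the gyroscope bias.  ζ is the
        # bias-convergence rate as a fraction of the attitude-correction
        # rate β: the effective gain ζβ must stay below β for the cascaded
        # loops to be stable.
        w_err = np.array(
            [
                2.0 * (q1 * s[1] - q2 * s[0] - q3 * s[3] + q4 * s[2]),
                2.0 * (q1 * s[2] + q2 * s[3] - q3 * s[0] - q4 * s[1]),
                2.0 * (q1 * s[3] - q2 * s[2] + q3 * s[1] - q4 * s[0]),
            ]
        )
        bias = bias + state.zeta * state.beta * w_err * dt

    w_c = w - bias
    q_dot = 0.5 * _quat_mult(state.q, np.array([0.0, *w_c]))
    if s is not None:
        q_dot = q_dot - state.beta * s
    q_new = state.q + q_dot * dt
    q_new = q_new / np.linalg.norm(q_new)
    return OrientationState(q=q_new, gyro_bias=bias, beta=state.beta, zeta=state.zeta)


def initial_quaternion(accel_g: np.ndarray) -> np.ndarray:
    """Roll/pitch-aligned initial quaternion (yaw = 0) from one
    accelerometer sample's gravity direction."""
    a = np.asarray(accel_g, dtype=float)
    n = np.linalg.norm(a)
    if n < 1e-12:
        return np.array([1.0, 0.0, 0.0, 0.0])
    rot, _ = Rotation.align_vectors([[0.0, 0.0, 1.0]], [a / n])
    x, y, z, w = rot.as_quat()
    return np.array([w, x, y, z])


def gravity_valid_mask(
    accel_g: np.ndarray,
    tol: float = DEFAULT_GATE_TOL,
    window: int = 2,
) -> np.ndarray:
    """Samples where the accelerometer is a valid gravity observation.

    True where ``|‖a‖ − 1 g|`` stays within ``tol`` over the sample and its
    ``window`` neighbours on each side.  A swinging foot's specific-force
    norm crosses 1 g only transiently as the acceleration vector rotates,
    so the windowed test rejects swing while accepting stance and standing
    (where weight-bearing tremor keeps the norm near 1 g throughout).
    """
    norms = np.linalg.norm(np.atleast_2d(accel_g), axis=1)
    near = np.abs(norms - 1.0) <= tol
    valid = near.copy()
    for k in range(1, window + 1):
        valid[k:] &= near[:-k]
        valid[:-k] &= near[k:]
    return valid


def estimate_orientation(
    rec: ImuRecording,
    beta: float = DEFAULT_BETA,
    zeta: float = DEFAULT_ZETA,
    accel_gate_tol: float | None = DEFAULT_GATE_TOL,
) -> np.ndarray:
    """Per-sample sensor→Earth quaternions for a uniform-rate recording.

    Returns an array of shape (n, 4) in [w, x, y, z] order.  The first
    quaternion is aligned to the first accelerometer sample's gravity
    direction for fast convergence.  With the gate enabled the gradient
    correction runs only where :func:`gravity_valid_mask` holds (a zero
    accelerometer vector is passed to skip the correction elsewhere, per
    the update contract), so swing-phase accelerations cannot drag the
    attitude or the bias estimate.
    """
    if len(rec) < 2:
        raise InputError("recording must have at least 2 samples")
    state = OrientationState(
        q=initial_quaternion(rec.accel_g[0]), beta=beta, zeta=zeta
    )
    if accel_gate_tol is None:
        valid = np.ones(len(rec), dtype=bool)
    else:
        valid = gravity_valid_mask(rec.accel_g, accel_gate_tol)
    zero = np.zeros(3)
    gyro = rec.gyro_rads
    dts = np.diff(rec.t)
    quats = np.empty((len(rec), 4))
    quats[0] = state.q
    for i in range(1, len(rec)):
        a = rec.accel_g[i] if valid[i] else zero
        state = madgwick_update(state, a, gyro[i], float(dts[i - 1]), None)
        quats[i] = state.q
    return quats


def remove_gravity(rec: ImuRecording, quats: np.ndarray) -> np.ndarray:
    """Movement acceleration ``AM`` in the Earth frame, m/s².

    Each accelerometer sample is rotated into the Earth frame with its
    quaternion, the unit gravity vector (0, 0, 1) g is subtracted and the
    remainder scaled by 9.81.
    """
    quats = np.asarray(quats, dtype=float)
    if len(quats) != len(rec):
        raise InputError(
            f"{len(quats)} quaternions for {len(rec)} samples"
        )
    # scipy expects [x, y, z, w]
    rot = Rotation.from_quat(np.column_stack([quats[:, 1:], quats[:, :1]]))
    a_earth = rot.apply(rec.accel_g)
    a_earth[:, 2] -= 1.0
    return a_earth * GRAVITY
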