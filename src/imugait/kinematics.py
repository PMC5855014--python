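"""Per-stride velocity, displacement and travelled distance.

Displacement is obtained by double trapezoidal integration of the Earth
frame movement acceleration, one stride at a time.  Drift is bounded by
three mechanisms working together:

* **ZUPT** — the foot is stationary throughout stance, so velocity is
  pinned to exactly zero outside swing windows;
* **per-swing linear drift removal** — the residual velocity at the end of
  each swing (which should be zero when the foot lands) is treated as
  linearly accumulated integration drift and a ramp is subtracted so the
  velocity is zero at both swing endpoints;
* **gentle high-passing** (1st-order Butterworth, 0.1 Hz by default,
  zero-phase) before each integration stage, removing the DC component the
  integrator would otherwise amplify.  Set ``hp_cut=None`` to disable the
  filters (exact trapezoidal integration, used by the oracle tests).

Because every stride starts and ends at zero velocity, stride
displacements are independent and the total travelled distance is their
sum of per-stride displacement norms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.integrate import cumulative_trapezoid

from .errors import InputError, ParameterError
from .events import StrideEvent, StrideSet


@dataclass
class KinematicsConfig:
    hp_order: int = 1
    hp_cut: float | None = 0.1  # Hz; None disables filtering entirely
    fs: float = 50.0
    td_mode: str = "net"  # net displacement per stride, or "per_sample"
    min_swing_samples: int = 10

    def __post_init__(self) -> None:
        if self.td_mode not in ("net", "per_sample"):
            raise ParameterError(f"td_mode must be net|per_sample, got {self.td_mode}")
        if self.hp_cut is not None and not 0 < self.hp_cut < self.fs / 2:
            raise ParameterError(f"hp_cut {self.hp_cut} outside (0, fs/2)")


@dataclass
class StrideKinematics:
    """Velocity and displacement series over one stride window.

    All arrays cover the half-open stride window ``[start_idx, end_idx)``;
    stance samples are zero by construction (ZUPT).
    """

    stride: StrideEvent
    t: np.ndarray
    v: np.ndarray  # (n, 3) stance-zero + raw swing velocity
    v_drift_free: np.ndarray  # (n, 3) after linear drift removal
    d: np.ndarray  # (n, 3) displacement, zero over stance
    td: float  # travelled distance of this stride, m

    @property
    def net_displacement(self) -> np.ndarray:
        return self.d[-1]

    @property
    def peak_swing_speed(self) -> float:
        return float(np.max(np.linalg.norm(self.v_drift_free, axis=1)))


@dataclass
class TrajectorySummary:
    total_distance: float
    total_time: float
    mean_velocity: float
    per_stride: np.ndarray = field(default_factory=lambda: np.empty(0))


def zupt_mask(strides: StrideSet, n_samples: int) -> np.ndarray:
    """Boolean stationarity mask: True over stance ``[Start, SS)`` and
    outside any stride, False over swing ``[SS, End)``."""
    mask = np.ones(n_samples, dtype=bool)
    for s in strides.strides:
        mask[s.mid_idx : s.end_idx] = False
    return mask


def _highpass(x: np.ndarray, cfg: KinematicsConfig) -> np.ndarray:
    """Zero-phase 1st-order high-pass; identity when disabled.

    The cutoff (0.1 Hz) implies a filter memory of seconds, so this is only
    well-posed on series much longer than that; ``compute_stride_kinematics``
    therefore filters the full record once rather than per swing window.
    """
    if cfg.hp_cut is None:
        return x
    sos = signal.butter(cfg.hp_order, cfg.hp_cut, "highpass", fs=cfg.fs, output="sos")
    padlen = min(x.shape[0] - 1, 3 * (2 * cfg.hp_order + 1))
    return signal.sosfiltfilt(sos, x, axis=0, padlen=padlen)


def integrate_swing(
    am: np.ndarray, t: np.ndarray, cfg: KinematicsConfig | None = None
) -> np.ndarray:
    """First integration: swing-window acceleration (n, 3) → velocity
    ``Vs(t)``, starting from zero.  The window is high-passed per axis
    before integrating unless filters are disabled."""
    if cfg is None:
        cfg = KinematicsConfig()
    am = np.atleast_2d(np.asarray(am, dtype=float))
    t = np.asarray(t, dtype=float)
    if am.shape[0] < 2:
        raise InputError("swing window must have at least 2 samples")
    a = _highpass(am, cfg)
    return cumulative_trapezoid(a, t, axis=0, initial=0.0)


def remove_drift(v: np.ndarray) -> np.ndarray:
    """Subtract the linear integration-drift ramp over a swing window.

    The velocity difference across the window, divided by the sample count
    and multiplied by each sample's index, is removed per axis, so the
    returned velocity is zero at both endpoints (up to the window's initial
    value, which ZUPT already pins to zero).
    """
    v = np.atleast_2d(np.asarray(v, dtype=float))
    n = v.shape[0]
    if n < 2:
        return v - v[0]
    ramp = np.linspace(0.0, 1.0, n)[:, None]
    return v - v[0] - (v[-1] - v[0]) * ramp


def stride_displacement(
    vd: np.ndarray, t: np.ndarray, cfg: KinematicsConfig | None = None
) -> np.ndarray:
    """Second integration: drift-free velocity → displacement ``D(t)``,
    high-passed per axis first unless filters are disabled."""
    if cfg is None:
        cfg = KinematicsConfig()
    vd = np.atleast_2d(np.asarray(vd, dtype=float))
    t = np.asarray(t, dtype=float)
    v = _highpass(vd, cfg)
    return cumulative_trapezoid(v, t, axis=0, initial=0.0)


def _stride_td(d: np.ndarray, cfg: KinematicsConfig) -> float:
    if cfg.td_mode == "per_sample":
        return float(np.sum(np.linalg.norm(np.diff(d, axis=0), axis=1)))
    return float(np.linalg.norm(d[-1]))


def compute_stride_kinematics(
    am: np.ndarray,
    t: np.ndarray,
    strides: StrideSet,
    cfg: KinematicsConfig | None = None,
) -> list[StrideKinematics]:
    """ZUPT + drift-corrected double integration for every stride.

    The DC-removal high-pass runs once over the full acceleration record
    (and once over the full ZUPT velocity record before the second
    integration): its ~10 s memory makes per-window filtering ill-posed on
    sub-second swings.  Strides whose swing window is shorter than
    ``min_swing_samples`` are excluded as degenerate.
    """
    if cfg is None:
        cfg = KinematicsConfig()
    am = np.asarray(am, dtype=float)
    t = np.asarray(t, dtype=float)
    am_f = _highpass(am, cfg)
    raw = KinematicsConfig(
        hp_order=cfg.hp_order,
        hp_cut=None,
        fs=cfg.fs,
        td_mode=cfg.td_mode,
        min_swing_samples=cfg.min_swing_samples,
    )
    kept: list[StrideEvent] = []
    v_full = np.zeros_like(am)
    vd_full = np.zeros_like(am)
    for s in strides.strides:
        n_swing = s.end_idx - s.mid_idx
        if n_swing < cfg.min_swing_samples:
            continue
        sw = slice(s.mid_idx, s.end_idx)
        vs = integrate_swing(am_f[sw], t[sw], raw)
        v_full[sw] = vs
        vd_full[sw] = remove_drift(vs)
        kept.append(s)
    # no high-pass before the second integration: the drift-corrected ZUPT
    # velocity is zero at every stride boundary by construction, and a DC
    # filter here would remove the walk's genuine mean forward velocity
    out: list[StrideKinematics] = []
    for s in kept:
        n = s.end_idx - s.start_idx
        n_stance = s.mid_idx - s.start_idx
        sw = slice(s.mid_idx, s.end_idx)
        d = np.zeros((n, 3))
        d[n_stance:] = stride_displacement(vd_full[sw], t[sw], raw)
        out.append(
            StrideKinematics(
                stride=s,
                t=t[s.start_idx : s.end_idx],
                v=v_full[s.start_idx : s.end_idx].copy(),
                v_drift_free=vd_full[s.start_idx : s.end_idx].copy(),
                d=d,
                td=_stride_td(d, cfg),
            )
        )
    return out


def travelled_distance(
    kin: list[StrideKinematics], total_time: float | None = None
) -> TrajectorySummary:
    """Total travelled distance: the sum over strides of the Euclidean norm
    of each stride's net displacement vector.  Mean velocity is total
    distance over total time (first stride start to last stride end when
    not given explicitly)."""
    if not kin:
        return TrajectorySummary(0.0, 0.0, 0.0)
    per = np.array([k.td for k in kin])
    total = float(per.sum())
    if total_time is None:
        total_time = kin[-1].stride.end_t - kin[0].stride.start_t
    vel = total / total_time if total_time > 0 else 0.0
    return TrajectorySummary(total, float(total_time), float(vel), per)
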