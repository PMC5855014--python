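"""Bilateral gait feature tables, asymmetry summaries and validation
statistics.

Twelve variables per leg (24 bilateral): stride length/time/velocity, step
length/time/velocity, cadence, step ratio, stance time, swing
length/time/velocity.  Distributional variables carry mean, sample SD,
variance, min and max over the detected strides/steps; velocity variables
are ratios of means (mean length over mean time), and cadence is the step
count normalised to a minute.  Because the foot is stationary in stance,
all of a stride's displacement accrues during swing, so swing length equals
stride length by construction.

Asymmetry is reported as right/left values with signed and absolute
differences; no clinical cut-off is applied.  The validation helpers
implement the relative-error accuracy statistic
``100·(1 − |actual − estimated| / actual) %`` and the summary statistics
used to compare estimates against a motion-capture reference (column
means/SDs, mean accuracy, normal-theory 95 % CI half-width, Pearson r).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import InputError, ParameterError
from .events import StepEvent, StrideSet
from .kinematics import StrideKinematics

DISTRIBUTIONAL = [
    "stride_length_m",
    "stride_time_s",
    "step_length_m",
    "step_time_s",
    "stance_time_s",
    "swing_length_m",
    "swing_time_s",
]
SCALAR = [
    "stride_velocity_mps",
    "step_velocity_mps",
    "cadence_steps_per_min",
    "step_ratio",
    "swing_velocity_mps",
]
VARIABLES = [
    "stride_length_m",
    "stride_time_s",
    "stride_velocity_mps",
    "step_length_m",
    "step_time_s",
    "step_velocity_mps",
    "cadence_steps_per_min",
    "step_ratio",
    "stance_time_s",
    "swing_length_m",
    "swing_time_s",
    "swing_velocity_mps",
]
STATS = ["mean", "std", "var", "min", "max"]


@dataclass
class GaitFeatureTable:
    """Per-leg feature table: variables × {mean, std, var, min, max}."""

    table: pd.DataFrame
    side: str
    n_strides: int
    n_steps: int
    total_time: float

    def value(self, variable: str, stat: str = "mean") -> float:
        return float(self.table.loc[variable, stat])

    def to_json_dict(self) -> dict:
        return {
            "side": self.side,
            "n_strides": self.n_strides,
            "n_steps": self.n_steps,
            "total_time_s": self.total_time,
            "variables": {
                v: {s: _none_if_nan(self.table.loc[v, s]) for s in STATS}
                for v in self.table.index
            },
        }


def _none_if_nan(x: float):
    return None if (isinstance(x, float) and math.isnan(x)) else float(x)


def _dist_stats(x: np.ndarray) -> dict:
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        return {s: float("nan") for s in STATS}
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return {
        "mean": float(np.mean(x)),
        "std": sd,
        "var": sd * sd,
        "min": float(np.min(x)),
        "max": float(np.max(x)),
    }


def _scalar_row(v: float) -> dict:
    return {"mean": float(v), "std": float("nan"), "var": float("nan"),
            "min": float("nan"), "max": float("nan")}


def step_lengths(steps: list[StepEvent], strides: StrideSet,
                 kin: list[StrideKinematics]) -> np.ndarray:
    """Length of each step: the displacement accumulated by the swinging
    foot within the step window.

    The swing that a step captures is the one ending at the step's closing
    heel contact, so the step length is that stride's travelled distance.
    A foot's very first contact closes a step during which it had not yet
    swung; that step has no length (NaN) and is excluded from the length
    statistics.
    """
    td_by_end = {round(k.stride.end_t, 9): k.td for k in kin}
    return np.array([td_by_end.get(round(s.end_t, 9), float("nan")) for s in steps])


def compute_features(
    strides: StrideSet,
    steps: list[StepEvent],
    kin: list[StrideKinematics],
    total_time: float,
    side: str | None = None,
) -> GaitFeatureTable:
    """Build one leg's feature table.

    ``steps`` must already be restricted to this leg (steps whose swinging
    foot is this side).  ``total_time`` is the walk duration used for
    cadence (first to last detected heel contact of the trial).
    """
    side = side or strides.side
    rows: dict[str, dict] = {}
    if not kin:
        table = pd.DataFrame(
            {s: {v: float("nan") for v in VARIABLES} for s in STATS}
        )[STATS]
        return GaitFeatureTable(table, side, 0, len(steps), total_time)

    own_steps = [s for s in steps if not s.anomalous]
    stride_len = np.array([k.td for k in kin])
    stride_t = np.array([k.stride.stride_time for k in kin])
    stance_t = np.array([k.stride.stance_time for k in kin])
    swing_t = np.array([k.stride.swing_time for k in kin])
    swing_len = np.array([float(np.linalg.norm(k.net_displacement)) for k in kin])
    step_t = np.array([s.step_time for s in own_steps])
    step_len = step_lengths(own_steps, strides, kin)

    rows["stride_length_m"] = _dist_stats(stride_len)
    rows["stride_time_s"] = _dist_stats(stride_t)
    rows["stance_time_s"] = _dist_stats(stance_t)
    rows["swing_time_s"] = _dist_stats(swing_t)
    rows["swing_length_m"] = _dist_stats(swing_len)
    rows["step_time_s"] = _dist_stats(step_t)
    rows["step_length_m"] = _dist_stats(step_len)

    # velocities are ratios of means, matching how the per-trial summary
    # divides total length by total duration
    rows["stride_velocity_mps"] = _scalar_row(
        rows["stride_length_m"]["mean"] / rows["stride_time_s"]["mean"]
    )
    rows["swing_velocity_mps"] = _scalar_row(
        rows["swing_length_m"]["mean"] / rows["swing_time_s"]["mean"]
    )
    if own_steps and np.isfinite(rows["step_time_s"]["mean"]):
        step_v = (
            rows["step_length_m"]["mean"] / rows["step_time_s"]["mean"]
            if np.isfinite(rows["step_length_m"]["mean"])
            else float("nan")
        )
    else:
        step_v = float("nan")
    rows["step_velocity_mps"] = _scalar_row(step_v)
    cadence = len(own_steps) / (total_time / 60.0) if total_time > 0 else float("nan")
    rows["cadence_steps_per_min"] = _scalar_row(cadence)
    step_ratio = (
        rows["step_length_m"]["mean"] / cadence
        if cadence and np.isfinite(rows["step_length_m"]["mean"])
        else float("nan")
    )
    rows["step_ratio"] = _scalar_row(step_ratio)

    table = pd.DataFrame(rows).T.loc[VARIABLES, STATS]
    return GaitFeatureTable(table, side, len(kin), len(own_steps), total_time)


@dataclass
class AsymmetrySummary:
    """Right-vs-left comparison of every variable's mean."""

    table: pd.DataFrame
    stride_count_right: int
    stride_count_left: int

    @property
    def count_mismatch(self) -> int:
        return abs(self.stride_count_right - self.stride_count_left)

    def to_json_dict(self) -> dict:
        return {
            "stride_count_right": self.stride_count_right,
            "stride_count_left": self.stride_count_left,
            "variables": {
                v: {c: _none_if_nan(self.table.loc[v, c]) for c in self.table.columns}
                for v in self.table.index
            },
        }


def asymmetry(right: GaitFeatureTable, left: GaitFeatureTable) -> AsymmetrySummary:
    """Per-variable right/left means with signed (right − left) and absolute
    differences.  Mismatched stride counts are allowed and reported."""
    if right.n_strides == 0 or left.n_strides == 0:
        raise InputError("asymmetry needs a non-empty table for each side")
    r = right.table["mean"]
    l = left.table["mean"]
    table = pd.DataFrame(
        {
            "right": r,
            "left": l,
            "difference": r - l,
            "abs_difference": (r - l).abs(),
        }
    )
    return AsymmetrySummary(table, right.n_strides, left.n_strides)


def symmetry_index(name: str, affected: float, unaffected: float) -> float:
    """Optional literature symmetry indices (not used by the core report).

    ``robinson``: 2·(u − a)/(u + a)·100;  ``log_ratio``: |100·ln(a/u)|;
    ``symmetry_angle``: (45° − arctan(a/u))·100/90.
    """
    if name == "robinson":
        return 200.0 * (unaffected - affected) / (unaffected + affected)
    if name == "log_ratio":
        return abs(100.0 * math.log(affected / unaffected))
    if name == "symmetry_angle":
        return (45.0 - math.degrees(math.atan2(affected, unaffected))) * 100.0 / 90.0
    raise ParameterError(f"unknown symmetry index {name!r}")


def accuracy(actual: float, estimated: float) -> float:
    """Relative-error accuracy in percent: 100·(1 − |actual − estimated| / actual)."""
    if actual <= 0:
        raise ParameterError(f"actual must be positive, got {actual}")
    return 100.0 * (1.0 - abs(actual - estimated) / actual)


def validation_stats(
    reference: np.ndarray,
    estimated: np.ndarray,
    ci_multiplier: float = 1.96,
) -> dict:
    """Summary statistics for reference-vs-estimated value pairs.

    Returns column means and sample SDs, per-pair accuracies with their
    mean, the 95 % CI half-width of the mean accuracy
    (``ci_multiplier × SD/√n``, normal multiplier by default) and the
    Pearson correlation between the columns (None when either column is
    constant, where the correlation is undefined).
    """
    ref = np.asarray(reference, dtype=float)
    est = np.asarray(estimated, dtype=float)
    if ref.shape != est.shape or ref.ndim != 1:
        raise InputError("reference and estimated must be equal-length 1-d arrays")
    n = ref.size
    if n < 2:
        raise InputError("need at least 2 pairs")
    acc = np.array([accuracy(a, e) for a, e in zip(ref, est)])
    sd_acc = float(np.std(acc, ddof=1))
    if np.std(ref) == 0 or np.std(est) == 0:
        r = None
    else:
        r = float(sstats.pearsonr(ref, est).statistic)
    return {
        "n": n,
        "mean_reference": float(ref.mean()),
        "sd_reference": float(np.std(ref, ddof=1)),
        "mean_estimated": float(est.mean()),
        "sd_estimated": float(np.std(est, ddof=1)),
        "accuracies": acc,
        "mean_accuracy": float(acc.mean()),
        "sd_accuracy": sd_acc,
        "ci_half_width": float(ci_multiplier * sd_acc / math.sqrt(n)),
        "pearson_r": r,
    }
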