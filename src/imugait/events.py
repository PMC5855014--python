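"""Stride, stance, swing and step detection from acceleration magnitudes.

The detector works on the per-sample Euclidean magnitude ``|AT|`` of the
Earth-frame movement acceleration.  The magnitude is conditioned (zero-phase
2nd-order Butterworth high-pass, rectification, zero-phase low-pass at 5 Hz,
mean removal) and stride boundaries are found as the prominent local
*minima* of the centered envelope: with a foot-mounted sensor the quietest
instants are the heel contacts, so the minima bound whole gait cycles.
This is amplitude-invariant (the prominence threshold is a fraction of the
signal SD), which is what lets the same detector work for fast young gait
and slow older gait where fixed-threshold peak pickers fail.

Within each stride window the single most prominent maximum of the
smoothed envelope marks the terminal-stance/pre-swing transition
(push-off); stance is ``[Start, SS)`` and swing ``[SS, End)``.  Steps interleave the two feet's
heel contacts: every stride Start opens a step that closes at the opposite
foot's next contact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import InputError, ParameterError

log = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    """Conditioning-filter parameters for event detection."""

    hp_order: int = 2
    # Hz; removes baseline/drift.  The cutoff must sit below the walker's
    # stride rate (the envelope fundamental); the pipeline self-tunes it to
    # 0.6 × the estimated stride rate, and this standalone default is a
    # conservative value below any plausible stride rate
    hp_cut: float = 0.12
    lp_cut: float = 5.0  # Hz; envelope smoothing after rectification
    fs: float = 50.0
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.hp_cut < self.lp_cut < self.fs / 2):
            raise ParameterError(
                f"need 0 < hp_cut < lp_cut < fs/2, got "
                f"{self.hp_cut}/{self.lp_cut}/{self.fs}"
            )


@dataclass
class StrideEvent:
    """One gait cycle: Start (heel contact), SS (stance→swing transition),
    End (next heel contact of the same foot)."""

    start_idx: int
    mid_idx: int
    end_idx: int
    start_t: float
    mid_t: float
    end_t: float

    def __post_init__(self) -> None:
        if not (self.start_idx < self.mid_idx < self.end_idx):
            raise InputError("stride indices must satisfy start < SS < end")

    @property
    def stride_time(self) -> float:
        return self.end_t - self.start_t

    @property
    def stance_time(self) -> float:
        return self.mid_t - self.start_t

    @property
    def swing_time(self) -> float:
        return self.end_t - self.mid_t


@dataclass
class StrideSet:
    """Detected stride boundaries for one foot."""

    minima_idx: np.ndarray
    minima_t: np.ndarray
    minima_values: np.ndarray
    strides: list[StrideEvent] = field(default_factory=list)
    side: str = "right"
    n_degenerate: int = 0
    n_long_excluded: int = 0

    @property
    def n_strides(self) -> int:
        return len(self.strides)

    @property
    def start_times(self) -> np.ndarray:
        return np.array([s.start_t for s in self.strides])

    @property
    def contact_times(self) -> np.ndarray:
        """Heel-contact instants: every stride Start plus the final End."""
        if not self.strides:
            return np.empty(0)
        return np.append(self.start_times, self.strides[-1].end_t)


@dataclass
class StepEvent:
    """One step: from a heel contact to the opposite foot's next contact.

    ``side`` is the foot that swings during (and terminates) the step;
    ``anomalous`` marks steps closed by a same-foot contact because the
    contralateral event was missed.
    """

    side: str
    start_t: float
    end_t: float
    anomalous: bool = False

    def __post_init__(self) -> None:
        if self.end_t <= self.start_t:
            raise InputError("step must have positive duration")

    @property
    def step_time(self) -> float:
        return self.end_t - self.start_t


def magnitude(vectors: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm of a (n, 3) series."""
    v = np.asarray(vectors, dtype=float)
    if not np.all(np.isfinite(v)):
        raise InputError("non-finite values in magnitude input")
    return np.linalg.norm(np.atleast_2d(v), axis=1)


def condition_signal(am: np.ndarray, cfg: FilterConfig | None = None) -> np.ndarray:
    """High-pass → rectify → low-pass → centre: the stride-detection envelope.

    ``am`` may be the (n, 3) movement acceleration or an already-rectified
    (n,) magnitude.  With 3-axis input the high-pass runs per axis on the
    signed accelerations (where it removes only drift/DC) and the
    rectification step is the Euclidean magnitude; this keeps the quiet
    stance floor at the bottom of the envelope.  High-passing an already
    non-negative magnitude instead would shift stance below zero and the
    rectification would fold it upward, relocating the envelope minima from
    the heel contacts to mean-crossings — so 3-axis input is what the
    pipeline uses, and 1-d input is supported for completeness.

    Both filters are Butterworth, applied forward–backward (zero phase) so
    detected event times are not delayed.  The output has zero mean.
    """
    if cfg is None:
        cfg = FilterConfig()
    x = np.asarray(am, dtype=float)
    min_len = 3 * (2 * cfg.hp_order + 1)
    if x.shape[0] <= min_len:
        raise InputError(f"series of {x.shape[0]} samples too short to filter")
    sos_hp = signal.butter(cfg.hp_order, cfg.hp_cut, "highpass", fs=cfg.fs, output="sos")
    sos_lp = signal.butter(cfg.hp_order, cfg.lp_cut, "lowpass", fs=cfg.fs, output="sos")
    filt = signal.sosfiltfilt if cfg.zero_phase else signal.sosfilt
    if x.ndim == 2:
        y = filt(sos_hp, x, axis=0)
        y = np.linalg.norm(y, axis=1)
    else:
        y = np.abs(filt(sos_hp, x))
    y = filt(sos_lp, y)
    return y - np.mean(y)


def detect_strides(
    cen: np.ndarray,
    t: np.ndarray,
    min_prominence_sd: float = 0.5,
    min_separation_s: float = 0.4,
    fs: float = 50.0,
    merge_short_fraction: float = 0.5,
) -> StrideSet:
    """Find stride-boundary minima of the centered envelope.

    Minima are the prominent peaks of the negated series, with prominence at
    least ``min_prominence_sd`` times the SD of the centered series and
    pairwise separation at least ``min_separation_s``.  Flat minima resolve
    to their lowest index.  An empty result is returned (not an error) when
    no minima qualify.

    A spurious minimum inside a gait cycle splits one stride into a long
    and a short fragment, so gaps shorter than ``merge_short_fraction``
    times the median inter-minima interval are re-merged by discarding the
    shallower of the two bounding minima (0 disables the merge).
    """
    cen = np.asarray(cen, dtype=float)
    t = np.asarray(t, dtype=float)
    sd = float(np.std(cen))
    if sd <= 0 or cen.size < 3:
        return StrideSet(np.empty(0, int), np.empty(0), np.empty(0))
    distance = max(1, int(round(min_separation_s * fs)))
    idx, props = signal.find_peaks(
        -cen,
        prominence=min_prominence_sd * sd,
        distance=distance,
        plateau_size=(None, None),
    )
    # flat-peak rule: report the lowest index of a plateau
    idx = props["left_edges"].astype(int)

    if merge_short_fraction > 0 and idx.size >= 4:
        keep = list(idx)
        while len(keep) >= 4:
            gaps = np.diff(t[keep])
            floor = merge_short_fraction * float(np.median(gaps))
            k = int(np.argmin(gaps))
            if gaps[k] >= floor:
                break
            a, b = keep[k], keep[k + 1]
            drop = a if cen[a] > cen[b] else b  # shallower minimum goes
            log.warning(
                "merging %.2f s stride fragment at t=%.2f s "
                "(spurious envelope minimum)",
                gaps[k],
                t[drop],
            )
            keep.remove(drop)
        idx = np.asarray(keep, dtype=int)

    return StrideSet(
        minima_idx=idx,
        minima_t=t[idx],
        minima_values=cen[idx],
    )


def split_stance_swing(
    at: np.ndarray,
    strideset: StrideSet,
    t: np.ndarray,
    max_stride_s: float = 6.0,
    min_activity_fraction: float = 0.25,
) -> StrideSet:
    """Populate Start/SS/End for each pair of consecutive minima.

    ``SS`` is the most prominent interior maximum of the windowed series
    (the smoothed magnitude envelope in the pipeline); ties resolve to the
    lower index.  Windows with no interior maximum are counted degenerate
    and excluded; windows longer than ``max_stride_s`` are treated as a
    turn-around/stop and excluded (the sequence is broken there instead of
    emitting a spurious stride); windows whose interior maximum falls below
    ``min_activity_fraction`` of the median window maximum contain no swing
    burst (quiet standing bounded by noise dips) and are excluded likewise.
    """
    at = np.asarray(at, dtype=float)
    t = np.asarray(t, dtype=float)
    mins = strideset.minima_idx
    if len(mins) < 2:
        return strideset
    candidates: list[tuple[int, int, int, float]] = []
    n_degenerate = 0
    n_long = 0
    for a, b in zip(mins[:-1], mins[1:]):
        if t[b] - t[a] > max_stride_s:
            n_long += 1
            continue
        window = at[a + 1 : b]
        if window.size < 1:
            n_degenerate += 1
            continue
        pk, props = signal.find_peaks(window, plateau_size=(None, None))
        if pk.size == 0:
            n_degenerate += 1
            log.warning(
                "stride window [%d, %d) has no interior maximum; excluded", a, b
            )
            continue
        prominences = signal.peak_prominences(window, pk)[0]
        best = props["left_edges"][int(np.argmax(prominences))]
        candidates.append((int(a), int(a + 1 + best), int(b), float(window.max())))

    strides: list[StrideEvent] = []
    if candidates:
        # window maxima are measured from the window's own floor so the
        # activity test is offset-invariant (the envelope is centered)
        floor = min(float(np.min(at[a:b + 1])) for a, _, b in
                    [(c[0], c[1], c[2]) for c in candidates])
        heights = np.array([c[3] for c in candidates]) - floor
        cutoff = min_activity_fraction * float(np.median(heights))
        for (a, mid, b, peak), h in zip(candidates, heights):
            if len(candidates) >= 3 and h < cutoff:
                n_degenerate += 1
                log.warning(
                    "window [%.2f, %.2f) s has no swing-scale activity; "
                    "treated as standing, not a stride",
                    t[a],
                    t[b],
                )
                continue
            strides.append(
                StrideEvent(a, mid, b, float(t[a]), float(t[mid]), float(t[b]))
            )
    return StrideSet(
        minima_idx=strideset.minima_idx,
        minima_t=strideset.minima_t,
        minima_values=strideset.minima_values,
        strides=strides,
        side=strideset.side,
        n_degenerate=n_degenerate,
        n_long_excluded=n_long,
    )


def detect_steps(left: StrideSet, right: StrideSet) -> list[StepEvent]:
    """Interleave the two feet's heel contacts into step events.

    Every stride Start opens a step; it closes at the opposite foot's next
    contact (a Start or that foot's final End).  Final End contacts close
    steps but never open one, so each leg contributes exactly one step per
    stride.  A same-foot Start arriving before any contralateral contact
    closes the open step as anomalous (missed contralateral event).
    """
    events = []  # (time, foot, opens)
    for ss in (left, right):
        for k, s in enumerate(ss.strides):
            events.append((s.start_t, ss.side, True))
        if ss.strides:
            events.append((ss.strides[-1].end_t, ss.side, False))
    if not left.strides or not right.strides:
        return []
    events.sort(key=lambda e: e[0])

    steps: list[StepEvent] = []
    open_t: float | None = None
    open_side: str | None = None
    for t_ev, foot, opens in events:
        if open_t is not None and t_ev > open_t:
            if foot != open_side:
                steps.append(StepEvent(side=foot, start_t=open_t, end_t=t_ev))
                open_t = None
            elif opens:
                log.warning(
                    "missed contralateral contact before t=%.3f s; "
                    "closing step as anomalous",
                    t_ev,
                )
                steps.append(
                    StepEvent(side=foot, start_t=open_t, end_t=t_ev, anomalous=True)
                )
                open_t = None
        if opens:
            open_t, open_side = t_ev, foot
    return steps
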