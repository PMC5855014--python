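"""Reading, writing, resampling and synchronizing dual foot-mounted IMU logs.

The on-disk dialect is the logging app's CSV: one row per sample with
``date (dd/mm/yyyy), time (HH:MM:SS.ss), system clock (ms), ax, ay, az, gx,
gy, gz`` where acceleration is in g (sensor range ±8 g) and angular rate in
deg/s (±500 deg/s).  The millisecond system clock is the authoritative time
base; wall date/time are carried as metadata only.  Internally time is float
seconds, zeroed at the first retained sample, and all windows are half-open
``[start, end)`` with 0-based indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    InputError,
    IntegrityError,
    ParameterError,
    SynchronizationError,
)

log = logging.getLogger(__name__)

GRAVITY = 9.81  # m/s² per g, the conversion constant used throughout
ACCEL_RANGE_G = 8.0  # sensor full scale, g
GYRO_RANGE_DPS = 500.0  # sensor full scale, deg/s

_COLUMNS = ["date", "time", "sys_clock_ms", "ax", "ay", "az", "gx", "gy", "gz"]


@dataclass
class ImuRecording:
    """A single foot's IMU stream.

    Attributes
    ----------
    t : ndarray, shape (n,)
        Time in seconds, zeroed at the first sample, derived from the
        millisecond system clock.
    accel_g : ndarray, shape (n, 3)
        Accelerometer samples in g (sensor frame).
    gyro_dps : ndarray, shape (n, 3)
        Gyroscope samples in deg/s (sensor frame).
    side : str
        Leg label, ``"left"`` or ``"right"``.
    fs : float
        Nominal sampling rate in Hz.
    wall_date, wall_time : str
        Wall-clock metadata of the first sample (not used for timing).
    """

    t: np.ndarray
    accel_g: np.ndarray
    gyro_dps: np.ndarray
    side: str = "right"
    fs: float = 50.0
    wall_date: str = "01/01/2000"
    wall_time: str = "00:00:00.00"
    sys_clock0_ms: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.accel_g = np.atleast_2d(np.asarray(self.accel_g, dtype=float))
        self.gyro_dps = np.atleast_2d(np.asarray(self.gyro_dps, dtype=float))
        n = len(self.t)
        if self.accel_g.shape != (n, 3) or self.gyro_dps.shape != (n, 3):
            raise InputError(
                f"channel shapes {self.accel_g.shape}/{self.gyro_dps.shape} "
                f"inconsistent with {n} timestamps"
            )
        if n >= 2 and np.any(np.diff(self.t) <= 0):
            raise IntegrityError("timestamps are not strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def gyro_rads(self) -> np.ndarray:
        """Angular rate converted to rad/s for the orientation filter."""
        return np.deg2rad(self.gyro_dps)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) else 0.0

    def validate_range(self) -> None:
        """Enforce the sensor's physical full-scale ranges."""
        if np.any(np.abs(self.accel_g) > ACCEL_RANGE_G):
            raise IntegrityError(f"accelerometer sample outside ±{ACCEL_RANGE_G} g")
        if np.any(np.abs(self.gyro_dps) > GYRO_RANGE_DPS):
            raise IntegrityError(f"gyroscope sample outside ±{GYRO_RANGE_DPS} deg/s")


def read_app_csv(path, side: str = "right", fs: float = 50.0) -> ImuRecording:
    """Read one foot's recording from the app's CSV dialect.

    A single header line is auto-detected.  Rows that do not parse into
    9 fields of the expected types are rejected with their row index
    logged.  Samples are ordered by the system clock; duplicate clock
    values keep the first occurrence.

    Raises
    ------
    FormatError
        If the file has fewer than 9 columns or no parseable rows.
    IntegrityError
        If the system clock is non-monotonic after sorting (i.e. ties
        beyond duplicates) or fewer than 1 sample remains.
    """
    try:
        raw = pd.read_csv(path, header=None, dtype=str, skip_blank_lines=True)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if raw.shape[1] < 9:
        raise FormatError(
            f"{path}: expected 9 columns (date,time,clock,3 accel,3 gyro), "
            f"got {raw.shape[1]}"
        )
    raw = raw.iloc[:, :9]
    raw.columns = _COLUMNS

    numeric = raw[_COLUMNS[2:]].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    # a leading all-NaN row is a header, not data corruption
    header_rows = bad & (np.arange(len(raw)) == 0)
    malformed = bad & ~header_rows
    for idx in raw.index[malformed]:
        log.warning("%s: rejecting malformed row %d", path, idx)
    keep = ~bad
    if not keep.any():
        raise FormatError(f"{path}: no parseable data rows")
    data = numeric[keep]
    dates = raw.loc[keep, "date"].to_numpy()
    times = raw.loc[keep, "time"].to_numpy()

    order = np.argsort(data["sys_clock_ms"].to_numpy(), kind="stable")
    if not np.array_equal(order, np.arange(len(order))):
        raise IntegrityError(f"{path}: system clock not monotonic")
    clock = data["sys_clock_ms"].to_numpy()
    uniq = np.concatenate([[True], np.diff(clock) > 0])
    n_dup = int((~uniq).sum())
    if n_dup:
        log.warning("%s: dropping %d duplicate-timestamp rows", path, n_dup)
    data = data[uniq]
    clock = clock[uniq]

    return ImuRecording(
        t=(clock - clock[0]) / 1000.0,
        accel_g=data[["ax", "ay", "az"]].to_numpy(),
        gyro_dps=data[["gx", "gy", "gz"]].to_numpy(),
        side=side,
        fs=fs,
        wall_date=str(dates[uniq][0]),
        wall_time=str(times[uniq][0]),
        sys_clock0_ms=float(clock[0]),
    )


def write_app_csv(rec: ImuRecording, path, header: bool = False):
    """Write a recording in the app's CSV dialect (round-trips with
    :func:`read_app_csv`).  Returns ``path``."""
    clock = np.round(rec.sys_clock0_ms + rec.t * 1000.0).astype(np.int64)
    df = pd.DataFrame(
        {
            "date": rec.wall_date,
            "time": rec.wall_time,
            "sys_clock_ms": clock,
            "ax": rec.accel_g[:, 0] if len(rec) else [],
            "ay": rec.accel_g[:, 1] if len(rec) else [],
            "az": rec.accel_g[:, 2] if len(rec) else [],
            "gx": rec.gyro_dps[:, 0] if len(rec) else [],
            "gy": rec.gyro_dps[:, 1] if len(rec) else [],
            "gz": rec.gyro_dps[:, 2] if len(rec) else [],
        }
        if len(rec)
        else {c: [] for c in _COLUMNS}
    )
    df.to_csv(path, index=False, header=header, float_format="%.6f")
    return path


def resample_uniform(rec: ImuRecording, fs: float | None = None) -> ImuRecording:
    """Linearly interpolate all channels onto an exact uniform grid at ``fs``.

    Real BLE timestamps jitter; downstream filtering and integration assume
    a uniform rate.  Endpoints are clamped to the original span.
    """
    if fs is None:
        fs = rec.fs
    if fs <= 0:
        raise ParameterError(f"fs must be positive, got {fs}")
    if len(rec) < 2 or rec.duration < 2.0 / fs:
        raise InputError("recording too short to resample")
    n_out = int(np.floor(rec.duration * fs)) + 1
    t_new = rec.t[0] + np.arange(n_out) / fs
    t_new = np.minimum(t_new, rec.t[-1])

    def interp(block: np.ndarray) -> np.ndarray:
        return np.column_stack(
            [np.interp(t_new, rec.t, block[:, j]) for j in range(3)]
        )

    return replace(
        rec,
        t=t_new - t_new[0],
        accel_g=interp(rec.accel_g),
        gyro_dps=interp(rec.gyro_dps),
        fs=float(fs),
    )


def synchronize(
    left: ImuRecording, right: ImuRecording, fs: float | None = None
) -> tuple[ImuRecording, ImuRecording]:
    """Trim both recordings to their common system-clock window and put them
    on identical uniform grids.

    The two sensors stream to one phone, so their millisecond system clocks
    share an epoch; the overlap of the absolute clock spans defines the
    usable window.
    """
    if fs is None:
        fs = left.fs
    la, lb = left.sys_clock0_ms, left.sys_clock0_ms + left.duration * 1000.0
    ra, rb = right.sys_clock0_ms, right.sys_clock0_ms + right.duration * 1000.0
    t0, t1 = max(la, ra), min(lb, rb)
    if t1 - t0 < 2000.0 / fs:
        raise SynchronizationError(
            f"recordings do not overlap (left [{la:.0f},{lb:.0f}] ms, "
            f"right [{ra:.0f},{rb:.0f}] ms)"
        )

    def trim(rec: ImuRecording) -> ImuRecording:
        abs_t = rec.sys_clock0_ms + rec.t * 1000.0
        n_out = int(np.floor((t1 - t0) / 1000.0 * fs)) + 1
        grid = t0 + np.arange(n_out) * 1000.0 / fs
        grid = np.minimum(grid, t1)
        acc = np.column_stack(
            [np.interp(grid, abs_t, rec.accel_g[:, j]) for j in range(3)]
        )
        gyr = np.column_stack(
            [np.interp(grid, abs_t, rec.gyro_dps[:, j]) for j in range(3)]
        )
        return replace(
            rec,
            t=(grid - t0) / 1000.0,
            accel_g=acc,
            gyro_dps=gyr,
            fs=float(fs),
            sys_clock0_ms=float(t0),
        )

    return trim(left), trim(right)
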