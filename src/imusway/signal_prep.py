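"""Recording I/O, zero-phase low-pass filtering and anatomical sway signals.

A recording holds raw tri-axial accelerometer (m/s^2) and gyroscope (deg/s)
series in sensor axes.  Downstream feature extraction consumes
:class:`SwaySignals`: filtered, demeaned acceleration mapped onto the
medio-lateral (ML), vertical (V) and antero-posterior (AP) anatomical axes
(sensor x -> ML, y -> V, z -> AP), filtered angular velocity on the same
axes, and the signal-vector-magnitude series

    svm(n) = sqrt(ml(n)^2 + v(n)^2 + ap(n)^2)

computed from the demeaned filtered components so that it measures sway
rather than gravity.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ConfigurationError, ParseError

__all__ = [
    "IMURecording",
    "SwaySignals",
    "read_recording",
    "write_recording",
    "lowpass_zero_phase",
    "to_sway_signals",
]

SESSIONS = ("EO", "EC", "RL", "LL")

RECORDING_COLUMNS = ["time_s", "acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z"]

_FILENAME_RE = re.compile(r"^(?P<sid>.+)_(?P<session>EO|EC|RL|LL)_(?P<trial>\d+)$")


@dataclass
class IMURecording:
    """One trial's synchronized accelerometer + gyroscope time series.

    ``acc`` and ``gyr`` are (3, N) arrays in sensor axes (x, y, z), in
    m/s^2 and deg/s respectively.
    """

    subject_id: str
    session: str
    trial: int
    fs: float
    acc: np.ndarray
    gyr: np.ndarray

    def __post_init__(self) -> None:
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyr = np.asarray(self.gyr, dtype=float)
        if self.acc.shape[0] != 3 or self.gyr.shape[0] != 3:
            raise ConfigurationError("acc and gyr must each have 3 channels")
        if self.acc.shape[1] != self.gyr.shape[1]:
            raise ConfigurationError(
                "acc and gyr channel lengths differ: "
                f"{self.acc.shape[1]} vs {self.gyr.shape[1]}"
            )
        if self.acc.shape[1] < 2:
            raise ConfigurationError("recording needs at least 2 samples")
        if not self.fs > 0:
            raise ConfigurationError(f"fs must be positive, got {self.fs}")
        if not (np.isfinite(self.acc).all() and np.isfinite(self.gyr).all()):
            raise ConfigurationError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.acc.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class SwaySignals:
    """Filtered, demeaned sway components on anatomical axes plus SVM."""

    ml: np.ndarray
    v: np.ndarray
    ap: np.ndarray
    gml: np.ndarray
    gv: np.ndarray
    gap: np.ndarray
    svm: np.ndarray
    fs: float
    subject_id: str = ""
    session: str = ""
    trial: int = 0
    gsvm: np.ndarray = field(default=None, repr=False)  # gyro magnitude

    def __post_init__(self) -> None:
        if self.gsvm is None:
            self.gsvm = np.sqrt(self.gml**2 + self.gv**2 + self.gap**2)

    @property
    def n_samples(self) -> int:
        return self.ml.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def recording_filename(rec: IMURecording) -> str:
    return f"{rec.subject_id}_{rec.session}_{rec.trial}.csv"


def read_recording(path: str, fs: float | None = None) -> IMURecording:
    """Read one trial CSV (columns ``time_s,acc_x..gyr_z``).

    Subject/session/trial metadata is recovered from a
    ``<subjectID>_<session>_<trial>.csv`` filename when it matches; the
    sampling rate is inferred from the time column unless given.
    """
    try:
        df = pd.read_csv(path)
    except (ValueError, OSError) as exc:
        raise ParseError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    df = df[RECORDING_COLUMNS]
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        # +2: 1-based on-disk numbering including the header line
        raise ParseError(f"{path}: non-numeric or missing value at row {row + 2}")
    t = numeric["time_s"].to_numpy()
    if fs is None:
        if len(t) < 2:
            raise ParseError(f"{path}: need at least 2 rows to infer fs")
        dt = np.median(np.diff(t))
        if dt <= 0:
            raise ParseError(f"{path}: non-increasing time column")
        fs = 1.0 / dt

    stem = os.path.splitext(os.path.basename(path))[0]
    m = _FILENAME_RE.match(stem)
    subject_id = m.group("sid") if m else stem
    session = m.group("session") if m else ""
    trial = int(m.group("trial")) if m else 0

    acc = numeric[["acc_x", "acc_y", "acc_z"]].to_numpy().T
    gyr = numeric[["gyr_x", "gyr_y", "gyr_z"]].to_numpy().T
    return IMURecording(subject_id, session, trial, float(fs), acc, gyr)


def write_recording(rec: IMURecording, path: str) -> None:
    """Write one trial CSV; round-trips through :func:`read_recording`."""
    t = np.arange(rec.n_samples) / rec.fs
    df = pd.DataFrame(
        {
            "time_s": t,
            "acc_x": rec.acc[0],
            "acc_y": rec.acc[1],
            "acc_z": rec.acc[2],
            "gyr_x": rec.gyr[0],
            "gyr_y": rec.gyr[1],
            "gyr_z": rec.gyr[2],
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def lowpass_zero_phase(
    series: np.ndarray, fs: float, order: int = 8, fc_hz: float = 5.0
) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter of the stated overall order.

    Realized as forward-backward (filtfilt) application of an order/2
    Butterworth, whose squared magnitude response matches the stated order;
    DC gain is exactly 1 and phase lag is zero.  Edges are handled by
    reflective padding of 3x the overall order.
    """
    series = np.asarray(series, dtype=float)
    if order < 2 or order % 2:
        raise ConfigurationError(f"order must be an even integer >= 2, got {order}")
    if not 0 < fc_hz < fs / 2:
        raise ConfigurationError(
            f"fc_hz must lie in (0, fs/2) = (0, {fs / 2:g}), got {fc_hz}"
        )
    if series.shape[-1] <= 3 * order:
        raise ConfigurationError(
            f"series too short for stable filtering: need > {3 * order} samples"
        )
    b, a = sps.butter(order // 2, fc_hz, btype="low", fs=fs)
    return sps.filtfilt(b, a, series, padtype="even", padlen=3 * order)


def to_sway_signals(
    rec: IMURecording,
    order: int = 8,
    fc_hz: float = 5.0,
    demean_gyro: bool = False,
) -> SwaySignals:
    """Filter, map sensor axes to anatomical axes and demean accelerations.

    All six channels are low-pass filtered; sensor x/y/z become ML/V/AP;
    the three acceleration channels then have their per-channel mean
    removed (gravity/offset removal) and svm is computed from the demeaned
    components.  Gyroscope channels are filtered but, by default, not
    demeaned (angular velocity carries no gravity offset).
    """
    acc = np.stack(
        [lowpass_zero_phase(c, rec.fs, order, fc_hz) for c in rec.acc]
    )
    gyr = np.stack(
        [lowpass_zero_phase(c, rec.fs, order, fc_hz) for c in rec.gyr]
    )
    acc = acc - acc.mean(axis=1, keepdims=True)
    if demean_gyro:
        gyr = gyr - gyr.mean(axis=1, keepdims=True)
    ml, v, ap = acc
    svm = np.sqrt(ml**2 + v**2 + ap**2)
    return SwaySignals(
        ml=ml,
        v=v,
        ap=ap,
        gml=gyr[0],
        gv=gyr[1],
        gap=gyr[2],
        svm=svm,
        fs=rec.fs,
        subject_id=rec.subject_id,
        session=rec.session,
        trial=rec.trial,
    )
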