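"""Reading, resampling and buffering of raw inertial recordings.

Wearable devices log triaxial acceleration and angular velocity at
irregular intervals because their operating systems multitask; every
downstream stage expects an equally spaced series.  This module holds the
raw-recording container, a validating text loader, cubic-spline resampling
to a uniform rate (50 Hz by default), the acceleration-magnitude series,
and fixed-span buffering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

logger = logging.getLogger(__name__)

#: Canonical column order of the delimited-text recording schema.
COLUMNS = ("t", "ax", "ay", "az", "qx", "qy", "qz")

#: Default uniform resampling rate in Hz.
DEFAULT_RATE = 50.0

#: Minimum buffer span in seconds fed to segmentation.
MIN_BUFFER_SPAN = 4.0


class ParseError(ValueError):
    """Raised when a recording file violates the text schema."""


@dataclass
class ImuRecording:
    """Timestamped triaxial accelerometer + gyroscope samples.

    Parameters
    ----------
    timestamps
        Sample times in seconds, strictly increasing, shape ``(n,)``.
    accel
        Acceleration vectors in m/s^2, shape ``(n, 3)``.
    gyro
        Angular-velocity vectors in rad/s, shape ``(n, 3)``.
    """

    timestamps: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        n = self.timestamps.shape[0]
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValueError(
                "timestamps, accel and gyro must have matching lengths; got "
                f"{n}, {self.accel.shape}, {self.gyro.shape}"
            )
        if n >= 2:
            bad = np.nonzero(np.diff(self.timestamps) <= 0)[0]
            if bad.size:
                raise ValueError(
                    f"timestamps must be strictly increasing; first violation "
                    f"at sample {bad[0] + 1} (t={self.timestamps[bad[0] + 1]!r})"
                )

    def __len__(self) -> int:
        return self.timestamps.shape[0]

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass
class UniformSeries:
    """Uniformly resampled buffer of acceleration, angular velocity and |a|.

    ``a`` and ``q`` hold the resampled triaxial series, ``aM`` the Euclidean
    magnitude of ``a`` computed after resampling.  ``l = n / rate`` is the
    buffer span in seconds.
    """

    rate: float
    t0: float
    a: np.ndarray
    q: np.ndarray
    aM: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.aM is None:
            self.aM = magnitude(self.a)
        self.aM = np.asarray(self.aM, dtype=float)
        if not (len(self.a) == len(self.q) == len(self.aM)):
            raise ValueError("a, q and aM must have equal lengths")

    @property
    def n(self) -> int:
        return self.a.shape[0]

    def __len__(self) -> int:
        return self.n

    @property
    def l(self) -> float:
        """Buffer span in seconds."""
        return self.n / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.rate


def magnitude(a: np.ndarray) -> np.ndarray:
    """Elementwise Euclidean norm of a sequence of 3-vectors.

    The magnitude series is the single channel used for gait segmentation:
    rotating the device rotates ``a`` but leaves ``|a|`` unchanged, which is
    what makes segmentation insensitive to how the sensor was pocketed.
    """
    a = np.asarray(a, dtype=float)
    return np.linalg.norm(a, axis=-1)


def load_recording(path, column_map: dict | None = None) -> ImuRecording:
    """Load a delimited-text recording (columns ``t,ax,ay,az,qx,qy,qz``).

    Parameters
    ----------
    path
        File with a header line, comma separator and ``.`` decimal.
    column_map
        Optional mapping from the canonical names to the file's column
        names, for foreign layouts (e.g. ``{"t": "timestamp"}``).

    Raises
    ------
    ParseError
        On missing columns, non-numeric rows or non-increasing timestamps,
        naming the offending line (1-based, header = line 1).
    """
    try:
        frame = pd.read_csv(path, sep=",")
    except Exception as exc:  # malformed CSV structure
        raise ParseError(f"{path}: cannot parse delimited text: {exc}") from exc

    mapping = {name: name for name in COLUMNS}
    if column_map:
        mapping.update(column_map)
    missing = [mapping[c] for c in COLUMNS if mapping[c] not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing} (line 1)")

    data = {}
    for canon in COLUMNS:
        col = pd.to_numeric(frame[mapping[canon]], errors="coerce")
        bad = np.nonzero(~np.isfinite(col.to_numpy(dtype=float)))[0]
        if bad.size:
            raise ParseError(
                f"{path}: non-numeric value in column {mapping[canon]!r} "
                f"at line {bad[0] + 2}"
            )
        data[canon] = col.to_numpy(dtype=float)

    t = data["t"]
    if t.size >= 2:
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            raise ParseError(
                f"{path}: timestamps not strictly increasing at line {bad[0] + 3}"
            )
    accel = np.column_stack([data["ax"], data["ay"], data["az"]])
    gyro = np.column_stack([data["qx"], data["qy"], data["qz"]])
    return ImuRecording(t, accel, gyro)


def save_recording(path, recording: ImuRecording) -> None:
    """Write a recording in the canonical delimited-text schema."""
    frame = pd.DataFrame(
        {
            "t": recording.timestamps,
            "ax": recording.accel[:, 0],
            "ay": recording.accel[:, 1],
            "az": recording.accel[:, 2],
            "qx": recording.gyro[:, 0],
            "qy": recording.gyro[:, 1],
            "qz": recording.gyro[:, 2],
        }
    )
    frame.to_csv(path, index=False)


def resample(recording: ImuRecording, rate: float = DEFAULT_RATE) -> UniformSeries:
    """Resample all six channels onto a uniform grid by cubic spline.

    The grid is anchored at the first timestamp (no extrapolation) and each
    channel is splined independently with the not-a-knot boundary condition,
    so channel values lying on a cubic polynomial are reproduced exactly.
    The magnitude series is computed after resampling.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if len(recording) < 4:
        raise ValueError(
            f"cubic-spline resampling needs at least 4 samples, got {len(recording)}"
        )
    t = recording.timestamps
    n_out = int(np.floor((t[-1] - t[0]) * rate)) + 1
    grid = t[0] + np.arange(n_out) / rate
    channels = np.hstack([recording.accel, recording.gyro])  # (n, 6)
    spline = CubicSpline(t, channels, axis=0, bc_type="not-a-knot")
    out = spline(grid)
    return UniformSeries(rate=rate, t0=float(t[0]), a=out[:, :3], q=out[:, 3:])


def buffer_windows(
    series: UniformSeries,
    span: float = MIN_BUFFER_SPAN,
    hop: float | None = None,
    min_span: float = MIN_BUFFER_SPAN,
) -> list[UniformSeries]:
    """Cut a uniform series into fixed-span windows for segmentation.

    Windows hold ``span * rate`` samples and start every ``hop`` seconds
    (default: non-overlapping).  A trailing partial window is dropped; a
    series shorter than one window yields an empty list.
    """
    if span < min_span:
        raise ValueError(f"buffer span {span} s is below the floor of {min_span} s")
    if hop is None:
        hop = span
    if hop <= 0:
        raise ValueError("hop must be positive")
    n_win = int(round(span * series.rate))
    n_hop = max(1, int(round(hop * series.rate)))
    windows = []
    for start in range(0, series.n - n_win + 1, n_hop):
        windows.append(
            UniformSeries(
                rate=series.rate,
                t0=series.t0 + start / series.rate,
                a=series.a[start : start + n_win],
                q=series.q[start : start + n_win],
            )
        )
    return windows
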