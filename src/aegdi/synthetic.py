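"""Seeded synthetic multi-subject gait recordings with known ground truth.

Real gait accelerometry is quasi-periodic: each cycle shows a dominant
spike in the acceleration magnitude plus sub-dominant structure, the
waveform is a stable per-subject signature, timestamps jitter because the
phone's OS multitasks, and the device orientation changes every time it is
pocketed.  The generator emulates exactly those features — per-axis sums
of 3-5 harmonics of the cadence frequency with seeded amplitudes and
phases, truncated-Gaussian inter-sample intervals, Gaussian sensor noise,
and a per-session rigid transform — so every downstream stage can be
tested offline against known cycle starts, subject identities and applied
orientations.  It does not attempt biomechanical realism (no treadmill or
incline variation, no sensor bias or drift).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import ImuRecording, magnitude

logger = logging.getLogger(__name__)

#: Range (s) that per-subject gait-cycle durations are drawn from.
CADENCE_RANGE = (0.9, 1.25)

#: Number of harmonics of the cadence frequency per axis.
N_HARMONICS = 4

#: Uniform amplitude ranges per harmonic order, accelerometer (m/s^2).
ACCEL_AMPLITUDES = ((1.8, 3.0), (0.3, 0.9), (0.1, 0.5), (0.05, 0.3))

#: Uniform amplitude ranges per harmonic order, gyroscope (rad/s).
GYRO_AMPLITUDES = ((0.5, 1.2), (0.2, 0.6), (0.05, 0.25), (0.02, 0.15))

#: Standard gravity magnitude placed on the z axis before per-subject jitter.
GRAVITY = 9.81

#: Default sensor-noise standard deviations (m/s^2, rad/s).
ACCEL_NOISE_SD = 0.15
GYRO_NOISE_SD = 0.05

#: Inter-sample intervals are floored at this fraction of the mean interval.
INTERVAL_FLOOR_FRACTION = 0.2

_ROTATION_TOL = 1e-8


@dataclass
class SubjectSpec:
    """Per-subject waveform signature.

    ``accel_harmonics`` / ``gyro_harmonics`` are lists (one per axis) of
    ``(order, amplitude, phase)`` triples; the signal on each axis is the
    sum of ``amplitude * cos(2*pi*order*t/cadence_period + phase)`` plus,
    for the accelerometer, a constant gravity offset.
    """

    subject_id: int
    cadence_period: float
    accel_harmonics: list[list[tuple[int, float, float]]]
    gyro_harmonics: list[list[tuple[int, float, float]]]
    gravity_offset: np.ndarray
    noise_sd: float
    gyro_noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        if self.cadence_period <= 0:
            raise ValueError("cadence_period must be positive")
        for table in (self.accel_harmonics, self.gyro_harmonics):
            for axis in table:
                if len(axis) < 2:
                    raise ValueError("need at least 2 harmonics per axis")
        self.gravity_offset = np.asarray(self.gravity_offset, dtype=float)

    def harmonic_vector(self) -> np.ndarray:
        """Flat vector of all harmonic amplitudes and phases (for distances)."""
        vals = []
        for table in (self.accel_harmonics, self.gyro_harmonics):
            for axis in table:
                for _, amp, phase in axis:
                    vals.extend((amp, phase))
        return np.asarray(vals)


@dataclass
class SessionSpec:
    """One recording session: duration, sampling statistics and device pose."""

    duration: float
    target_rate_mean: float = 28.57
    target_rate_sd: float = 4.17
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.orientation = np.asarray(self.orientation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        _check_rotation(self.orientation)
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.duration < 4.0:
            raise ValueError("session duration must be at least 4 s")


def _check_rotation(rotation: np.ndarray) -> None:
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3):
        raise ValueError("rotation must be a 3x3 matrix")
    if not np.allclose(rotation.T @ rotation, np.eye(3), atol=_ROTATION_TOL):
        raise ValueError("rotation matrix is not orthonormal")
    if not np.isclose(np.linalg.det(rotation), 1.0, atol=_ROTATION_TOL):
        raise ValueError("rotation matrix must have determinant +1")


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random proper rotation via QR of a Gaussian matrix."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))  # make decomposition unique
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _draw_harmonics(rng, ranges) -> list[list[tuple[int, float, float]]]:
    table = []
    for _axis in range(3):
        axis = []
        for order in range(1, N_HARMONICS + 1):
            lo, hi = ranges[order - 1]
            axis.append(
                (order, float(rng.uniform(lo, hi)), float(rng.uniform(0, 2 * np.pi)))
            )
        table.append(axis)
    return table


def make_subject(
    subject_id: int,
    seed: int,
    cadence_range: tuple[float, float] = CADENCE_RANGE,
    noise_sd: float = ACCEL_NOISE_SD,
    gyro_noise_sd: float = GYRO_NOISE_SD,
) -> SubjectSpec:
    """Draw a subject's waveform signature from seeded distributions.

    The same ``(subject_id, seed)`` always yields the same spec; distinct
    subject ids give distinct harmonic tables with overwhelming probability.
    ``cadence_range`` and the amplitude ranges are the knobs controlling
    inter-subject separability.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(subject_id)]))
    cadence = float(rng.uniform(*cadence_range))
    accel = _draw_harmonics(rng, ACCEL_AMPLITUDES)
    gyro = _draw_harmonics(rng, GYRO_AMPLITUDES)
    gravity = np.array([0.0, 0.0, GRAVITY]) + rng.uniform(-0.3, 0.3, size=3)
    return SubjectSpec(
        subject_id=subject_id,
        cadence_period=cadence,
        accel_harmonics=accel,
        gyro_harmonics=gyro,
        gravity_offset=gravity,
        noise_sd=noise_sd,
        gyro_noise_sd=gyro_noise_sd,
        seed=seed,
    )


def random_session(
    seed: int,
    duration: float,
    target_rate_mean: float = 28.57,
    target_rate_sd: float = 4.17,
) -> SessionSpec:
    """Session with a random device orientation, emulating re-pocketing."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 915]))
    return SessionSpec(
        duration=duration,
        target_rate_mean=target_rate_mean,
        target_rate_sd=target_rate_sd,
        orientation=random_rotation(rng),
        seed=seed,
    )


def _harmonic_signal(table, period: float, t: np.ndarray) -> np.ndarray:
    """Evaluate the harmonic sum on each axis; shape (len(t), 3)."""
    out = np.zeros((t.shape[0], 3))
    for axis_idx, axis in enumerate(table):
        for order, amp, phase in axis:
            out[:, axis_idx] += amp * np.cos(2 * np.pi * order * t / period + phase)
    return out


def _noiseless_accel(subject: SubjectSpec, t: np.ndarray) -> np.ndarray:
    return _harmonic_signal(subject.accel_harmonics, subject.cadence_period, t) + (
        subject.gravity_offset
    )


def cycle_peak_phase(subject: SubjectSpec, resolution: int = 4096) -> float:
    """Phase (s, in [0, P)) of the dominant |a| peak within one cycle.

    Ground-truth cycle starts are defined as the global per-cycle maximum of
    the noiseless acceleration-magnitude signal, matching the assumption
    that each gait cycle starts with a peak in the magnitude series.
    """
    p = subject.cadence_period
    grid = np.arange(resolution) * (p / resolution)
    mag = magnitude(_noiseless_accel(subject, grid))
    return float(grid[int(np.argmax(mag))])


def apply_rigid_transform(
    series: np.ndarray,
    rotation: np.ndarray,
    translation: np.ndarray,
    scale: float,
) -> np.ndarray:
    """Map every sample ``x`` to ``scale * rotation @ x + translation``."""
    _check_rotation(rotation)
    if scale <= 0:
        raise ValueError("scale must be positive")
    series = np.asarray(series, dtype=float)
    return scale * series @ np.asarray(rotation, dtype=float).T + np.asarray(
        translation, dtype=float
    )


def simulate_recording(
    subject: SubjectSpec, session: SessionSpec
) -> tuple[ImuRecording, list[float]]:
    """Simulate one session and return (recording, ground-truth starts).

    Timestamps are strictly increasing with truncated-Gaussian spacing
    around the target rate; both channels are harmonic sums at the cadence
    frequency plus Gaussian noise, then transformed by the session's
    orientation/translation/scale.  Ground-truth starts (seconds) mark the
    dominant noiseless acceleration-magnitude peak of each cycle.
    """
    if session.duration < 2 * subject.cadence_period:
        raise ValueError(
            "session duration must cover at least two gait cycles "
            f"({session.duration} s < 2 * {subject.cadence_period} s)"
        )
    rng = np.random.default_rng(
        np.random.SeedSequence([int(subject.seed), int(subject.subject_id), int(session.seed)])
    )
    mean_int = 1.0 / session.target_rate_mean
    sd_int = session.target_rate_sd / session.target_rate_mean**2
    n_max = int(np.ceil(session.duration / (INTERVAL_FLOOR_FRACTION * mean_int))) + 1
    intervals = rng.normal(mean_int, sd_int, size=n_max)
    intervals = np.maximum(intervals, INTERVAL_FLOOR_FRACTION * mean_int)
    t = np.concatenate([[0.0], np.cumsum(intervals)])
    t = t[t <= session.duration]

    accel = _noiseless_accel(subject, t)
    gyro = _harmonic_signal(subject.gyro_harmonics, subject.cadence_period, t)
    if subject.noise_sd > 0:
        accel = accel + rng.normal(0.0, subject.noise_sd, size=accel.shape)
    if subject.gyro_noise_sd > 0:
        gyro = gyro + rng.normal(0.0, subject.gyro_noise_sd, size=gyro.shape)
    accel = apply_rigid_transform(
        accel, session.orientation, session.translation, session.scale
    )
    gyro = apply_rigid_transform(
        gyro, session.orientation, session.translation, session.scale
    )

    phase = cycle_peak_phase(subject)
    starts = []
    k = 0
    while phase + k * subject.cadence_period < session.duration:
        starts.append(phase + k * subject.cadence_period)
        k += 1
    return ImuRecording(t, accel, gyro), starts


def attenuated_peak_series(
    period: int = 50,
    n_cycles: int = 8,
    attenuate_cycle: int = 5,
    factor: float = 0.6,
    baseline: float = 10.0,
    amplitudes: tuple[float, ...] = (1.0, 0.35, 0.15),
    phases: tuple[float, ...] = (0.0, 0.7, 1.9),
) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude-series fixture with one cycle's dominant peak attenuated.

    Returns ``(aM, true_starts)`` where ``aM`` is a periodic harmonic sum
    of ``n_cycles * period`` samples whose dominant peak in cycle
    ``attenuate_cycle`` has its deviation from baseline scaled by
    ``factor`` inside a narrow window.  The weakened peak remains a local
    maximum, reproducing the "weak peak that still marks gait periodicity"
    robustness scenario for the segmenter.
    """
    n = n_cycles * period
    t = np.arange(n)
    am = np.full(n, baseline)
    for order, (amp, phase) in enumerate(zip(amplitudes, phases), start=1):
        am = am + amp * np.cos(2 * np.pi * order * t / period + phase)

    one = am[:period]
    peak_phase = int(np.argmax(one))
    starts = peak_phase + period * np.arange(n_cycles)

    target = int(starts[attenuate_cycle])
    half = max(2, period // 8)
    lo, hi = max(0, target - half), min(n, target + half + 1)
    ref = min(am[lo], am[hi - 1])
    am[lo:hi] = ref + factor * (am[lo:hi] - ref)
    return am, starts


def save_starts(path, starts) -> None:
    """Sidecar text file of ground-truth start times, one per line."""
    np.savetxt(path, np.asarray(starts, dtype=float), fmt="%.6f")


def load_starts(path) -> np.ndarray:
    return np.atleast_1d(np.loadtxt(path, dtype=float))
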