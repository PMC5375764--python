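"""Angle-embedded gait dynamic images (AE-GDIs) and baselines.

An AE-GDI turns a window of a triaxial series into an image: treating the
samples as points in 3-D space, pixel ``(j, i)`` is the angle at vertex
``x(t)`` (``t = start + i``) between the chords to ``x(t - j)`` and
``x(t + j)`` for time delay ``j``.  Angles are preserved by any rotation,
translation or uniform scaling of the point sequence, so the image is
invariant to how the device was oriented or calibrated — the property the
whole pipeline rests on.  The delay-inner-product GDI baseline (rotation-
but not translation-invariant) and the overlap-window segmentation
baseline are provided for comparison experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np

logger = logging.getLogger(__name__)

#: Experimental AE-GDI geometry: window width (samples) and max time delay.
DEFAULT_NW = 64
DEFAULT_NH = 32

#: Legs shorter than this are treated as degenerate vertices.
DEGENERATE_TOL = 1e-12

CHANNEL_ORDER = ("accel", "gyro")


@dataclass
class AeGdi:
    """One AE-GDI: ``(Nl, Nh, Nw)`` angle image aligned to a cycle start.

    Row ``j`` (0-based) holds time delay ``m = j + 1``; delay 0 is excluded
    because its legs would be zero vectors everywhere.  ``degenerate``
    flags pixels whose angle was undefined (a zero-length leg) and was set
    to 0.
    """

    pixels: np.ndarray
    start: int
    channels: tuple[str, ...]
    degenerate: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[None]
        if self.pixels.ndim != 3:
            raise ValueError("pixels must have shape (Nl, Nh, Nw)")
        if self.degenerate is None:
            self.degenerate = np.zeros(self.pixels.shape, dtype=bool)

    @property
    def nl(self) -> int:
        return self.pixels.shape[0]

    @property
    def nh(self) -> int:
        return self.pixels.shape[1]

    @property
    def nw(self) -> int:
        return self.pixels.shape[2]


def angle_feature(x: np.ndarray, m: int, t: int, tol: float = DEGENERATE_TOL) -> float:
    """Angle (radians) at vertex ``x(t)`` between delay-``m`` chords.

    Computed as ``arccos`` of the normalized inner product of
    ``x(t-m) - x(t)`` and ``x(t+m) - x(t)`` with the cosine clipped to
    ``[-1, 1]``.  A leg shorter than ``tol`` makes the angle undefined;
    0 is returned (callers track the degenerate flag via
    :func:`generate_aegdi`).
    """
    x = np.asarray(x, dtype=float)
    if not 0 < m < len(x) / 2:
        raise ValueError(f"delay m={m} out of range for series of length {len(x)}")
    if not m <= t <= len(x) - 1 - m:
        raise ValueError(f"t={t} leaves delay-{m} neighbours out of range")
    u = x[t - m] - x[t]
    v = x[t + m] - x[t]
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < tol or nv < tol:
        return 0.0
    cos = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.arccos(cos))


def generate_aegdi(
    x: np.ndarray,
    start: int,
    nw: int = DEFAULT_NW,
    nh: int = DEFAULT_NH,
    channel: str = "accel",
    tol: float = DEGENERATE_TOL,
) -> AeGdi | None:
    """Encode one cycle-aligned window of a 3-vector series as an AE-GDI.

    Entry ``(j, i)`` is the delay-``(j+1)`` vertex angle at ``start + i``
    for ``i = 0..nw-1``, ``j = 0..nh-1``.  Cycles whose window would index
    outside the series are skipped (returns ``None`` with a logged reason)
    rather than padded, because padding would fabricate angles.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if start - nh < 0 or start + nw - 1 + nh > n - 1:
        logger.info(
            "skipping cycle at %d: needs samples [%d, %d] outside [0, %d]",
            start, start - nh, start + nw - 1 + nh, n - 1,
        )
        return None
    pixels = np.zeros((nh, nw))
    degenerate = np.zeros((nh, nw), dtype=bool)
    base = x[start : start + nw]                      # x(t), t = start + i
    for j in range(1, nh + 1):
        u = x[start - j : start - j + nw] - base
        v = x[start + j : start + j + nw] - base
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        bad = (nu < tol) | (nv < tol)
        denom = np.where(bad, 1.0, nu * nv)
        cos = np.clip(np.einsum("ij,ij->i", u, v) / denom, -1.0, 1.0)
        row = np.arccos(cos)
        row[bad] = 0.0
        pixels[j - 1] = row
        degenerate[j - 1] = bad
    return AeGdi(pixels[None], start, (channel,), degenerate[None])


def assemble_channels(*gdis: AeGdi) -> AeGdi:
    """Stack single-channel AE-GDIs into the canonical (accel, gyro) order.

    Accepts one or two single-channel images in any argument order; the
    acceleration channel is always stored first.
    """
    if not 1 <= len(gdis) <= 2:
        raise ValueError("expected one or two single-channel AE-GDIs")
    by_name: dict[str, AeGdi] = {}
    for g in gdis:
        if g.nl != 1:
            raise ValueError("assemble_channels expects single-channel inputs")
        name = g.channels[0]
        if name in by_name:
            raise ValueError(f"duplicate channel {name!r}")
        by_name[name] = g
    ordered = [by_name[name] for name in CHANNEL_ORDER if name in by_name]
    if len(ordered) != len(gdis):
        raise ValueError(f"unknown channel names {sorted(by_name)}")
    first = ordered[0]
    for g in ordered[1:]:
        if g.start != first.start or g.pixels.shape != first.pixels.shape:
            raise ValueError("channel shape or start mismatch")
    return AeGdi(
        np.concatenate([g.pixels for g in ordered], axis=0),
        first.start,
        tuple(g.channels[0] for g in ordered),
        np.concatenate([g.degenerate for g in ordered], axis=0),
    )


def generate_gdi(
    x: np.ndarray, start: int, nw: int = DEFAULT_NW, nh: int = DEFAULT_NH
) -> np.ndarray | None:
    """Delay-inner-product image baseline: entry ``(j, i)`` is
    ``<x(start+i), x(start+i+j+1)>``.

    Rotation-invariant but, unlike the AE-GDI, changed by translating the
    series. ``None`` when the window would index outside the series.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if start < 0 or start + nw - 1 + nh > n - 1:
        logger.info("skipping GDI at %d: window outside series", start)
        return None
    base = x[start : start + nw]
    out = np.zeros((nh, nw))
    for j in range(1, nh + 1):
        out[j - 1] = np.einsum("ij,ij->i", base, x[start + j : start + j + nw])
    return out


def overlap_window_starts(
    series_len: int,
    rate: float,
    window: float = 1.28,
    overlap: float = 0.5,
) -> np.ndarray:
    """Fixed-size sliding-window starts (baseline segmentation).

    Windows of ``window`` seconds begin every ``window - overlap`` seconds
    while a full window fits in the series.
    """
    if not window > overlap >= 0:
        raise ValueError("need window > overlap >= 0")
    n_win = int(round(window * rate))
    n_hop = int(round((window - overlap) * rate))
    if n_win > series_len:
        return np.array([], dtype=int)
    return np.arange(0, series_len - n_win + 1, n_hop)


def encode_cycles(
    accel: np.ndarray,
    gyro: np.ndarray | None,
    starts,
    nw: int = DEFAULT_NW,
    nh: int = DEFAULT_NH,
) -> tuple[np.ndarray, np.ndarray]:
    """Encode every feasible cycle start into a stacked AE-GDI batch.

    Returns ``(pixels, kept_starts)`` with ``pixels`` of shape
    ``(n_kept, Nl, nh, nw)``; both channels use the same start indexes
    (cycles are detected once per buffer on the magnitude series).
    """
    batch, kept = [], []
    for start in np.asarray(starts, dtype=int):
        a_img = generate_aegdi(accel, int(start), nw, nh, channel="accel")
        if a_img is None:
            continue
        if gyro is not None:
            q_img = generate_aegdi(gyro, int(start), nw, nh, channel="gyro")
            if q_img is None:
                continue
            img = assemble_channels(a_img, q_img)
        else:
            img = a_img
        batch.append(img.pixels)
        kept.append(int(start))
    if not batch:
        nl = 1 if gyro is None else 2
        return np.zeros((0, nl, nh, nw)), np.array([], dtype=int)
    return np.stack(batch), np.asarray(kept, dtype=int)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_gdis(
    path,
    pixels: np.ndarray,
    starts: np.ndarray,
    subject: np.ndarray,
    session: np.ndarray,
    rate: float,
    nw: int,
    nh: int,
) -> None:
    """Persist an AE-GDI batch (count x Nl x Nh x Nw) as HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("pixels", data=np.asarray(pixels, dtype=np.float32))
        f.create_dataset("starts", data=np.asarray(starts, dtype=np.int64))
        f.create_dataset("subject", data=np.asarray(subject, dtype=np.int64))
        f.create_dataset("session", data=np.asarray(session, dtype=np.int64))
        f.attrs["rate"] = rate
        f.attrs["nw"] = nw
        f.attrs["nh"] = nh


def load_gdis(path) -> dict:
    with h5py.File(path, "r") as f:
        return {
            "pixels": f["pixels"][()].astype(float),
            "starts": f["starts"][()],
            "subject": f["subject"][()],
            "session": f["session"][()],
            "rate": float(f.attrs["rate"]),
            "nw": int(f.attrs["nw"]),
            "nh": int(f.attrs["nh"]),
        }


def export_png(gdi: AeGdi, path) -> None:
    """Optional visual export; grayscale, one file per channel suffix."""
    from matplotlib import image as mpimg  # deferred: viz-only dependency

    for name, channel in zip(gdi.channels, gdi.pixels):
        target = str(path)
        if gdi.nl > 1:
            stem, dot, ext = target.rpartition(".")
            target = f"{stem}_{name}.{ext}" if dot else f"{target}_{name}"
        mpimg.imsave(target, channel, cmap="viridis", vmin=0.0, vmax=np.pi)
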