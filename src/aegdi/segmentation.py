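"""Gait-cycle starting-position detection on the acceleration magnitude.

Each gait cycle is assumed to start with a peak in the magnitude series
``aM``.  Simple successive comparison of peaks can reject the meaningful
one when a cycle happens to show a weak peak, so detection proceeds in
three steps:

1.  the cycle period ``g`` (samples) is estimated from the circular
    autocorrelation of the mean-removed series;
2.  every local maximum is scored by its height plus the arc length of the
    nearest U-shaped valley to its left, and the top-scoring peaks form a
    candidate set ``C``;
3.  a quasi-equally spaced grid of cycle starts is fitted greedily: first
    the grid offset ``b`` and spacing ``c`` are iterated by snapping grid
    points to nearby candidates (radius ``g/2``), then each grid point is
    locally optimised (radius ``g/4``) with a score penalised by distance
    from the grid, which keeps a weak-but-periodic peak competitive against
    a strong aperiodic one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


class SegmentationError(RuntimeError):
    """Raised when a magnitude series cannot be segmented into cycles."""


class PeriodEstimationError(SegmentationError):
    """Raised when no periodicity is found in the configured lag window."""


@dataclass
class SegmentationConfig:
    """Tunable parameters of the segmenter.

    epsilon
        Eq-length coefficient: one sample interval contributes an
        "equivalent length" of ``epsilon / rate`` to arc lengths and to the
        stage-2 distance penalty.  ``None`` (default) picks epsilon so that
        ``epsilon / rate = 0.1 * std(aM)``.
    min_seg_len
        Monotone runs with arc length below ``min_seg_len * epsilon/rate``
        are omitted from U-shape assembly.
    lag_window
        Period-search window in seconds for the autocorrelation.
    min_periodicity
        Minimum normalized circular autocorrelation required at the best
        lag; below it the input is declared non-periodic.
    period_tie_tol
        Relative band within which a shorter lag is preferred over the
        maximum, guarding against locking onto the double period of an
        almost exactly periodic series.
    term_eps
        Stage-1 termination threshold (samples) on max(|db|, |dc|).
    """

    rate: float = 50.0
    epsilon: float | None = None
    min_seg_len: float = 3.0
    lag_window: tuple[float, float] = (0.4, 2.0)
    min_periodicity: float = 0.2
    period_tie_tol: float = 0.02
    term_eps: float = 0.5
    max_iter: int = 20


@dataclass
class MonotoneSegment:
    """Maximal monotone run ``[start, end]`` (inclusive) with arc length."""

    start: int
    end: int
    sign: int
    length: float


@dataclass
class PeakScoreTable:
    """Peak indicators, scores and U-shape bookkeeping for one buffer."""

    peaks: np.ndarray          # bool, shape (n,)
    scores: np.ndarray         # tau(t), zero off-peak
    u_lengths: np.ndarray      # lU(t), zero off-peak
    segments: list[MonotoneSegment]


@dataclass
class SegmentationResult:
    period_estimate: int
    candidates: np.ndarray     # sorted candidate indexes C
    grid_offset: float         # b
    grid_spacing: float        # c
    starts: np.ndarray         # final cycle starts h(k), strictly increasing
    n_cycles: int
    table: PeakScoreTable
    n_iterations: int = 0
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# period estimation
# ---------------------------------------------------------------------------

def estimate_period(
    aM: np.ndarray,
    rate: float = 50.0,
    lag_window: tuple[float, float] = (0.4, 2.0),
    min_periodicity: float = 0.2,
    tie_tol: float = 0.02,
) -> int:
    """Estimate the gait period in samples via circular autocorrelation.

    The lag maximising the circular autocorrelation of the mean-removed
    series within ``lag_window`` is returned; among lags whose normalized
    autocorrelation is within ``tie_tol`` of the maximum the smallest is
    preferred (the double period of an exactly periodic series correlates
    equally well).

    Raises
    ------
    PeriodEstimationError
        If the normalized autocorrelation never reaches ``min_periodicity``
        in the window, i.e. the input is not periodic there.
    """
    x = np.asarray(aM, dtype=float)
    n = x.shape[0]
    x = x - x.mean()
    r = np.fft.irfft(np.abs(np.fft.rfft(x)) ** 2, n=n)
    r0 = r[0]
    if r0 <= 0:
        raise PeriodEstimationError("constant series has no periodicity")
    lo = max(1, int(round(lag_window[0] * rate)))
    hi = min(n // 2, int(round(lag_window[1] * rate)))
    if hi <= lo:
        raise PeriodEstimationError(
            f"series too short to search lags in {lag_window} s at {rate} Hz"
        )
    window = r[lo : hi + 1] / r0
    best = float(window.max())
    if best < min_periodicity:
        raise PeriodEstimationError(
            f"no autocorrelation peak above {min_periodicity} in the lag window "
            f"(max {best:.3f}); input looks non-periodic"
        )
    # Prefer the smallest *locally maximal* lag within the tie band: for an
    # almost exactly periodic series the double period correlates equally
    # well, but neighbouring lags of a smooth peak must not shadow it.
    interior = np.arange(1, window.size - 1)
    is_local_max = (window[interior] >= window[interior - 1]) & (
        window[interior] >= window[interior + 1]
    )
    local = interior[is_local_max]
    near = local[window[local] >= best * (1 - tie_tol)] if local.size else np.array([], dtype=int)
    if near.size == 0:
        near = np.asarray([int(np.argmax(window))])
    return int(lo + near[0])


# ---------------------------------------------------------------------------
# peaks, monotone segments, U-shapes, scores
# ---------------------------------------------------------------------------

def find_peaks(aM: np.ndarray) -> np.ndarray:
    """Local-maximum indicator: left-strict, right-non-strict comparison.

    ``p(t) = 1`` iff ``aM(t-1) < aM(t) >= aM(t+1)``; endpoints are never
    peaks and a plateau collapses to its leftmost index.
    """
    x = np.asarray(aM, dtype=float)
    p = np.zeros(x.shape[0], dtype=bool)
    if x.shape[0] >= 3:
        p[1:-1] = (x[1:-1] > x[:-2]) & (x[1:-1] >= x[2:])
    return p


def monotone_segments(
    aM: np.ndarray,
    epsilon: float,
    rate: float,
    min_len: float = 3.0,
) -> list[MonotoneSegment]:
    """Maximal monotone runs of ``aM`` with their arc lengths.

    Each step contributes ``sqrt(da^2 + (epsilon/rate)^2)`` so the series
    is treated as a planar shape whose sample spacing has the equivalent
    length ``epsilon/rate``.  Runs with arc length below
    ``min_len * epsilon/rate`` are dropped, and adjacent surviving runs of
    equal sign are merged so the result alternates in sign.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    x = np.asarray(aM, dtype=float)
    d = np.diff(x)
    if d.size == 0:
        return []
    step_time = epsilon / rate
    step_len = np.sqrt(d**2 + step_time**2)
    signs = np.sign(d).astype(int)

    raw: list[MonotoneSegment] = []
    run_start = 0
    run_sign = 0
    for i, s in enumerate(signs):
        if s == 0:
            continue  # flat steps extend the current run
        if run_sign == 0:
            run_sign = s
            run_start = i
        elif s != run_sign:
            raw.append(
                MonotoneSegment(
                    run_start, i, run_sign, float(step_len[run_start:i].sum())
                )
            )
            run_sign = s
            run_start = i
    if run_sign != 0:
        raw.append(
            MonotoneSegment(
                run_start, d.size, run_sign, float(step_len[run_start:].sum())
            )
        )

    threshold = min_len * step_time
    kept = [seg for seg in raw if seg.length >= threshold and seg.length > 0]
    merged: list[MonotoneSegment] = []
    for seg in kept:
        if merged and merged[-1].sign == seg.sign:
            prev = merged[-1]
            merged[-1] = MonotoneSegment(
                prev.start, seg.end, seg.sign, prev.length + seg.length
            )
        else:
            merged.append(seg)
    return merged


def u_shape_length_left(t: int, segments: list[MonotoneSegment]) -> float:
    """Arc length of the nearest U-shaped valley wholly to the left of ``t``.

    A U-shape is an adjacent (decreasing, increasing) segment pair; its
    length is the sum of the two arc lengths.  Returns 0 when no valid pair
    ends at or before ``t``.
    """
    best = 0.0
    best_end = -1
    for i in range(len(segments) - 1):
        down, up = segments[i], segments[i + 1]
        if down.sign < 0 < up.sign and up.end <= t and up.end > best_end:
            best_end = up.end
            best = down.length + up.length
    return best


def candidate_count(n: int, period: int) -> int:
    """Smallest integer strictly greater than ``2 n / period``."""
    return int(np.floor(2 * n / period)) + 1


def score_candidates(
    aM: np.ndarray,
    peaks: np.ndarray,
    u_lengths: np.ndarray,
    period: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Score peaks by height plus left-U-shape length; keep the top ones.

    Returns ``(tau, candidates)`` where ``tau(t) = p(t) (aM(t) + lU(t))``
    and ``candidates`` are the ``Nc`` highest-scoring peak indexes (sorted
    ascending), ``Nc`` being the smallest integer above ``2 n / period``.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    x = np.asarray(aM, dtype=float)
    tau = np.where(peaks, x + u_lengths, 0.0)
    peak_idx = np.nonzero(peaks)[0]
    nc = candidate_count(x.shape[0], period)
    if peak_idx.size <= nc:
        if peak_idx.size < nc:
            logger.warning(
                "only %d peaks available for %d requested candidates",
                peak_idx.size,
                nc,
            )
        chosen = peak_idx
    else:
        order = np.argsort(tau[peak_idx], kind="stable")[::-1]
        chosen = np.sort(peak_idx[order[:nc]])
    return tau, chosen


def build_score_table(
    aM: np.ndarray, config: SegmentationConfig
) -> tuple[PeakScoreTable, float]:
    """Peaks, segments, U-lengths and the resolved epsilon for one buffer."""
    x = np.asarray(aM, dtype=float)
    eps = config.epsilon
    if eps is None:
        eps = 0.1 * float(np.std(x)) * config.rate
    peaks = find_peaks(x)
    segments = monotone_segments(x, eps, config.rate, config.min_seg_len)
    u_len = np.zeros(x.shape[0])
    for t in np.nonzero(peaks)[0]:
        u_len[t] = u_shape_length_left(int(t), segments)
    return PeakScoreTable(peaks, np.zeros_like(x), u_len, segments), eps


# ---------------------------------------------------------------------------
# grid-based greedy search
# ---------------------------------------------------------------------------

def _greedy_pick(
    candidates: np.ndarray,
    scores: np.ndarray,
    center: float,
    radius: float,
) -> int | None:
    """Candidate within ``radius`` of ``center`` maximising ``scores``.

    Score ties break toward the smaller distance from ``center``, then the
    smaller index, keeping the search deterministic.
    """
    dist = np.abs(candidates - center)
    sel = candidates[dist <= radius]
    if sel.size == 0:
        return None
    key = sorted(
        (float(-scores[c]), float(abs(c - center)), int(c)) for c in sel
    )
    return int(key[0][2])


def segment_gait(
    aM: np.ndarray, config: SegmentationConfig | None = None
) -> SegmentationResult:
    """Detect gait-cycle starting indexes in a magnitude buffer.

    Stage 1 fits an equally spaced grid (offset ``b``, spacing ``c``,
    initialised to 0 and the estimated period) by snapping each grid index
    to the best candidate within half a period and updating ``b`` and ``c``
    from the snaps until both move by at most ``term_eps`` samples (with an
    iteration cap).  Stage 2 relaxes the equal-spacing constraint: each
    final grid index snaps within a quarter period using the score minus a
    distance penalty of ``epsilon/rate`` per sample from the nearest grid
    point.  The snapped indexes, deduplicated and sorted, are the cycle
    starts.
    """
    config = config or SegmentationConfig()
    x = np.asarray(aM, dtype=float)
    n = x.shape[0]

    g = estimate_period(
        x, config.rate, config.lag_window, config.min_periodicity,
        config.period_tie_tol,
    )
    table, eps = build_score_table(x, config)
    tau, cand = score_candidates(x, table.peaks, table.u_lengths, g)
    table.scores = tau
    if cand.size == 0:
        raise SegmentationError("no candidate peaks found in buffer")

    # stage 1: equally spaced grid optimisation
    b, c = 0.0, float(g)
    iterations = 0
    for _ in range(config.max_iter):
        iterations += 1
        nc = int(n / c)
        grid_k = np.arange(nc)
        grid = (b + grid_k * c).astype(int)
        kept: list[tuple[int, int, int]] = []  # (k, snap, grid index)
        for k, h in zip(grid_k, grid):
            s = _greedy_pick(cand, tau, h, g / 2)
            if s is None:
                continue
            # Two grid points snapping into the same cycle (closer than half
            # a period) would bias the spacing estimate; keep the higher
            # scoring snap of such a conflict.
            if kept and s - kept[-1][1] < c / 2:
                if tau[s] > tau[kept[-1][1]]:
                    kept[-1] = (int(k), s, h)
                continue
            kept.append((int(k), s, h))
        if len(kept) < 2:
            raise SegmentationError(
                "grid fitting failed: fewer than two grid points found candidates"
            )
        k_a = np.asarray([k for k, _, _ in kept], dtype=float)
        snapped_a = np.asarray([s for _, s, _ in kept], dtype=float)
        grid_a = np.asarray([h for _, _, h in kept], dtype=float)
        c_new = float(np.median(np.diff(snapped_a) / np.diff(k_a)))
        c_new = float(np.clip(c_new, 0.5 * g, 1.5 * g))
        b_new = b + float(np.mean(snapped_a - grid_a))
        delta = max(abs(b_new - b), abs(c_new - c))
        b, c = b_new, c_new
        if delta <= config.term_eps:
            break
    b = b % c  # equivalent grid anchored inside the buffer

    # stage 2: local optimisation with distance penalty
    nc = int(n / c)
    grid = (b + np.arange(nc) * c).astype(int)
    grid_in = grid[(grid >= 0) & (grid < n)]
    if grid_in.size == 0:
        raise SegmentationError("fitted grid lies entirely outside the buffer")
    penalty_rate = eps / config.rate
    penalised = tau.copy()
    cand_dist = np.abs(cand[:, None] - grid_in[None, :]).min(axis=1)
    penalised[cand] = tau[cand] - penalty_rate * cand_dist
    starts = []
    for h in grid_in:
        s = _greedy_pick(cand, penalised, h, g / 4)
        if s is not None:
            starts.append(s)
    starts_a = np.unique(np.asarray(starts, dtype=int))
    if starts_a.size == 0:
        raise SegmentationError("no cycle starts found within grid neighbourhoods")

    return SegmentationResult(
        period_estimate=g,
        candidates=cand,
        grid_offset=b,
        grid_spacing=c,
        starts=starts_a,
        n_cycles=int(starts_a.size),
        table=table,
        n_iterations=iterations,
        extras={"epsilon": eps, "penalised_scores": penalised},
    )
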