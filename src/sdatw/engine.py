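"""Streaming, threshold-free subsequence matching of a stride template.

The matcher maintains a single column of the accumulated-distance matrix
``D`` (template rows x stream time) together with a parallel column of
memorized match-start indices, the SPRING construction.  For each
incoming sample the column is updated in O(n):

    D(j, t) = dist(j, t) + min{ D(j-1, t-1), D(j, t-1), D(j-1, t) }

with a permanently zero boundary row j = 0, so a new match may open at
any time.  Each cell inherits the stream index at which its warping path
entered row 1.  The best candidate seen so far (smallest full-template
distance ``d_min``) is *confirmed* — reported as a detected stride — as
soon as no live path overlapping it could still beat it, i.e. every row
satisfies D >= d_min or starts after the candidate ends.  The column is
then reset to +infinity ("star-padding") and the search restarts, which
makes consecutive matches disjoint.  No distance threshold appears
anywhere; the only pruning is the physiological stride-duration window
of 0.25–2.0 s.

Because a loosely worn sensor can invert the signal, a full segmentation
run matches both the original and the sign-flipped stream and keeps
whichever yields more strides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .descriptors import DescriptorConfig, describe, distance_matrix
from .errors import ParameterError
from .imu_io import ImuRecording
from .preprocess import ChannelScheme, fuse_axes, mean_filter, znormalize
from .template import StrideTemplate

__all__ = [
    "WarpState",
    "DetectedStride",
    "init_state",
    "step",
    "star_pad",
    "flush",
    "run_stream",
    "time_filter",
    "segment",
]

MIN_STRIDE_S = 0.25
MAX_STRIDE_S = 2.0


@dataclass(frozen=True)
class DetectedStride:
    """A detected stride: half-open sample interval [start, end) plus its
    accumulated warping distance."""

    start: int
    end: int
    distance: float
    sample_rate: float = 100.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ParameterError("stride must have end > start")

    @property
    def duration(self) -> float:
        return (self.end - self.start) / self.sample_rate

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class WarpState:
    """One-column streaming state of the augmented warping matrix."""

    n: int
    D_col: np.ndarray  # (n+1,) accumulated distances, row 0 = boundary 0
    s_col: np.ndarray  # (n+1,) memorized match-start stream indices
    d_min: float = np.inf
    cand_start: int = -1
    cand_end: int = -1
    t: int = 0  # next stream index to consume
    confirmed: list[DetectedStride] = field(default_factory=list)
    cell_updates: int = 0
    sample_rate: float = 100.0
    # online form of the stride-duration constraint: candidates whose
    # span (in samples) falls outside [min_span, max_span] can never be
    # physiological strides, so they are not eligible to become the
    # current candidate.  0 / inf disables the gate (pure matcher).
    min_span: int = 0
    max_span: float = np.inf
    # a match boundary is only defined up to the descriptor-window
    # half-width: paths whose start overlaps the candidate by at most
    # overlap_tol samples are near-duplicates of the *next* cycle's
    # alignment, not competitors, and survive confirmation; emitted
    # intervals are clipped so reported strides stay strictly disjoint.
    overlap_tol: int = 0
    last_end: int = 0

    @property
    def has_candidate(self) -> bool:
        return np.isfinite(self.d_min)


def init_state(
    n: int,
    sample_rate: float = 100.0,
    min_span: int = 0,
    max_span: float = np.inf,
    overlap_tol: int = 0,
) -> WarpState:
    """Fresh state: boundary row 0, interior +inf, no candidate."""
    if n < 1:
        raise ParameterError("template length must be >= 1")
    D = np.full(n + 1, np.inf)
    D[0] = 0.0
    return WarpState(
        n=n,
        D_col=D,
        s_col=np.zeros(n + 1, dtype=np.int64),
        sample_rate=sample_rate,
        min_span=min_span,
        max_span=max_span,
        overlap_tol=overlap_tol,
    )


def star_pad(state: WarpState) -> WarpState:
    """Reset the column to +inf (boundary 0) and forget start memory.

    Applied right after a candidate is confirmed so the next search
    cannot reuse any sample of the reported match.
    """
    state.D_col = np.full(state.n + 1, np.inf)
    state.D_col[0] = 0.0
    state.s_col = np.zeros(state.n + 1, dtype=np.int64)
    state.d_min = np.inf
    state.cand_start = -1
    state.cand_end = -1
    return state


def _emit(state: WarpState) -> None:
    start = max(int(state.cand_start), state.last_end)
    end = int(state.cand_end) + 1
    if start >= end:
        return  # fully shadowed by the previous report (degenerate)
    span = end - start
    if not (state.min_span <= span <= state.max_span):
        return  # confirmed but not a physiologically possible stride
    state.confirmed.append(
        DetectedStride(
            start=start,
            end=end,
            distance=float(state.d_min),
            sample_rate=state.sample_rate,
        )
    )
    state.last_end = end


def step(state: WarpState, dist_col: np.ndarray) -> WarpState:
    """Consume one stream sample: update the column, the candidate, and
    confirm/star-pad when the candidate can no longer be beaten.

    ``dist_col`` holds the descriptor distances between the incoming
    sample and each of the n template samples.  Predecessor ties are
    broken diagonal > left > down; a path entering template row 1 from
    the boundary starts a new match at the current stream index.
    """
    dist = np.asarray(dist_col, dtype=float)
    if dist.shape != (state.n,):
        raise ParameterError(f"dist_col must have shape ({state.n},), got {dist.shape}")
    if np.any(dist < 0):
        raise ParameterError("descriptor distances must be nonnegative")

    t = state.t
    D_prev = state.D_col
    s_prev = state.s_col.copy()
    s_prev[0] = t  # a boundary entry at this column starts a match here

    if np.all(np.isfinite(dist)):
        D_new, s_new = _column_scan(dist, D_prev, s_prev, t)
    else:
        D_new, s_new = _column_loop(dist, D_prev, s_prev, t)
    state.cell_updates += state.n
    state.D_col = D_new
    state.s_col = s_new
    state.t = t + 1

    # candidate replacement: a cheaper full-template alignment ends here
    # (a span beyond the longest possible stride is ineligible; short
    # degenerate candidates are dropped at emission instead, so they
    # cannot displace or truncate genuine ones)
    span = t - int(s_new[state.n]) + 1
    if D_new[state.n] < state.d_min and span <= state.max_span:
        state.d_min = float(D_new[state.n])
        state.cand_start = int(s_new[state.n])
        state.cand_end = t

    # confirmation: no live path overlapping the candidate can beat it
    if state.has_candidate:
        interior_D = D_new[1:]
        interior_s = s_new[1:]
        cutoff = state.cand_end - state.overlap_tol
        if np.all((interior_D >= state.d_min) | (interior_s > cutoff)):
            _emit(state)
            _invalidate_overlapping(state)
    return state


def _invalidate_overlapping(state: WarpState) -> None:
    """Reset only the rows whose warping path truly overlaps the match
    just emitted; paths that began after it (up to overlap_tol inside
    its tail) are exactly the ones the confirmation rule classified as
    non-competing, and they are already part-way through matching the
    next cycle.  Killing them too (a full +inf column reset) blinds the
    matcher for up to a template length after every report and, on a
    periodic stream, systematically skips alternate cycles.  Reported
    strides stay strictly disjoint because emission clips each start to
    the previous reported end."""
    overlapping = state.s_col <= state.cand_end - state.overlap_tol
    overlapping[0] = False  # boundary row stays open
    state.D_col[overlapping] = np.inf
    state.s_col[overlapping] = 0
    state.d_min = np.inf
    state.cand_start = -1
    state.cand_end = -1


def _column_scan(
    dist: np.ndarray, D_prev: np.ndarray, s_prev: np.ndarray, t: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized column update via a min-plus prefix scan.

    Splitting the recursion: E(j) = dist(j) + min(diagonal, left) uses
    only the previous column, and the remaining "down" chain D(j) =
    min(E(j), D(j-1) + dist(j)) unrolls to D(j) = C(j) + min_{k<=j}
    (E(k) - C(k)) with C the cumulative sum of dist, computable with
    ``np.minimum.accumulate``.  Ties prefer E over the chain and the
    diagonal over the left predecessor, matching the scalar recursion.
    """
    n = dist.size
    diag_D = D_prev[:-1]
    left_D = D_prev[1:]
    take_diag = diag_D <= left_D
    E = np.empty(n + 1)
    E[0] = 0.0
    E[1:] = dist + np.where(take_diag, diag_D, left_D)
    sE = np.empty(n + 1, dtype=np.int64)
    sE[0] = t
    sE[1:] = np.where(take_diag, s_prev[:-1], s_prev[1:])

    C = np.concatenate(([0.0], np.cumsum(dist)))
    G = E - C
    M = np.minimum.accumulate(G)
    record = G == M
    k_star = np.maximum.accumulate(np.where(record, np.arange(n + 1), -1))
    D_new = C + M
    D_new[0] = 0.0
    return D_new, sE[k_star]


def _column_loop(
    dist: np.ndarray, D_prev: np.ndarray, s_prev: np.ndarray, t: int
) -> tuple[np.ndarray, np.ndarray]:
    """Scalar column update; handles +inf costs the scan cannot."""
    n = dist.size
    D_new = np.empty(n + 1)
    s_new = np.empty(n + 1, dtype=np.int64)
    D_new[0] = 0.0
    s_new[0] = t
    for j in range(1, n + 1):
        cands = (
            (D_prev[j - 1], s_prev[j - 1]),  # diagonal
            (D_prev[j], s_prev[j]),  # left
            (D_new[j - 1], s_new[j - 1]),  # down
        )
        best_d, best_s = cands[0]
        for d, s in cands[1:]:
            if d < best_d:
                best_d, best_s = d, s
        D_new[j] = dist[j - 1] + best_d
        s_new[j] = best_s
    return D_new, s_new


def flush(state: WarpState) -> WarpState:
    """Emit a live full-template candidate at end of stream, if any."""
    if state.has_candidate:
        _emit(state)
        star_pad(state)
    return state


def run_stream(
    dist_matrix: np.ndarray,
    sample_rate: float = 100.0,
    min_span: int = 0,
    max_span: float = np.inf,
    overlap_tol: int = 0,
) -> tuple[list[DetectedStride], WarpState]:
    """Run the matcher over a precomputed m x n descriptor-distance matrix."""
    dm = np.asarray(dist_matrix, dtype=float)
    state = init_state(
        dm.shape[1],
        sample_rate=sample_rate,
        min_span=min_span,
        max_span=max_span,
        overlap_tol=overlap_tol,
    )
    for row in dm:
        step(state, row)
    flush(state)
    return list(state.confirmed), state


def time_filter(
    strides: list[DetectedStride], sample_rate: float | None = None
) -> list[DetectedStride]:
    """Keep strides with physiological duration (0.25–2.0 s, inclusive)."""
    kept = []
    for s in strides:
        fs = sample_rate if sample_rate is not None else s.sample_rate
        duration = (s.end - s.start) / fs
        if MIN_STRIDE_S <= duration <= MAX_STRIDE_S:
            kept.append(s)
    return kept


def _select_signals(
    acc: np.ndarray,
    gyro: np.ndarray,
    scheme: ChannelScheme,
    smooth_window: int,
) -> list[np.ndarray]:
    """Channel selection, acc smoothing and optional modulus fusion."""
    source = acc if scheme.sensor == "acc" else gyro
    axes = [source[:, i].astype(float) for i in scheme.axis_indices]
    if scheme.sensor == "acc" and smooth_window > 1:
        axes = [mean_filter(a, smooth_window) for a in axes]
    if scheme.fused:
        return [fuse_axes(np.stack(axes, axis=1))]
    return axes


def segment(
    rec: ImuRecording,
    template: StrideTemplate,
    config: DescriptorConfig,
    scheme: ChannelScheme,
    smooth_window: int = 5,
    try_flip: bool = True,
) -> list[DetectedStride]:
    """Full pipeline: select channels, normalize, describe, stream-match.

    Both the original and the sign-flipped stream are matched and the
    run detecting more strides wins (ties go to the original), which
    compensates for inverted mounting of a loosely worn sensor.
    """
    q_raw = _select_signals(rec.acc, rec.gyro, scheme, smooth_window)
    t_raw = _select_signals(template.B[:, 0:3], template.B[:, 3:6], scheme, smooth_window)

    # the template is one cycle of a periodic signal: wrap its window
    # context so boundary descriptors see adjacent-cycle samples
    t_desc = [describe(znormalize(sig), config, scheme, pad="wrap") for sig in t_raw]

    def run(sign: float) -> list[DetectedStride]:
        q_desc = [describe(sign * znormalize(sig), config, scheme) for sig in q_raw]
        dm = distance_matrix(q_desc, t_desc)
        strides, _ = run_stream(
            dm,
            sample_rate=rec.sample_rate,
            min_span=int(round(MIN_STRIDE_S * rec.sample_rate)),
            max_span=int(round(MAX_STRIDE_S * rec.sample_rate)),
            overlap_tol=config.l // 2,
        )
        return time_filter(strides)

    original = run(1.0)
    if not try_flip:
        return original
    flipped = run(-1.0)
    return flipped if _run_quality(flipped) > _run_quality(original) else original


def _run_quality(strides: list[DetectedStride]) -> float:
    """Orientation-selection score: detection count, discounted by match
    distance.  The correctly oriented stream both segments into more
    template-shaped cycles and fits each of them more tightly, so the
    count is divided by the median per-stride warping distance; a count
    alone can be inflated by spurious fragments of a badly fitting
    orientation."""
    if not strides:
        return 0.0
    return len(strides) / float(np.median([s.distance for s in strides]))
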