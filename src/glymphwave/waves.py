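"""Detection of infra-slow global-signal waves propagating along the cortical hierarchy.

Cortical units are sorted by their principal-gradient (PG) value into
position bins; the bin-averaged, temporally interpolated BOLD forms a
time-position graph in which propagating waves appear as tilted bands. The
graph is cut at troughs of the global signal, and within each segment the
per-bin local peak timings (relative to the global peak) are correlated with
bin position: a strong positive time-position correlation marks a bottom-up
(sensory-motor to DMN) wave, a strong negative one a top-down wave.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline
from scipy.stats import ttest_ind

from .preprocess import BoldSession

__all__ = [
    "DEFAULT_N_BINS",
    "DEFAULT_INTERP_FACTOR",
    "DEFAULT_DIRECTION_THRESHOLD",
    "DEFAULT_MIN_BINS_WITH_PEAK",
    "TimePositionGraph",
    "Segment",
    "PropagationEvent",
    "MeanWavePattern",
    "pg_bin",
    "interpolate_series",
    "time_position_graph",
    "segment_by_troughs",
    "detect_propagation",
    "detect_session_propagations",
    "average_propagations",
    "snapshot",
    "compare_wave_groups",
]

DEFAULT_N_BINS = 70
DEFAULT_INTERP_FACTOR = 5  # 3 s TR -> 0.6 s interpolated resolution
DEFAULT_DIRECTION_THRESHOLD = 0.3  # |time-position r| needed to call a direction
DEFAULT_MIN_BINS_WITH_PEAK = 50  # validity requires strictly more bins with a peak
DEFAULT_TROUGH_PROMINENCE_SD = 0.25  # trough prominence floor, in SDs of gBOLD
DEFAULT_WINDOW_S = 12.0  # averaging window centered on the gBOLD peak


def pg_bin(pg_values: np.ndarray, n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Assign each unit to one of ``n_bins`` contiguous rank-order position bins.

    Units are sorted by PG value and split into bins whose sizes differ by at
    most one; when the count does not divide evenly, the extra units go to
    the highest-PG bins (deterministically).
    """
    pg_values = np.asarray(pg_values, dtype=float)
    n = pg_values.size
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} units, got {n}")
    base, rem = divmod(n, n_bins)
    sizes = np.full(n_bins, base)
    if rem:
        sizes[-rem:] += 1
    order = np.argsort(pg_values, kind="stable")
    bins = np.empty(n, dtype=int)
    bins[order] = np.repeat(np.arange(n_bins), sizes)
    return bins


def interpolate_series(series: np.ndarray, tr: float, interp_factor: int) -> tuple[np.ndarray, float]:
    """Cubic-spline temporal interpolation along the last axis.

    Returns the resampled data and the new sampling interval ``tr / factor``
    (0.6 s for a 3 s TR at the default factor of 5).
    """
    if interp_factor < 1:
        raise ValueError("interp_factor must be >= 1")
    series = np.asarray(series, dtype=float)
    n_t = series.shape[-1]
    if interp_factor == 1:
        return series.copy(), tr
    t = np.arange(n_t) * tr
    dt = tr / interp_factor
    t_fine = np.arange((n_t - 1) * interp_factor + 1) * dt
    spline = CubicSpline(t, series, axis=-1)
    return spline(t_fine), dt


@dataclass
class TimePositionGraph:
    """Bin x interpolated-time matrix of bin-mean BOLD, ordered along the PG."""

    data: np.ndarray  # (n_bins, n_frames)
    interval: float  # seconds between interpolated frames
    gbold: np.ndarray  # global signal at the same interpolated resolution

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.gbold = np.asarray(self.gbold, dtype=float)
        if self.data.shape[1] != self.gbold.shape[0]:
            raise ValueError("graph and gbold must share the time axis")

    @property
    def n_bins(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.interval


def time_position_graph(
    session: BoldSession,
    bins: np.ndarray,
    interp_factor: int = DEFAULT_INTERP_FACTOR,
) -> TimePositionGraph:
    """Interpolate parcel series and average them within PG position bins."""
    bins = np.asarray(bins, dtype=int)
    if bins.shape[0] != session.n_parcels:
        raise ValueError("one bin assignment per parcel required")
    fine, dt = interpolate_series(session.bold, session.tr, interp_factor)
    n_bins = int(bins.max()) + 1
    data = np.empty((n_bins, fine.shape[1]))
    for b in range(n_bins):
        data[b] = fine[bins == b].mean(axis=0)
    gbold_fine, _ = interpolate_series(session.gbold(), session.tr, interp_factor)
    return TimePositionGraph(data=data, interval=dt, gbold=gbold_fine)


@dataclass(frozen=True)
class Segment:
    """One inter-trough span of the global signal, with its internal gBOLD peak."""

    start: int  # frame index of the opening trough
    end: int  # frame index of the closing trough (inclusive)
    gbold_peak_index: int
    gbold_peak_time: float


def segment_by_troughs(
    graph: TimePositionGraph,
    prominence_sd: float = DEFAULT_TROUGH_PROMINENCE_SD,
) -> list[Segment]:
    """Cut the interpolated global signal at its troughs.

    Troughs are local minima with prominence of at least ``prominence_sd``
    standard deviations of the global signal. Consecutive troughs bound one
    segment each (so the segments tile the span between the first and last
    trough); fewer than two troughs yield no segments.
    """
    g = graph.gbold
    sd = g.std()
    if sd == 0:
        return []
    troughs, _ = sps.find_peaks(-g, prominence=prominence_sd * sd)
    segments = []
    for a, b in zip(troughs[:-1], troughs[1:]):
        peak = a + int(np.argmax(g[a : b + 1]))
        segments.append(
            Segment(start=int(a), end=int(b), gbold_peak_index=int(peak),
                    gbold_peak_time=float(peak * graph.interval))
        )
    return segments


@dataclass
class PropagationEvent:
    """Per-segment propagation measurement along the PG direction."""

    segment: Segment
    peak_timings: np.ndarray  # per bin, seconds relative to the gBOLD peak (NaN = no peak)
    n_bins_with_peak: int
    time_position_r: float
    direction: str  # bottom_up | top_down | none | invalid
    meta: dict = field(default_factory=dict)


def _bin_peak_timing(series: np.ndarray, seg: Segment, interval: float) -> float:
    """Highest strictly-interior local maximum of a bin series within a segment.

    Maxima at the segment edges do not count as peaks; a bin with no interior
    local maximum contributes NaN (no peak identified).
    """
    window = series[seg.start : seg.end + 1]
    peaks, _ = sps.find_peaks(window)
    if peaks.size == 0:
        return np.nan
    best = peaks[np.argmax(window[peaks])]
    return (seg.start + best - seg.gbold_peak_index) * interval


def detect_propagation(
    graph: TimePositionGraph,
    segment: Segment,
    threshold: float = DEFAULT_DIRECTION_THRESHOLD,
    min_bins: int = DEFAULT_MIN_BINS_WITH_PEAK,
) -> PropagationEvent:
    """Classify one segment as bottom-up, top-down, none, or invalid.

    The timing of each bin's local BOLD peak (relative to the segment's
    gBOLD peak) is Pearson-correlated with bin position along the PG.
    Segments whose peaks are identified in ``min_bins`` or fewer bins are
    invalid; otherwise the direction thresholds are strict (``r`` exactly at
    the threshold is classified as none).
    """
    if not (0 <= segment.start <= segment.end < graph.n_frames):
        raise ValueError("segment out of graph bounds")
    timings = np.array(
        [_bin_peak_timing(graph.data[b], segment, graph.interval) for b in range(graph.n_bins)]
    )
    has_peak = np.isfinite(timings)
    n_with = int(has_peak.sum())
    r = np.nan
    if n_with >= 2:
        t = timings[has_peak]
        pos = np.flatnonzero(has_peak).astype(float)
        if np.ptp(t) > 0:
            t_c = t - t.mean()
            p_c = pos - pos.mean()
            r = float(t_c @ p_c / np.sqrt((t_c @ t_c) * (p_c @ p_c)))
    if n_with <= min_bins:
        direction = "invalid"
    elif np.isfinite(r) and r > threshold:
        direction = "bottom_up"
    elif np.isfinite(r) and r < -threshold:
        direction = "top_down"
    else:
        direction = "none"
    return PropagationEvent(
        segment=segment,
        peak_timings=timings,
        n_bins_with_peak=n_with,
        time_position_r=r if np.isfinite(r) else (np.nan if n_with < 2 else 0.0),
        direction=direction,
    )


def detect_session_propagations(
    session: BoldSession,
    bins: np.ndarray,
    interp_factor: int = DEFAULT_INTERP_FACTOR,
    threshold: float = DEFAULT_DIRECTION_THRESHOLD,
    min_bins: int = DEFAULT_MIN_BINS_WITH_PEAK,
    prominence_sd: float = DEFAULT_TROUGH_PROMINENCE_SD,
) -> tuple[TimePositionGraph, list[PropagationEvent]]:
    """Convenience wrapper: graph construction, segmentation, and detection."""
    graph = time_position_graph(session, bins, interp_factor)
    segments = segment_by_troughs(graph, prominence_sd)
    return graph, [detect_propagation(graph, s, threshold, min_bins) for s in segments]


@dataclass
class MeanWavePattern:
    """gBOLD-peak-aligned mean time-position pattern over a set of events."""

    data: np.ndarray  # (n_bins, n_window_frames); empty when no event fit the window
    times: np.ndarray  # seconds relative to the gBOLD peak
    interval: float
    n_events: int
    n_skipped: int = 0

    @property
    def empty(self) -> bool:
        return self.n_events == 0


def average_propagations(
    events: Sequence[PropagationEvent],
    graph: TimePositionGraph,
    window: float = DEFAULT_WINDOW_S,
) -> MeanWavePattern:
    """Average event windows of ``window`` seconds centered on each gBOLD peak.

    The window spans [-window/2, +window/2] inclusive (21 frames at the
    default 0.6 s resolution); events whose window leaves the graph are
    skipped and counted in ``n_skipped``. Zero usable events yield an empty,
    flagged pattern.
    """
    half_frames = int(round(window / 2 / graph.interval))
    n_w = 2 * half_frames + 1
    times = (np.arange(n_w) - half_frames) * graph.interval
    stack = []
    skipped = 0
    for ev in events:
        c = ev.segment.gbold_peak_index
        if c - half_frames < 0 or c + half_frames >= graph.n_frames:
            skipped += 1
            continue
        stack.append(graph.data[:, c - half_frames : c + half_frames + 1])
    if not stack:
        return MeanWavePattern(
            data=np.empty((graph.n_bins, 0)), times=times, interval=graph.interval,
            n_events=0, n_skipped=skipped,
        )
    return MeanWavePattern(
        data=np.mean(stack, axis=0), times=times, interval=graph.interval,
        n_events=len(stack), n_skipped=skipped,
    )


def snapshot(pattern: MeanWavePattern, t: float) -> np.ndarray:
    """Per-bin values of a mean pattern at time ``t`` relative to the gBOLD peak."""
    if pattern.empty:
        raise ValueError("cannot take a snapshot of an empty pattern")
    idx = int(round((t - pattern.times[0]) / pattern.interval))
    if not 0 <= idx < pattern.times.size or not np.isclose(
        pattern.times[idx], t, atol=pattern.interval / 2
    ):
        raise ValueError(f"time {t} s outside the pattern window")
    return pattern.data[:, idx]


def compare_wave_groups(
    patterns_a: Sequence[MeanWavePattern] | np.ndarray,
    patterns_b: Sequence[MeanWavePattern] | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Element-wise two-sample t-test between two groups of mean patterns.

    Returns (t, p) maps with the A-minus-B sign convention and uncorrected
    two-sided p-values. Each group stacks one mean pattern per subject.
    """

    def as_stack(patterns):
        arrs = [p.data if isinstance(p, MeanWavePattern) else np.asarray(p) for p in patterns]
        return np.stack(arrs)

    a = as_stack(patterns_a)
    b = as_stack(patterns_b)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 subjects")
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("group patterns have mismatched shapes")
    res = ttest_ind(a, b, axis=0)
    return np.asarray(res.statistic), np.asarray(res.pvalue)
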