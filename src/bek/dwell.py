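"""Single-molecule dwell-time and visit statistics from intensity traces.

Works on frame-sampled traces: threshold to a binary presence record,
collect presence intervals (dwells), summarize their durations, count the
twinfilin visits that precede uncapping, invert the mean visit count into
a per-visit uncapping probability, and count photobleaching steps.

Durations are ``(end_frame - start_frame) * frame_interval`` with
half-open frame intervals; a single-frame event gets one frame interval
and a lower-bound flag, since the true dwell may be much shorter than the
frame.  No outlier trimming is applied anywhere: every detected event
enters the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .observe import ChannelTrace

__all__ = [
    "PresenceIntervals",
    "DwellSummary",
    "UncapVisitRecord",
    "binarize_trace",
    "intervals_from_binary",
    "auto_threshold",
    "dwell_summary",
    "visits_until_uncapping",
    "estimate_uncap_probability",
    "count_bleach_steps",
    "detect_depolymerization_onset",
]


@dataclass
class PresenceIntervals:
    """Disjoint, sorted half-open [start_frame, end_frame) presence runs."""

    filament_id: int
    intervals: list[tuple[int, int]]
    frame_interval: float
    single_frame_flags: list[bool]
    t0: float = 0.0

    def __post_init__(self) -> None:
        for (s, e) in self.intervals:
            if e <= s:
                raise ValueError("intervals must satisfy end_frame > start_frame")
        starts = [s for s, _ in self.intervals]
        ends = [e for _, e in self.intervals]
        if any(s2 < e1 for e1, s2 in zip(ends, starts[1:])):
            raise ValueError("intervals must be disjoint and sorted")

    def durations(self) -> np.ndarray:
        return np.array([(e - s) * self.frame_interval for s, e in self.intervals])

    def start_times(self) -> np.ndarray:
        return self.t0 + self.frame_interval * np.array([s for s, _ in self.intervals])


@dataclass
class DwellSummary:
    """Mean +/- sem of pooled dwell durations (no trimming)."""

    n_events: int
    mean: float
    sem: float
    durations: np.ndarray
    sem_defined: bool = True


@dataclass
class UncapVisitRecord:
    """Number of twinfilin visits observed up to (and including) uncapping."""

    filament_id: int
    n_visits: int
    t_uncap: float
    resolved: bool


def auto_threshold(values: np.ndarray) -> float:
    """Midpoint between baseline and single-fluorophore level.

    Estimated by a two-class split of the intensity histogram (Otsu's
    criterion): the threshold maximizing between-class variance, then the
    midpoint of the two class means.  Falls back to 0.5 for (near-)constant
    traces, which matches the unit-intensity rendering convention.
    """
    v = np.asarray(values, dtype=float)
    if np.ptp(v) < 1e-12:
        return 0.5
    hist, edges = np.histogram(v, bins=128)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = hist.astype(float)
    cw = np.cumsum(w)
    cm = np.cumsum(w * centers)
    total_w, total_m = cw[-1], cm[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = cm / cw
        mu1 = (total_m - cm) / (total_w - cw)
        between = cw * (total_w - cw) * (mu0 - mu1) ** 2
    between[~np.isfinite(between)] = -1.0
    i = int(np.argmax(between[:-1]))
    return float(0.5 * (mu0[i] + mu1[i]))


def intervals_from_binary(
    on: np.ndarray,
    frame_interval: float,
    filament_id: int = 0,
    min_frames: int = 1,
    gap_tolerance: int = 0,
    t0: float = 0.0,
) -> PresenceIntervals:
    """Presence intervals from a binary per-frame vector.

    On-runs separated by at most ``gap_tolerance`` off frames are merged;
    merged runs shorter than ``min_frames`` are discarded; single-frame
    intervals are flagged as lower bounds.
    """
    if min_frames < 1 or gap_tolerance < 0:
        raise ValueError("min_frames >= 1 and gap_tolerance >= 0 required")
    on = np.asarray(on).astype(bool)
    idx = np.flatnonzero(np.diff(np.concatenate(([0], on.view(np.int8), [0]))))
    runs = list(zip(idx[0::2], idx[1::2]))
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] <= gap_tolerance:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    kept = [(s, e) for s, e in merged if e - s >= min_frames]
    return PresenceIntervals(
        filament_id=filament_id,
        intervals=kept,
        frame_interval=frame_interval,
        single_frame_flags=[e - s == 1 for s, e in kept],
        t0=t0,
    )


def binarize_trace(
    trace: ChannelTrace,
    threshold: float | str = "auto",
    min_frames: int = 1,
    gap_tolerance: int = 0,
) -> PresenceIntervals:
    """Threshold a trace into presence intervals.

    Frames with ``value >= threshold`` are "on".  ``threshold="auto"``
    uses :func:`auto_threshold`.
    """
    if trace.n_frames == 0:
        raise ValueError("empty trace")
    if threshold == "auto":
        threshold = auto_threshold(trace.values)
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return intervals_from_binary(
        trace.values >= threshold,
        trace.frame_interval,
        filament_id=trace.filament_id,
        min_frames=min_frames,
        gap_tolerance=gap_tolerance,
        t0=trace.t0,
    )


def dwell_summary(intervals) -> DwellSummary:
    """Pool dwell durations and report mean +/- sem.

    ``intervals`` is a :class:`PresenceIntervals`, an iterable of them, or
    an iterable of durations in seconds.  All events are included (no
    outlier exclusion).  With a single event the sem is undefined and
    reported as 0 with ``sem_defined=False``.
    """
    if isinstance(intervals, PresenceIntervals):
        durations = intervals.durations()
    else:
        items = list(intervals)
        if items and isinstance(items[0], PresenceIntervals):
            parts = [p.durations() for p in items]
            durations = np.concatenate(parts) if parts else np.array([])
        else:
            durations = np.asarray(items, dtype=float)
    n = len(durations)
    if n == 0:
        raise ValueError("no dwell events")
    mean = float(np.mean(durations))
    if n >= 2:
        sem = float(np.std(durations, ddof=1) / np.sqrt(n))
        return DwellSummary(n_events=n, mean=mean, sem=sem, durations=durations)
    return DwellSummary(n_events=1, mean=mean, sem=0.0, durations=durations,
                        sem_defined=False)


def visits_until_uncapping(presence: PresenceIntervals, t_uncap: float | None) -> UncapVisitRecord:
    """Count twinfilin visits that started up to the uncapping time.

    The visit during which uncapping occurs is included.  ``t_uncap=None``
    (or NaN) marks an unresolved filament: all observed visits are
    reported with ``resolved=False``.
    """
    if t_uncap is None or not np.isfinite(t_uncap):
        return UncapVisitRecord(
            filament_id=presence.filament_id,
            n_visits=len(presence.intervals),
            t_uncap=float("nan"),
            resolved=False,
        )
    if t_uncap < presence.t0:
        raise ValueError("t_uncap precedes the start of the trace")
    n = int((presence.start_times() <= t_uncap).sum())
    return UncapVisitRecord(
        filament_id=presence.filament_id, n_visits=n, t_uncap=float(t_uncap),
        resolved=True,
    )


def estimate_uncap_probability(
    records: list[UncapVisitRecord],
    level: float = 0.65,
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[float, tuple[float, float]]:
    """Per-visit uncapping probability from visit counts.

    Independent visits with per-visit success probability p give a
    geometric number of visits until uncapping with mean 1/p, so
    ``p_hat = 1 / mean(n_visits)`` over resolved filaments.  The CI is a
    percentile bootstrap over filaments.
    """
    counts = np.array([r.n_visits for r in records if r.resolved], dtype=float)
    if len(counts) == 0 or counts.max() < 1:
        raise ValueError("need at least one resolved record with >= 1 visit")
    p_hat = 1.0 / counts.mean()
    rng = np.random.default_rng(seed)
    res = rng.choice(counts, size=(n_boot, len(counts)), replace=True).mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(1.0 / res, [alpha, 1.0 - alpha])
    return float(p_hat), (float(lo), float(hi))


def _best_split(x: np.ndarray) -> tuple[int, float]:
    """Index and SSE gain of the best single change point of x (len >= 2)."""
    n = len(x)
    cs = np.cumsum(x)
    cs2 = np.cumsum(x * x)
    total = cs2[-1] - cs[-1] ** 2 / n
    i = np.arange(1, n)
    left = cs2[i - 1] - cs[i - 1] ** 2 / i
    rs = cs[-1] - cs[i - 1]
    rs2 = cs2[-1] - cs2[i - 1]
    right = rs2 - rs ** 2 / (n - i)
    gains = total - (left + right)
    j = int(np.argmax(gains))
    return j + 1, float(gains[j])


def count_bleach_steps(trace: ChannelTrace, min_step: float,
                       smooth_frames: int = 5) -> int:
    """Number of irreversible downward intensity steps of size >= min_step.

    Greedy change-point analysis on the running mean: the trace is
    recursively split at the point giving the largest residual
    sum-of-squares reduction, accepting a split only while the SSE gain
    exceeds what a level change of ``min_step / 2`` would produce;
    adjacent segments whose mean levels differ by less than ``min_step``
    are then merged, and the remaining downward level changes are counted.
    Intended for monotone bleaching traces; a flat trace returns 0.
    """
    if trace.n_frames < 3:
        raise ValueError("trace too short for step counting")
    if min_step <= 0:
        raise ValueError("min_step must be positive")
    w = max(1, int(smooth_frames))
    x = np.convolve(trace.values, np.ones(w) / w, mode="valid")

    boundaries = [0, len(x)]

    def split(lo: int, hi: int) -> None:
        if hi - lo < 4:
            return
        j, gain = _best_split(x[lo:hi])
        seg_n = hi - lo
        # SSE gain of a true level change d at the segment midpoint is
        # ~ seg_n * d^2 / 4; require at least that for d = min_step / 2
        if gain < seg_n * (min_step / 2.0) ** 2 / 4.0:
            return
        boundaries.append(lo + j)
        split(lo, lo + j)
        split(lo + j, hi)

    split(0, len(x))
    bounds = sorted(set(boundaries))
    levels = [float(np.mean(x[a:b])) for a, b in zip(bounds[:-1], bounds[1:])]
    # merge neighbours closer than min_step
    merged = [levels[0]]
    for lv in levels[1:]:
        if abs(lv - merged[-1]) < min_step:
            merged[-1] = 0.5 * (merged[-1] + lv)
        else:
            merged.append(lv)
    return sum(1 for a, b in zip(merged, merged[1:]) if a - b >= min_step)


def detect_depolymerization_onset(
    length_trace: ChannelTrace, min_frames: int = 3, tol: float = 0.0
) -> float | None:
    """Time at which the length trace starts shrinking monotonically.

    Returns the time of the first frame followed by at least ``min_frames``
    consecutive decreases larger than ``tol``; ``None`` if no such run
    exists.  This is the operational proxy for CP loss when CP itself is
    unlabeled: a capped end cannot shrink, so sustained shortening marks
    uncapping-driven depolymerization.
    """
    if min_frames < 1:
        raise ValueError("min_frames must be >= 1")
    dec = np.diff(length_trace.values) < -tol
    run = 0
    for i, d in enumerate(dec):
        run = run + 1 if d else 0
        if run >= min_frames:
            start = i - min_frames + 1
            return float(length_trace.t0 + start * length_trace.frame_interval)
    return None
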