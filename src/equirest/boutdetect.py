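"""Lying-bout detection from leg-worn accelerometer traces.

A single-axis logger strapped to the metacarpal bone records acceleration
parallel to the vertical leg axis at 1 Hz.  While the horse stands the axis is
aligned with gravity and reads about −1 g; in sternal or lateral recumbency
the bone is horizontal and the reading sits near 0 g.  The detector converts a
raw trace into lying bouts in four stages:

1. threshold each sample at −0.75 g (lying above, standing at or below),
2. smooth the binary state series with a centred 31 s majority vote
   (a moving median of a binary series is exactly the majority state),
3. segment maximal lying runs into bouts and drop those shorter than 30 s,
4. remove bouts that fall into logged pasture-access intervals.

Timestamps are integer seconds; bouts use the half-open convention
``[start, end)`` so ``duration == end - start``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AccelTrace",
    "StateSeries",
    "LyingBout",
    "PastureInterval",
    "classify_samples",
    "smooth_states",
    "segment_bouts",
    "exclude_pasture",
    "detect_bouts",
    "read_trace_csv",
    "write_bouts_csv",
]

#: Acceleration threshold separating lying (above) from standing (at/below), in g.
LYING_THRESHOLD_G = -0.75

#: Minimum bout duration retained for analysis, seconds.
MIN_BOUT_DURATION_S = 30

#: Half-width of the majority-smoothing window, seconds.
SMOOTHING_HALF_WINDOW_S = 15

#: Traces with missing samples are split into segments at gaps longer than this.
MAX_FILLABLE_GAP_S = 5

LYING = 1
STANDING = 0


@dataclass(frozen=True)
class AccelTrace:
    """A per-horse 1 Hz acceleration series.

    ``timestamps`` are seconds (integers, strictly increasing); ``accel`` is
    the acceleration in g, one value per timestamp.  Nominal spacing is 1 s;
    gaps are tolerated and handled by :func:`detect_bouts`.
    """

    horse_id: str
    timestamps: np.ndarray
    accel: np.ndarray

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=np.int64)
        ac = np.asarray(self.accel, dtype=float)
        if ts.shape != ac.shape or ts.ndim != 1:
            raise ValueError("timestamps and accel must be 1-D arrays of equal length")
        if ts.size > 1 and np.any(np.diff(ts) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "accel", ac)

    def __len__(self) -> int:
        return self.timestamps.size


@dataclass(frozen=True)
class StateSeries:
    """Per-sample binary posture states aligned with a source trace."""

    timestamps: np.ndarray
    states: np.ndarray  # LYING (1) / STANDING (0)

    def __len__(self) -> int:
        return self.timestamps.size


@dataclass(frozen=True, order=True)
class LyingBout:
    """A detected recumbency interval, half-open ``[start, end)`` in seconds."""

    horse_id: str = field(compare=False)
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"bout end ({self.end}) must exceed start ({self.start})")

    @property
    def duration(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class PastureInterval:
    """A logged pasture-access interval; recumbency during access is discarded."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("pasture interval end must exceed start")


def classify_samples(trace: AccelTrace, threshold: float = LYING_THRESHOLD_G) -> StateSeries:
    """Threshold each sample: above ``threshold`` → lying, otherwise standing.

    Equality is assigned to standing — the conservative choice, since the two
    strict inequalities of the classification rule leave the boundary value
    undefined and assigning it to lying would inflate recumbency.

    Raises ``ValueError`` naming the first offending index if any sample is
    non-finite.  An empty trace yields an empty series.
    """
    accel = trace.accel
    bad = ~np.isfinite(accel)
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise ValueError(f"non-finite acceleration at index {idx} (t={trace.timestamps[idx]})")
    states = (accel > threshold).astype(np.int8)
    return StateSeries(trace.timestamps, states)


def smooth_states(
    raw: StateSeries,
    half_window: int = SMOOTHING_HALF_WINDOW_S,
    include_center: bool = True,
) -> StateSeries:
    """Majority-vote smoothing over a centred window of ±``half_window`` samples.

    Each output sample takes the majority state over the samples in the
    ``half_window`` seconds before and after it (plus itself when
    ``include_center``, the default — this makes the interior window odd and
    tie-free).  Windows are truncated at the edges of the series, with no
    padding; any tie falls back to the sample's own raw state.  The operation
    is idempotent on constant series.
    """
    n = len(raw)
    if n == 0:
        return raw
    x = raw.states.astype(np.int64)
    csum = np.concatenate(([0], np.cumsum(x)))
    idx = np.arange(n)
    lo = np.maximum(0, idx - half_window)
    hi = np.minimum(n, idx + half_window + 1)
    lying_counts = csum[hi] - csum[lo]
    window_sizes = hi - lo
    if not include_center:
        lying_counts = lying_counts - x
        window_sizes = window_sizes - 1
    out = np.where(
        2 * lying_counts > window_sizes,
        LYING,
        np.where(2 * lying_counts < window_sizes, STANDING, raw.states),
    ).astype(np.int8)
    return StateSeries(raw.timestamps, out)


def segment_bouts(
    states: StateSeries,
    horse_id: str = "",
    min_duration: int = MIN_BOUT_DURATION_S,
) -> list[LyingBout]:
    """Turn maximal lying runs into bouts, dropping runs shorter than ``min_duration``.

    At 1 Hz each sample covers one second, so a run of k consecutive lying
    samples is a candidate of duration k s (half-open: start at the first
    lying timestamp, end one second past the last).  A 29 s run is discarded;
    a 30 s run is retained.
    """
    s = states.states
    if s.size == 0:
        return []
    boundaries = np.flatnonzero(np.diff(s) != 0) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [s.size]))
    bouts = []
    for i0, i1 in zip(starts, ends):
        if s[i0] != LYING:
            continue
        start_t = int(states.timestamps[i0])
        end_t = int(states.timestamps[i1 - 1]) + 1
        if end_t - start_t >= min_duration:
            bouts.append(LyingBout(horse_id, start_t, end_t))
    return bouts


def _merge_intervals(pasture: list[PastureInterval]) -> list[PastureInterval]:
    if not pasture:
        return []
    ivs = sorted(pasture, key=lambda p: p.start)
    merged = [ivs[0]]
    overlapped = False
    for iv in ivs[1:]:
        last = merged[-1]
        if iv.start <= last.end:
            overlapped = True
            merged[-1] = PastureInterval(last.start, max(last.end, iv.end))
        else:
            merged.append(iv)
    if overlapped:
        warnings.warn("overlapping pasture intervals were merged", stacklevel=3)
    return merged


def exclude_pasture(bouts: list[LyingBout], pasture: list[PastureInterval]) -> list[LyingBout]:
    """Drop bouts whose midpoint lies inside any pasture-access interval.

    Recumbency on pasture is not analysed; the midpoint rule is a
    deterministic proxy for the manual removal of the handful of short
    pasture bouts.  Overlapping intervals are merged with a warning.
    """
    merged = _merge_intervals(pasture)
    if not merged:
        return list(bouts)
    kept = []
    for b in bouts:
        m = b.midpoint
        if any(iv.start <= m < iv.end for iv in merged):
            continue
        kept.append(b)
    return kept


def _split_segments(trace: AccelTrace, max_gap: int = MAX_FILLABLE_GAP_S) -> list[AccelTrace]:
    """Split a trace at gaps > ``max_gap`` s; fill smaller gaps by repeating
    the previous sample so each segment is uniform at 1 s spacing."""
    ts, ac = trace.timestamps, trace.accel
    if ts.size == 0:
        return []
    gaps = np.diff(ts)
    cut = np.flatnonzero(gaps > max_gap) + 1
    segments = []
    for lo, hi in zip(np.concatenate(([0], cut)), np.concatenate((cut, [ts.size]))):
        seg_ts, seg_ac = ts[lo:hi], ac[lo:hi]
        full_ts = np.arange(seg_ts[0], seg_ts[-1] + 1)
        if full_ts.size != seg_ts.size:  # short gaps: forward-fill
            idx = np.searchsorted(seg_ts, full_ts, side="right") - 1
            seg_ac = seg_ac[idx]
            seg_ts = full_ts
        segments.append(AccelTrace(trace.horse_id, seg_ts, seg_ac))
    return segments


def detect_bouts(
    trace: AccelTrace,
    pasture: list[PastureInterval] | None = None,
    threshold: float = LYING_THRESHOLD_G,
    half_window: int = SMOOTHING_HALF_WINDOW_S,
    min_duration: int = MIN_BOUT_DURATION_S,
    include_center: bool = True,
) -> list[LyingBout]:
    """Full detector: threshold → majority smoothing → segmentation → pasture filter.

    Traces with missing samples are split at gaps > 5 s and the pieces
    processed independently (gaps ≤ 5 s are forward-filled).
    """
    bouts: list[LyingBout] = []
    for seg in _split_segments(trace):
        raw = classify_samples(seg, threshold=threshold)
        smooth = smooth_states(raw, half_window=half_window, include_center=include_center)
        bouts.extend(segment_bouts(smooth, seg.horse_id, min_duration=min_duration))
    bouts.sort(key=lambda b: b.start)
    return exclude_pasture(bouts, pasture or [])


# ---------------------------------------------------------------------------
# CSV interfaces

_EPOCH = pd.Timestamp("2014-03-01 00:00:00")  # arbitrary origin for ISO output


def read_trace_csv(path, horse_id: str | None = None) -> AccelTrace:
    """Read a trace CSV in either the package dialect or an MSR-logger export.

    Package dialect: comma-separated, columns ``horse_id, timestamp_iso,
    accel_g``.  Logger dialect: semicolon-separated with a header row and one
    acceleration column (first column timestamps).
    """
    with open(path) as fh:
        first = fh.readline()
    sep = ";" if first.count(";") > first.count(",") else ","
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.strip().lower() for c in df.columns]
    acc_col = next(c for c in df.columns if "acc" in c)
    ts_col = next(c for c in df.columns if "time" in c or "stamp" in c)
    ts = pd.to_datetime(df[ts_col])
    seconds = ((ts - ts.iloc[0]).dt.total_seconds()).round().astype(np.int64)
    hid = horse_id or (str(df["horse_id"].iloc[0]) if "horse_id" in df.columns else "unknown")
    return AccelTrace(hid, seconds.to_numpy(), df[acc_col].to_numpy(dtype=float))


def write_bouts_csv(bouts: list[LyingBout], path, origin: pd.Timestamp = _EPOCH) -> None:
    """Write bouts as ``horse_id, start_iso, end_iso, duration_s``."""
    rows = [
        {
            "horse_id": b.horse_id,
            "start_iso": (origin + pd.Timedelta(seconds=b.start)).isoformat(),
            "end_iso": (origin + pd.Timedelta(seconds=b.end)).isoformat(),
            "duration_s": b.duration,
        }
        for b in bouts
    ]
    pd.DataFrame(rows, columns=["horse_id", "start_iso", "end_iso", "duration_s"]).to_csv(
        path, index=False
    )
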