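"""Mobility scores, bout segmentation, lickometer consumption events.

The behavioral rules implemented here:

* speed from tracked coordinates: two-point Euclidean distance over the
  time step, assigned to the interval's end time;
* mobility score: session-wise min-max scaling of speed into [0, 1];
* immobility bout: maximal run with mobility score strictly below 0.1
  lasting at least 2 s; mobility bouts are the complement, so the two
  classes tile the session;
* consumption event: lick contacts merged across gaps shorter than 1 s,
  kept if the merged event persists for at least 0.5 s.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import BehaviorTrack, BoutTable, DataError, EventSeries

__all__ = ["speed_from_coords", "mobility_score", "track_from_coords",
           "detect_bouts", "detect_consumption", "select_events",
           "read_state_csv", "read_coords_csv",
           "IMMOBILITY_THRESHOLD", "MIN_IMMOBILITY_S",
           "MIN_CONSUMPTION_S", "MAX_LICK_GAP_S"]

IMMOBILITY_THRESHOLD = 0.1
MIN_IMMOBILITY_S = 2.0
MIN_CONSUMPTION_S = 0.5
MAX_LICK_GAP_S = 1.0


def speed_from_coords(x, y, t) -> np.ndarray:
    """Two-point speed sqrt(dx^2 + dy^2)/dt, length n-1 (at interval ends)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    if not (len(x) == len(y) == len(t)):
        raise DataError("x, y, t must have equal lengths")
    if len(t) < 2:
        raise DataError("need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise DataError("timestamps must be strictly increasing (no repeats)")
    return np.hypot(np.diff(x), np.diff(y)) / dt


def mobility_score(speed, timestamp_s) -> BehaviorTrack:
    """Min-max scale speed to [0, 1] over the session.

    A constant-speed session cannot be scaled; it maps to all zeros and the
    returned track is flagged ``degenerate``.
    """
    v = np.asarray(speed, dtype=float)
    t = np.asarray(timestamp_s, dtype=float)
    if len(v) < 2:
        raise DataError("need at least 2 speed samples")
    span = v.max() - v.min()
    if span <= 0:
        return BehaviorTrack(t, np.zeros_like(v), raw_speed=v, degenerate=True)
    return BehaviorTrack(t, (v - v.min()) / span, raw_speed=v)


def track_from_coords(x, y, t) -> BehaviorTrack:
    """Coordinates straight to a mobility track (speed at interval ends)."""
    v = speed_from_coords(x, y, t)
    return mobility_score(v, np.asarray(t, dtype=float)[1:])


def detect_bouts(track: BehaviorTrack,
                 immobility_thresh: float = IMMOBILITY_THRESHOLD,
                 min_immobile_s: float = MIN_IMMOBILITY_S) -> BoutTable:
    """Segment a mobility track into immobility and mobility bouts.

    A sample belongs to a candidate immobility run iff its score is
    strictly below ``immobility_thresh`` (a score exactly at the threshold
    counts as mobile). Runs lasting at least ``min_immobile_s`` become
    immobility bouts; everything else is mobility. The returned bouts tile
    [t0, tN] exactly.
    """
    t = track.timestamp_s
    below = track.mobility < immobility_thresh
    edges = np.flatnonzero(np.diff(below.astype(np.int8)))
    starts = np.concatenate(([0], edges + 1))
    ends = np.concatenate((edges, [len(below) - 1]))  # inclusive sample runs

    immobility: list[tuple[float, float]] = []
    for i0, i1 in zip(starts, ends):
        if not below[i0]:
            continue
        t0 = t[i0]
        t1 = t[i1 + 1] if i1 + 1 < len(t) else t[-1]
        if t1 - t0 >= min_immobile_s:
            immobility.append((t0, t1))

    intervals, labels = [], []
    cursor = t[0]
    for t0, t1 in immobility:
        if t0 > cursor:
            intervals.append((cursor, t0))
            labels.append("mobility")
        intervals.append((t0, t1))
        labels.append("immobility")
        cursor = t1
    if cursor < t[-1]:
        intervals.append((cursor, t[-1]))
        labels.append("mobility")
    return BoutTable(np.array(intervals).reshape(-1, 2),
                     np.array(labels, dtype=object))


def detect_consumption(licks: EventSeries,
                       min_event_s: float = MIN_CONSUMPTION_S,
                       max_gap_s: float = MAX_LICK_GAP_S) -> EventSeries:
    """Merge lick contacts into consumption events.

    Contacts separated by gaps strictly shorter than ``max_gap_s`` are
    merged (a gap of at least ``max_gap_s`` ends the event); merged events
    shorter than ``min_event_s`` are discarded (an event lasting exactly
    ``min_event_s`` is kept).
    """
    if not licks.is_intervals:
        raise DataError("detect_consumption expects contact intervals")
    iv = licks.intervals[np.argsort(licks.intervals[:, 0])]
    if len(iv) == 0:
        return EventSeries("consumption", intervals=np.empty((0, 2)))
    if np.any(iv[1:, 0] < iv[:-1, 1]):
        raise DataError("lick contacts overlap")
    merged = [[iv[0, 0], iv[0, 1]]]
    for s, e in iv[1:]:
        if s - merged[-1][1] < max_gap_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    kept = [(s, e) for s, e in merged if e - s >= min_event_s]
    return EventSeries("consumption", intervals=np.array(kept).reshape(-1, 2))


EVENT_KINDS = ("mobility_onset", "immobility_onset",
               "random_mobility", "random_immobility")


def select_events(bouts: BoutTable, kinds=EVENT_KINDS, n_random: int = 20,
                  window_s: float = 6.0, seed: int = 0) -> dict[str, EventSeries]:
    """Pick the four peri-event correlation event kinds from a bout table.

    Onset kinds are bout start times; random kinds are drawn uniformly
    within bouts of the matching label. Every returned event keeps at
    least ``window_s / 2`` clearance from bout edges and session edges so
    peri-event traces are complete; a kind with no eligible bout returns an
    empty series with a warning.
    """
    half = window_s / 2.0
    session_lo = bouts.intervals[0, 0]
    session_hi = bouts.intervals[-1, 1]
    rng = np.random.default_rng(seed)
    out: dict[str, EventSeries] = {}
    for kind in kinds:
        label = "mobility" if "mobility" in kind and "immobility" not in kind \
            else "immobility"
        if kind.endswith("_onset"):
            times = bouts.onsets(label)
            times = times[(times - half >= session_lo) & (times + half <= session_hi)]
        else:
            segs = [(max(s + half, session_lo + half), min(e - half, session_hi - half))
                    for s, e in bouts.select(label)]
            segs = [(a, b) for a, b in segs if b > a]
            if not segs:
                warnings.warn(f"no eligible bout for event kind {kind!r}")
                out[kind] = EventSeries(kind, times_s=np.empty(0))
                continue
            lengths = np.array([b - a for a, b in segs])
            picks = rng.choice(len(segs), size=n_random, p=lengths / lengths.sum())
            times = np.sort(np.array(
                [rng.uniform(*segs[i]) for i in picks]))
        if len(times) == 0:
            warnings.warn(f"no eligible events for kind {kind!r}")
        out[kind] = EventSeries(kind, times_s=np.sort(times))
    return out


# ---------------------------------------------------------------------------
# CSV readers for tracking-system exports


def read_state_csv(source, time_col: str = "Time",
                   state_col: str = "State", label: str | None = None) -> EventSeries:
    """Read a timestamp+state export (lick/laser logs) into ON intervals.

    The state column is binarized (nonzero = ON); contiguous ON runs become
    intervals, a trailing ON run closes at the last timestamp.
    """
    df = pd.read_csv(source)
    for col in (time_col, state_col):
        if col not in df.columns:
            raise DataError(f"missing column {col!r}")
    t = df[time_col].to_numpy(float)
    on = df[state_col].to_numpy(float) != 0
    intervals = []
    start = None
    for ti, flag in zip(t, on):
        if flag and start is None:
            start = ti
        elif not flag and start is not None:
            intervals.append((start, ti))
            start = None
    if start is not None and t[-1] > start:
        intervals.append((start, t[-1]))
    return EventSeries(label or state_col.lower(),
                       intervals=np.array(intervals).reshape(-1, 2))


def read_coords_csv(source, x_col: str = "x", y_col: str = "y",
                    time_col: str = "t"):
    """Read a pose-estimation coordinate export (x, y, optional likelihood).

    Returns ``(x, y, t)`` arrays; a ``likelihood`` column, if present, is
    ignored by default.
    """
    df = pd.read_csv(source)
    for col in (x_col, y_col, time_col):
        if col not in df.columns:
            raise DataError(f"missing column {col!r}")
    return (df[x_col].to_numpy(float), df[y_col].to_numpy(float),
            df[time_col].to_numpy(float))
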