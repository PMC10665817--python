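"""Core in-memory containers for photometry and behavior sessions.

The containers are thin, validated dataclasses around numpy arrays. They
carry the minimum metadata the analysis needs (timestamps, labels, nominal
rates) and validate their own invariants on construction so that downstream
code can assume well-formed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DataError",
    "FormatError",
    "AlignmentError",
    "InterleavedRecording",
    "PhotometryTrace",
    "BehaviorTrack",
    "EventSeries",
    "BoutTable",
    "PeriEventMatrix",
]


class DataError(ValueError):
    """Raised when input data violates a structural invariant."""


class FormatError(ValueError):
    """Raised when a file does not conform to the expected dialect."""


class AlignmentError(ValueError):
    """Raised when two series have no overlapping time support."""


def _as_1d_float(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise DataError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class InterleavedRecording:
    """Raw multi-LED camera frames before deinterleaving.

    Each frame carries an integer LED-state code identifying which
    excitation LED was on when the frame was captured; ``values`` holds one
    fluorescence column per fiber/ROI in raw camera units.
    """

    frame_index: np.ndarray
    timestamp_s: np.ndarray
    led_state: np.ndarray
    values: dict[str, np.ndarray]
    channel_map: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=np.int64)
        self.timestamp_s = _as_1d_float(self.timestamp_s, "timestamp_s")
        self.led_state = np.asarray(self.led_state, dtype=np.int64)
        n = len(self.frame_index)
        if not (len(self.timestamp_s) == len(self.led_state) == n):
            raise DataError("frame_index, timestamp_s and led_state lengths differ")
        for roi, col in self.values.items():
            self.values[roi] = col = _as_1d_float(col, f"values[{roi}]")
            if len(col) != n:
                raise DataError(f"ROI column {roi!r} length {len(col)} != {n} frames")
        dt = np.diff(self.timestamp_s)
        bad = np.nonzero(dt <= 0)[0]
        if bad.size:
            raise DataError(
                f"timestamps not strictly increasing at row {int(bad[0]) + 1}"
            )
        if self.channel_map:
            unknown = set(np.unique(self.led_state)) - set(self.channel_map)
            if unknown:
                raise DataError(f"unknown LED-state codes {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.frame_index)


@dataclass
class PhotometryTrace:
    """One channel's uniformly sampled fluorescence series.

    ``value`` is in raw camera units before correction, or dimensionless
    zdF/F after. The nominal rate is the per-channel rate (camera rate
    divided by the number of interleaved LEDs).
    """

    timestamp_s: np.ndarray
    value: np.ndarray
    channel_label: str = ""
    roi_label: str = ""
    nominal_rate_hz: float = 0.0

    def __post_init__(self) -> None:
        self.timestamp_s = _as_1d_float(self.timestamp_s, "timestamp_s")
        self.value = _as_1d_float(self.value, "value")
        if len(self.timestamp_s) != len(self.value):
            raise DataError("timestamp_s and value lengths differ")
        if len(self.value) < 2:
            raise DataError("trace needs at least 2 samples")
        if np.any(np.diff(self.timestamp_s) <= 0):
            raise DataError("trace timestamps not strictly increasing")
        if self.nominal_rate_hz:
            med = float(np.median(np.diff(self.timestamp_s)))
            if abs(med - 1.0 / self.nominal_rate_hz) > 0.2 / self.nominal_rate_hz:
                raise DataError(
                    "median sampling interval inconsistent with nominal_rate_hz"
                )

    def __len__(self) -> int:
        return len(self.value)

    def with_values(self, value: np.ndarray) -> "PhotometryTrace":
        """Copy of this trace with the same grid and metadata, new values."""
        return PhotometryTrace(
            self.timestamp_s.copy(),
            np.asarray(value, dtype=float),
            self.channel_label,
            self.roi_label,
            self.nominal_rate_hz,
        )


@dataclass
class BehaviorTrack:
    """Mobility score in [0, 1] over time, optionally with raw speed."""

    timestamp_s: np.ndarray
    mobility: np.ndarray
    raw_speed: np.ndarray | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.timestamp_s = _as_1d_float(self.timestamp_s, "timestamp_s")
        self.mobility = _as_1d_float(self.mobility, "mobility")
        if len(self.timestamp_s) != len(self.mobility):
            raise DataError("timestamp_s and mobility lengths differ")
        if np.any(np.diff(self.timestamp_s) <= 0):
            raise DataError("track timestamps not strictly increasing")
        if np.any((self.mobility < -1e-12) | (self.mobility > 1 + 1e-12)):
            raise DataError("mobility score outside [0, 1]")
        if self.raw_speed is not None:
            self.raw_speed = _as_1d_float(self.raw_speed, "raw_speed")

    def __len__(self) -> int:
        return len(self.mobility)


@dataclass
class EventSeries:
    """Labeled point events (times) or intervals (start/end pairs)."""

    label: str
    times_s: np.ndarray | None = None
    intervals: np.ndarray | None = None  # shape (n, 2)

    def __post_init__(self) -> None:
        if (self.times_s is None) == (self.intervals is None):
            raise DataError("EventSeries needs exactly one of times_s or intervals")
        if self.times_s is not None:
            self.times_s = _as_1d_float(self.times_s, "times_s")
            if np.any(np.diff(self.times_s) < 0):
                raise DataError("event times not sorted")
        else:
            iv = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
            if iv.size and np.any(iv[:, 1] <= iv[:, 0]):
                raise DataError("interval end must exceed start")
            if iv.shape[0] > 1 and np.any(np.diff(iv[:, 0]) < 0):
                raise DataError("intervals not sorted by start")
            self.intervals = iv

    @property
    def is_intervals(self) -> bool:
        return self.intervals is not None

    def __len__(self) -> int:
        return len(self.intervals) if self.is_intervals else len(self.times_s)

    def onsets(self) -> np.ndarray:
        """Event start times (the times themselves for point events)."""
        return self.intervals[:, 0] if self.is_intervals else self.times_s


@dataclass
class BoutTable:
    """Non-overlapping labeled intervals tiling a session."""

    intervals: np.ndarray  # (n, 2)
    labels: np.ndarray  # (n,), 'mobility' | 'immobility'

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.intervals) != len(self.labels):
            raise DataError("intervals and labels lengths differ")
        if self.intervals.size:
            if np.any(self.intervals[:, 1] <= self.intervals[:, 0]):
                raise DataError("bout end must exceed start")
            if np.any(self.intervals[1:, 0] < self.intervals[:-1, 1] - 1e-9):
                raise DataError("bouts overlap")

    def __len__(self) -> int:
        return len(self.labels)

    def select(self, label: str) -> np.ndarray:
        return self.intervals[self.labels == label]

    def onsets(self, label: str) -> np.ndarray:
        """Start times of bouts with the given label."""
        return self.select(label)[:, 0]


@dataclass
class PeriEventMatrix:
    """Trials x time matrix of a trace aligned to events on a common grid."""

    rel_time_s: np.ndarray
    values: np.ndarray  # (n_trials, n_time)
    event_times_s: np.ndarray
    source_label: str = ""
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.rel_time_s = _as_1d_float(self.rel_time_s, "rel_time_s")
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.event_times_s = _as_1d_float(self.event_times_s, "event_times_s")
        if self.values.shape[1] != len(self.rel_time_s):
            raise DataError("values column count != grid length")
        if self.values.shape[0] != len(self.event_times_s):
            raise DataError("values row count != number of events")
        steps = np.diff(self.rel_time_s)
        if steps.size and not np.allclose(steps, steps[0], rtol=1e-6):
            raise DataError("relative-time grid not uniform")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]
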