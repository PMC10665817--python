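"""Peri-event alignment, trial averaging and windowed normalized AUC.

Traces are aligned to event times on a common relative-time grid by linear
interpolation; trials whose window is not fully covered by the recording
are dropped (never padded) and counted. The per-test AUC windows are the
fixed analysis windows of each behavioral test; the AUC is a trapezoidal
integral normalized by window duration, AUCnorm = AUC / (t1 - t0), so a
constant trace has AUCnorm equal to that constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import BehaviorTrack, DataError, PeriEventMatrix, PhotometryTrace

__all__ = ["WindowSpec", "window_table", "extract", "trial_mean", "auc"]


@dataclass
class WindowSpec:
    """Named (t0, t1) analysis windows, in seconds relative to the event."""

    test_name: str
    named_windows: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (t0, t1) in self.named_windows.items():
            if not t1 > t0:
                raise DataError(f"window {name!r}: t1 must exceed t0")


_WINDOW_TABLES: dict[str, dict[str, tuple[float, float]]] = {
    "airpuff": {"baseline": (-2.0, -1.0), "airpuff": (0.0, 1.5)},
    "consumption": {"baseline": (-2.0, -1.0), "onset": (-0.5, 1.0),
                    "drinking": (2.0, 4.0)},
    "mobility": {"immobile": (-3.0, -1.0), "pre-onset": (-1.0, 0.0),
                 "onset": (0.0, 1.0), "mobility": (1.0, 3.0)},
    "avoidance": {"baseline": (-2.0, -1.0), "CS": (0.0, 8.0),
                  "crossed": (8.0, 11.0)},
}


def window_table(test_name: str) -> WindowSpec:
    """The fixed AUC windows for one of the four behavioral tests."""
    if test_name not in _WINDOW_TABLES:
        raise KeyError(
            f"unknown test {test_name!r}; known: {sorted(_WINDOW_TABLES)}")
    return WindowSpec(test_name, dict(_WINDOW_TABLES[test_name]))


def extract(trace, event_times, pre_s: float = 5.0, post_s: float = 5.0,
            grid_rate_hz: float | None = None) -> PeriEventMatrix:
    """Align a trace (or behavior track) to events on a common grid.

    Each retained trial is interpolated onto ``rel_time_s`` in
    [-pre_s, +post_s]; trials extending beyond the recording are dropped
    and counted in ``n_dropped``.
    """
    if isinstance(trace, PhotometryTrace):
        t, v, label = trace.timestamp_s, trace.value, trace.channel_label
        rate = trace.nominal_rate_hz or None
    elif isinstance(trace, BehaviorTrack):
        t, v, label = trace.timestamp_s, trace.mobility, "mobility"
        rate = None
    else:
        t, v = np.asarray(trace[0], float), np.asarray(trace[1], float)
        label, rate = "", None
    events = np.sort(np.asarray(event_times, dtype=float).ravel())
    if grid_rate_hz is None:
        grid_rate_hz = rate or 1.0 / float(np.median(np.diff(t)))
    n_pre = int(round(pre_s * grid_rate_hz))
    n_post = int(round(post_s * grid_rate_hz))
    rel = np.arange(-n_pre, n_post + 1) / grid_rate_hz

    rows, kept = [], []
    for ev in events:
        if ev - pre_s < t[0] or ev + post_s > t[-1]:
            continue
        rows.append(np.interp(ev + rel, t, v))
        kept.append(ev)
    if not rows:
        raise DataError("no event has full peri-event coverage")
    return PeriEventMatrix(rel, np.vstack(rows), np.array(kept),
                           source_label=label,
                           n_dropped=len(events) - len(kept))


def trial_mean(matrix: PeriEventMatrix):
    """Pointwise mean and SEM across trials; returns ``(mean, sem, n)``.

    SEM uses the population standard deviation (sd/sqrt(n) with ddof=0),
    so two trials at +1/-1 give sem = 1/sqrt(2). With a single trial the
    SEM is reported as zeros (no spread to estimate); callers can detect
    this via ``n == 1``.
    """
    n = matrix.n_trials
    mean = matrix.values.mean(axis=0)
    if n == 1:
        return mean, np.zeros_like(mean), 1
    sem = matrix.values.std(axis=0, ddof=0) / np.sqrt(n)
    return mean, sem, n


def auc(matrix_or_curve, window: tuple[float, float],
        rel_time_s: np.ndarray | None = None):
    """Duration-normalized trapezoidal AUC over a relative-time window.

    For a :class:`PeriEventMatrix` returns ``(per_trial, mean)``; for a
    bare curve (with ``rel_time_s`` supplied) returns a scalar. The window
    endpoints are included exactly: values at t0 and t1 are obtained by
    linear interpolation if they fall between grid points.
    """
    t0, t1 = window
    if not t1 > t0:
        raise DataError("window end must exceed start")
    if isinstance(matrix_or_curve, PeriEventMatrix):
        grid = matrix_or_curve.rel_time_s
        values = matrix_or_curve.values
    else:
        if rel_time_s is None:
            raise DataError("rel_time_s required for a bare curve")
        grid = np.asarray(rel_time_s, dtype=float)
        values = np.atleast_2d(np.asarray(matrix_or_curve, dtype=float))
    if t0 < grid[0] - 1e-9 or t1 > grid[-1] + 1e-9:
        raise DataError(
            f"window ({t0}, {t1}) outside grid [{grid[0]}, {grid[-1]}]")

    inside = (grid > t0) & (grid < t1)
    sub_t = np.concatenate(([t0], grid[inside], [t1]))
    out = np.empty(values.shape[0])
    for i, row in enumerate(values):
        sub_v = np.concatenate(([np.interp(t0, grid, row)], row[inside],
                                [np.interp(t1, grid, row)]))
        out[i] = np.trapezoid(sub_v, sub_t) / (t1 - t0)
    if isinstance(matrix_or_curve, PeriEventMatrix):
        return out, float(out.mean())
    return float(out[0]) if out.shape[0] == 1 else out
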