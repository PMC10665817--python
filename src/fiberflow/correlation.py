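"""Correlation between calcium activity and mobility.

Three analyses: whole-session Pearson correlation (traces interpolated to
a common rate), peri-event correlation classification (events whose 6-s
windowed correlation satisfies p < 0.001 and r > 0.6 are *positive*,
p < 0.001 and r < -0.6 *negative*, anything else *uncorrelated*), and
cross-correlation lag-of-maximum estimation around events.

Sign convention for lags: the calcium trace is evaluated at ``t + lag``
against mobility at ``t``, so a negative ``lag_at_max`` means the calcium
signal *leads* the mobility change.

p-values come from the standard t-distribution Pearson test. Peri-event
samples are autocorrelated, so these p-values are anticonservative for
slow signals; the thresholds are configurable for that reason.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datatypes import BehaviorTrack, DataError, PhotometryTrace

__all__ = ["CorrelationResult", "EventClassCounts", "LagResult",
           "session_pearson", "classify_events", "crosscorr_lag"]


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    degenerate: bool = False


@dataclass
class EventClassCounts:
    """Counts and fractions of positive/negative/uncorrelated events."""

    n_positive: int
    n_negative: int
    n_uncorrelated: int
    n_excluded: int = 0
    per_event: list = field(default_factory=list)  # (time, r, p, label)

    @property
    def n_total(self) -> int:
        return self.n_positive + self.n_negative + self.n_uncorrelated

    @property
    def fractions(self) -> dict[str, float]:
        tot = self.n_total
        if tot == 0:
            return {"positive": 0.0, "negative": 0.0, "uncorrelated": 0.0}
        return {"positive": self.n_positive / tot,
                "negative": self.n_negative / tot,
                "uncorrelated": self.n_uncorrelated / tot}


@dataclass
class LagResult:
    lags_s: np.ndarray
    corr_vs_lag: np.ndarray  # (n_events, n_lags)
    lag_at_max_s: np.ndarray  # (n_events,)
    event_times_s: np.ndarray
    n_excluded: int = 0

    @property
    def mean_lag_s(self) -> float:
        return float(np.mean(self.lag_at_max_s))

    @property
    def sem_lag_s(self) -> float:
        n = len(self.lag_at_max_s)
        if n < 2:
            return 0.0
        return float(np.std(self.lag_at_max_s, ddof=1) / np.sqrt(n))

    @property
    def mean_curve(self) -> np.ndarray:
        """Mean correlation-vs-lag curve across events."""
        return self.corr_vs_lag.mean(axis=0)


def _series(obj):
    """(timestamps, values, rate) from a trace, track or (t, v) pair."""
    if isinstance(obj, PhotometryTrace):
        t, v = obj.timestamp_s, obj.value
        rate = obj.nominal_rate_hz or None
    elif isinstance(obj, BehaviorTrack):
        t, v = obj.timestamp_s, obj.mobility
        rate = None
    else:
        t = np.asarray(obj[0], dtype=float)
        v = np.asarray(obj[1], dtype=float)
        rate = None
    if rate is None:
        rate = 1.0 / float(np.median(np.diff(t)))
    return t, v, rate


def _pearson(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(np.nan, np.nan, len(x), degenerate=True)
    res = stats.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), len(x))


def session_pearson(calcium, mobility) -> CorrelationResult:
    """Whole-session Pearson between calcium signal and mobility score.

    Both series are linearly interpolated onto the slower one's rate over
    their common time support before correlating.
    """
    tc, vc, rc = _series(calcium)
    tm, vm, rm = _series(mobility)
    lo, hi = max(tc[0], tm[0]), min(tc[-1], tm[-1])
    if hi <= lo:
        raise DataError("no overlapping time support")
    rate = min(rc, rm)
    grid = np.arange(lo, hi + 0.5 / rate, 1.0 / rate)
    grid = grid[grid <= hi]
    if len(grid) < 3:
        raise DataError("fewer than 3 common samples")
    return _pearson(np.interp(grid, tc, vc), np.interp(grid, tm, vm))


def classify_events(calcium, mobility, events, window_s: float = 6.0,
                    r_pos: float = 0.6, r_neg: float = -0.6,
                    p_thresh: float = 0.001) -> EventClassCounts:
    """Classify peri-event windows as positive/negative/uncorrelated.

    For each event the two traces are resampled onto a common grid over the
    window centered on the event (event - window_s/2 to event + window_s/2)
    and the Pearson r and p computed. Events without full window coverage
    are excluded and counted.
    """
    tc, vc, rc = _series(calcium)
    tm, vm, rm = _series(mobility)
    times = np.asarray(getattr(events, "times_s", events), dtype=float).ravel()
    rate = min(rc, rm)
    half = window_s / 2.0
    rel = np.arange(-int(round(half * rate)), int(round(half * rate)) + 1) / rate

    n_pos = n_neg = n_unc = n_exc = 0
    per_event = []
    for ev in times:
        if (ev - half < max(tc[0], tm[0])) or (ev + half > min(tc[-1], tm[-1])):
            n_exc += 1
            continue
        x = np.interp(ev + rel, tc, vc)
        y = np.interp(ev + rel, tm, vm)
        res = _pearson(x, y)
        if res.degenerate:
            label = "uncorrelated"
            n_unc += 1
        elif res.p < p_thresh and res.r > r_pos:
            label = "positive"
            n_pos += 1
        elif res.p < p_thresh and res.r < r_neg:
            label = "negative"
            n_neg += 1
        else:
            label = "uncorrelated"
            n_unc += 1
        per_event.append((float(ev), res.r, res.p, label))
    if n_exc:
        warnings.warn(f"{n_exc} event(s) excluded for incomplete window coverage")
    return EventClassCounts(n_pos, n_neg, n_unc, n_exc, per_event)


def crosscorr_lag(calcium, mobility, events, window_s: float = 6.0,
                  max_lag_s: float = 2.0,
                  lag_step_s: float | None = None) -> LagResult:
    """Windowed correlation-vs-lag curves and the per-event lag of maximum.

    For each event and each lag in ``[-max_lag_s, +max_lag_s]`` the calcium
    trace shifted by the lag is correlated with mobility over the centered
    event window. Exact ties in the maximum are broken toward the smallest
    absolute lag. Events lacking window + lag coverage are excluded.
    """
    tc, vc, rc = _series(calcium)
    tm, vm, rm = _series(mobility)
    times = np.asarray(getattr(events, "times_s", events), dtype=float).ravel()
    rate = min(rc, rm)
    if lag_step_s is None:
        lag_step_s = 1.0 / rate
    n_lag = int(round(max_lag_s / lag_step_s))
    lags = np.arange(-n_lag, n_lag + 1) * lag_step_s
    half = window_s / 2.0
    rel = np.arange(-int(round(half * rate)), int(round(half * rate)) + 1) / rate

    curves, kept = [], []
    n_exc = 0
    for ev in times:
        if (ev - half - max_lag_s < tc[0] or ev + half + max_lag_s > tc[-1]
                or ev - half < tm[0] or ev + half > tm[-1]):
            n_exc += 1
            continue
        y = np.interp(ev + rel, tm, vm)
        row = np.empty(len(lags))
        for j, lag in enumerate(lags):
            x = np.interp(ev + rel + lag, tc, vc)
            if np.std(x) == 0 or np.std(y) == 0:
                row[j] = 0.0
            else:
                row[j] = float(np.corrcoef(x, y)[0, 1])
        curves.append(row)
        kept.append(ev)
    if n_exc:
        warnings.warn(f"{n_exc} event(s) excluded for incomplete lag coverage")
    if not curves:
        raise DataError("no event has full window + lag coverage")
    corr = np.vstack(curves)

    # lag of maximum; exact ties resolved toward the smallest |lag|
    order = np.argsort(np.abs(lags), kind="stable")
    lag_at_max = np.empty(corr.shape[0])
    for i, row in enumerate(corr):
        best = row.max()
        for j in order:
            if row[j] >= best - 1e-12:
                lag_at_max[i] = lags[j]
                break
    return LagResult(lags, corr, lag_at_max, np.array(kept), n_exc)
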