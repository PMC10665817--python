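"""Optogenetics behavioral readouts.

Real-time place preference (RTPP) score, per-laser-condition mobility and
bout metrics over an alternating epoch schedule, and sucrose-consumption
metrics normalized to no-stimulation baseline sessions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .behavior import detect_bouts
from .datatypes import BehaviorTrack, BoutTable, DataError, EventSeries
from .synth import ParameterError

__all__ = ["EpochSchedule", "ConsumptionMetrics", "preference_score",
           "epoch_metrics", "consumption_metrics", "normalize_to_baseline"]


@dataclass
class EpochSchedule:
    """Laser ON/OFF epochs tiling a session."""

    epochs: list[tuple[float, float, bool]]  # (start_s, end_s, laser_on)
    session_len_s: float

    def __post_init__(self) -> None:
        cursor = 0.0
        for start, end, _ in self.epochs:
            if not math.isclose(start, cursor, abs_tol=1e-9):
                raise DataError("epochs must tile the session without gaps")
            if end <= start:
                raise DataError("epoch end must exceed start")
            cursor = end
        if not math.isclose(cursor, self.session_len_s, abs_tol=1e-9):
            raise DataError("epochs do not cover the full session")

    @classmethod
    def alternating(cls, session_len_s: float, epoch_len_s: float,
                    first_on: bool = False) -> "EpochSchedule":
        """Alternating fixed-length epochs (OFF first by default)."""
        epochs = []
        t, on = 0.0, first_on
        while t < session_len_s - 1e-9:
            end = min(t + epoch_len_s, session_len_s)
            epochs.append((t, end, on))
            t, on = end, not on
        return cls(epochs, session_len_s)

    def condition_of(self, t: float) -> bool:
        for start, end, on in self.epochs:
            if start <= t < end:
                return on
        return self.epochs[-1][2]

    def n_epochs(self, laser_on: bool) -> int:
        return sum(1 for *_, on in self.epochs if on == laser_on)


@dataclass
class ConsumptionMetrics:
    mean_event_dur_s: float
    mean_inter_event_interval_s: float
    n_events: int
    total_dur_s: float
    interval_defined: bool = True


def preference_score(occupancy: EventSeries, session_len_s: float) -> float:
    """RTPP preference: (time laser ON - time laser OFF) / total time.

    ``occupancy`` holds the laser-paired-chamber intervals; everything not
    spent there counts as OFF, reproducing the printed formula exactly.
    """
    if session_len_s <= 0:
        raise ParameterError("session_len_s must be > 0")
    if not occupancy.is_intervals:
        raise DataError("occupancy must be an interval series")
    iv = occupancy.intervals
    if iv.size and (iv.min() < -1e-9 or iv.max() > session_len_s + 1e-9):
        raise DataError("occupancy intervals exceed session bounds")
    t_on = float(np.sum(iv[:, 1] - iv[:, 0])) if iv.size else 0.0
    t_off = session_len_s - t_on
    return (t_on - t_off) / session_len_s


def epoch_metrics(track: BehaviorTrack, schedule: EpochSchedule,
                  bout_params: dict | None = None) -> dict[bool, dict]:
    """Mobility/bout metrics per laser condition.

    Bouts are detected on the whole session and attributed to ON/OFF by
    their onset time (bouts straddling an epoch boundary are not split).
    Returns ``{laser_on: {mean_mobility, bout_vigor, mean_bout_dur_s,
    n_bouts}}``.
    """
    bout_params = bout_params or {}
    bouts = detect_bouts(track, **bout_params)
    out: dict[bool, dict] = {}
    for on in (False, True):
        sel = np.array([schedule.condition_of(t) == on
                        for t in track.timestamp_s])
        mean_mob = float(track.mobility[sel].mean()) if sel.any() else float("nan")
        mob_bouts = [(s, e) for s, e in bouts.select("mobility")
                     if schedule.condition_of(s) == on]
        if mob_bouts:
            durs = np.array([e - s for s, e in mob_bouts])
            in_bout = np.zeros(len(track), dtype=bool)
            for s, e in mob_bouts:
                in_bout |= (track.timestamp_s >= s) & (track.timestamp_s < e)
            vigor = float(track.mobility[in_bout].mean())
            mean_dur = float(durs.mean())
        else:
            vigor, mean_dur = float("nan"), float("nan")
        out[on] = {"mean_mobility": mean_mob, "bout_vigor": vigor,
                   "mean_bout_dur_s": mean_dur, "n_bouts": len(mob_bouts)}
    return out


def consumption_metrics(events: EventSeries,
                        session_len_s: float) -> ConsumptionMetrics:
    """Average duration, inter-event interval, count and total duration."""
    if not events.is_intervals:
        raise DataError("consumption events must be intervals")
    iv = events.intervals
    if len(iv) > 1 and np.any(iv[1:, 0] < iv[:-1, 1]):
        raise DataError("consumption events overlap")
    if iv.size and iv[:, 1].max() > session_len_s + 1e-9:
        raise DataError("events exceed session length")
    if len(iv) == 0:
        return ConsumptionMetrics(0.0, 0.0, 0, 0.0, interval_defined=False)
    durs = iv[:, 1] - iv[:, 0]
    if len(iv) >= 2:
        gaps = iv[1:, 0] - iv[:-1, 1]
        return ConsumptionMetrics(float(durs.mean()), float(gaps.mean()),
                                  len(iv), float(durs.sum()))
    return ConsumptionMetrics(float(durs.mean()), 0.0, 1, float(durs.sum()),
                              interval_defined=False)


_METRIC_FIELDS = ("mean_event_dur_s", "mean_inter_event_interval_s",
                  "n_events", "total_dur_s")


def normalize_to_baseline(stim: ConsumptionMetrics, last_pre: ConsumptionMetrics,
                          post: ConsumptionMetrics) -> dict[str, float]:
    """Divide each stimulation-session metric by the mean of the last
    pre-session and the post-session value of the same metric.

    A zero baseline yields NaN for that entry rather than raising.
    """
    out: dict[str, float] = {}
    for name in _METRIC_FIELDS:
        denom = (float(getattr(last_pre, name)) + float(getattr(post, name))) / 2.0
        num = float(getattr(stim, name))
        out[name] = num / denom if denom != 0 else float("nan")
    return out
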