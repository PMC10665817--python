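"""Synthetic photometry/behavior session generator with known latent structure.

Emulates a multi-LED fiber-photometry acquisition: a camera captures frames
at ``camera_rate_hz`` while excitation LEDs alternate, so each channel is
sampled at camera_rate / n_channels on an offset grid. The first declared
channel is the calcium-independent reference (isosbestic-style); every
other channel carries kernel-convolved calcium transients. All channels
share slow photobleaching drift (double exponential, channel-specific
amplitude) and a common motion-artifact component with channel-specific
gain — the premise that makes reference-based correction work.

Behavior is an alternating mobility/immobility bout process: the score is
the bout envelope (linear 0.3-s ramps at transitions) times a smooth
within-bout fluctuation, so immobility reads exactly zero and bout
boundaries are recoverable. The calcium-dependent channel carries, besides
discrete transients, a sustained movement-locked component proportional to
the mobility score shifted by ``coupling_lag_s`` (negative = calcium
leads), which is what makes the planted lead/lag recoverable by
cross-correlation. Every latent variable is returned in
:class:`GroundTruth` so downstream stages can be tested by parameter
recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datatypes import BehaviorTrack, BoutTable, EventSeries, InterleavedRecording

__all__ = ["ParameterError", "SynthConfig", "GroundTruth", "generate_session",
           "generate_lick_train", "transient_kernel"]


class ParameterError(ValueError):
    """Raised when a configuration field is invalid (names the field)."""


# Fixed channel plumbing: reference is the first declared channel.
_REFERENCE_ARTIFACT_GAIN = 0.7
_SIGNAL_ARTIFACT_GAIN = 1.0
_BASELINE_OFFSET = 100.0  # camera units; absorbed by standardization
_RAMP_S = 0.3  # mobility envelope transition ramp
_MIN_IMMOBILITY_S = 2.5  # floor so planted immobility bouts are detectable
_MIN_MOBILITY_S = 1.0


@dataclass
class SynthConfig:
    """Parameters of the generative session model.

    Defaults mirror the acquisition described for the recordings this
    package analyzes (20 Hz camera alternating two LEDs -> 10 Hz per
    channel); amplitudes are chosen so that per-frame noise is half the
    unit transient peak.
    """

    duration_s: float = 600.0
    camera_rate_hz: float = 20.0
    led_channels: tuple[str, ...] = ("415", "470")
    bleach_amp: float = 10.0
    bleach_tau_s: float = 120.0
    artifact_rate_hz: float = 0.2
    artifact_amp: float = 3.0
    transient_rate_hz: float = 0.8
    movement_gain: float = 2.0
    kernel_rise_s: float = 0.2
    kernel_decay_s: float = 1.0
    noise_sd: float = 0.5
    coupling_lag_s: float = -0.4
    bout_mean_dur_s: float = 6.0
    immobility_mean_dur_s: float = 8.0
    lick_params: dict = field(default_factory=lambda: {
        "bout_rate_hz": 0.02,
        "lick_rate_hz": 5.0,
        "licks_per_bout_mean": 8.0,
        "contact_dur_s": 0.1,
    })
    seed: int = 0

    def validate(self) -> None:
        if not self.duration_s > 0:
            raise ParameterError("duration_s must be > 0")
        if not self.camera_rate_hz > 0:
            raise ParameterError("camera_rate_hz must be > 0")
        if len(self.led_channels) < 1:
            raise ParameterError("led_channels must list at least one channel")
        if not (self.kernel_decay_s > self.kernel_rise_s > 0):
            raise ParameterError(
                "kernel time constants must satisfy kernel_decay_s > kernel_rise_s > 0"
            )
        for name in ("artifact_rate_hz", "transient_rate_hz", "noise_sd",
                     "artifact_amp", "bleach_amp", "movement_gain"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for name in ("bout_mean_dur_s", "immobility_mean_dur_s", "bleach_tau_s"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be > 0")

    def replace(self, **kw) -> "SynthConfig":
        return replace(self, **kw)

    @property
    def channel_rate_hz(self) -> float:
        return self.camera_rate_hz / len(self.led_channels)


@dataclass
class GroundTruth:
    """Latent variables of a generated session, for recovery tests."""

    transient_times: np.ndarray
    transient_amps: np.ndarray
    clean_transient_trace: dict[str, np.ndarray]  # per channel, on channel grid
    drift_trace: dict[str, np.ndarray]
    artifact_frame: np.ndarray  # shared artifact on the full camera-frame grid
    artifact_gains: dict[str, float]
    mobility_onsets: np.ndarray
    true_lag_s: float
    lick_intervals: np.ndarray
    bouts: BoutTable
    channel_times: dict[str, np.ndarray]


def transient_kernel(t: np.ndarray, rise_s: float, decay_s: float) -> np.ndarray:
    """Difference-of-exponentials calcium kernel, normalized to unit peak."""
    t = np.asarray(t, dtype=float)
    k = np.where(t >= 0, np.exp(-t / decay_s) - np.exp(-t / rise_s), 0.0)
    # peak at t* = log(decay/rise) * rise*decay/(decay-rise)
    tstar = np.log(decay_s / rise_s) * rise_s * decay_s / (decay_s - rise_s)
    peak = np.exp(-tstar / decay_s) - np.exp(-tstar / rise_s)
    return k / peak


def _bout_process(rng: np.random.Generator, duration: float,
                  mob_mean: float, immob_mean: float) -> BoutTable:
    """Alternating immobility/mobility bouts with exponential durations."""
    intervals, labels = [], []
    t = 0.0
    immobile = True
    while t < duration:
        if immobile:
            d = _MIN_IMMOBILITY_S + rng.exponential(max(immob_mean - _MIN_IMMOBILITY_S, 0.1))
        else:
            d = _MIN_MOBILITY_S + rng.exponential(max(mob_mean - _MIN_MOBILITY_S, 0.1))
        end = min(t + d, duration)
        intervals.append((t, end))
        labels.append("immobility" if immobile else "mobility")
        t = end
        immobile = not immobile
    return BoutTable(np.array(intervals), np.array(labels, dtype=object))


def _envelope(t: np.ndarray, bouts: BoutTable) -> np.ndarray:
    """Mobility-bout indicator with linear ramps at transitions."""
    e = np.zeros_like(t)
    for start, end in bouts.select("mobility"):
        rise = np.clip((t - start) / _RAMP_S, 0.0, 1.0)
        fall = np.clip((end - t) / _RAMP_S, 0.0, 1.0)
        e = np.maximum(e, np.minimum(rise, fall) * ((t >= start) & (t <= end)))
    return e


def _sum_kernels(t: np.ndarray, times: np.ndarray, amps: np.ndarray,
                 rise: float, decay: float) -> np.ndarray:
    out = np.zeros_like(t)
    support = 10.0 * decay
    for ti, ai in zip(times, amps):
        i0, i1 = np.searchsorted(t, [ti, ti + support])
        out[i0:i1] += ai * transient_kernel(t[i0:i1] - ti, rise, decay)
    return out


def _artifact_bumps(t: np.ndarray, times: np.ndarray, amps: np.ndarray) -> np.ndarray:
    # fiber-motion bumps with ~1-s kinetics: slow enough to survive the
    # default 1-s smoothing, which is the regime reference correction targets
    return _sum_kernels(t, times, amps, rise=0.1, decay=0.8)


def generate_session(config: SynthConfig):
    """Generate one full synthetic session.

    Returns ``(recording, track, events, truth)`` where ``recording`` is the
    raw interleaved frame table, ``track`` the mobility score, ``events`` a
    dict of labeled EventSeries (licks, mobility/immobility onsets) and
    ``truth`` the :class:`GroundTruth` latents. Identical config (including
    seed) yields bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_ch = len(config.led_channels)
    n_frames = int(round(config.duration_s * config.camera_rate_hz))
    t_frame = np.arange(n_frames) / config.camera_rate_hz
    ch_of_frame = np.arange(n_frames) % n_ch
    led_state = np.left_shift(1, ch_of_frame)  # bitmask: 1, 2, 4

    bouts = _bout_process(rng, config.duration_s,
                          config.bout_mean_dur_s, config.immobility_mean_dur_s)
    mobility_onsets = bouts.onsets("mobility")

    # mobility score: bout envelope times a smooth within-bout fluctuation
    # (kernel-filtered noise mapped into [0.55, 1]); immobility is exactly 0
    env = _envelope(t_frame, bouts)
    white = rng.normal(size=n_frames)
    ker = transient_kernel(np.arange(0.0, 5.0 * config.kernel_decay_s,
                                     1.0 / config.camera_rate_hz),
                           config.kernel_rise_s, config.kernel_decay_s)
    fluct = np.convolve(white, ker / ker.sum(), mode="same")
    span = fluct.max() - fluct.min()
    u = (fluct - fluct.min()) / span if span > 0 else np.zeros_like(fluct)
    mob = env * (0.55 + 0.45 * u)
    if mob.max() > 0:
        mob = mob / mob.max()
    track = BehaviorTrack(t_frame.copy(), mob)

    # transient process: one transient locked to each mobility onset plus
    # Poisson background within (lag-shifted) mobility windows
    transient_times: list[float] = []
    if config.transient_rate_hz > 0:
        for start, end in bouts.select("mobility"):
            w0 = start + config.coupling_lag_s
            w1 = end + config.coupling_lag_s
            transient_times.append(w0)
            n_extra = rng.poisson(config.transient_rate_hz * (w1 - w0))
            transient_times.extend(rng.uniform(w0, w1, size=n_extra))
    transient_times = np.sort(np.array(transient_times, dtype=float))
    transient_amps = rng.uniform(0.8, 1.2, size=len(transient_times))

    art_n = rng.poisson(config.artifact_rate_hz * config.duration_s)
    art_times = np.sort(rng.uniform(0, config.duration_s, size=art_n))
    art_amps = (config.artifact_amp
                * rng.choice([-1.0, 1.0], size=art_n)
                * rng.uniform(0.5, 1.5, size=art_n))
    artifact_frame = _artifact_bumps(t_frame, art_times, art_amps)

    # per-channel latents on each channel's own (offset) grid; the clean
    # calcium signal = discrete transients + movement-locked sustained
    # component (mobility shifted so that calcium leads when lag < 0)
    channel_times, clean, drift, gains = {}, {}, {}, {}
    frame_values = np.zeros(n_frames)
    for idx, label in enumerate(config.led_channels):
        sel = ch_of_frame == idx
        t_ch = t_frame[sel]
        channel_times[label] = t_ch
        amp_ch = config.bleach_amp * (1.0 - 0.15 * idx)
        d = (_BASELINE_OFFSET + 5.0 * idx
             + amp_ch * (0.7 * np.exp(-t_ch / config.bleach_tau_s)
                         + 0.3 * np.exp(-t_ch / (config.bleach_tau_s / 8.0))))
        drift[label] = d
        is_reference = idx == 0
        gains[label] = _REFERENCE_ARTIFACT_GAIN if is_reference else _SIGNAL_ARTIFACT_GAIN
        if is_reference or not len(transient_times):
            c = np.zeros_like(t_ch)
        else:
            c = _sum_kernels(t_ch, transient_times, transient_amps,
                             config.kernel_rise_s, config.kernel_decay_s)
            c = c + config.movement_gain * np.interp(
                t_ch - config.coupling_lag_s, t_frame, mob)
        clean[label] = c
        frame_values[sel] = d + gains[label] * artifact_frame[sel] + c
    frame_values = frame_values + rng.normal(0.0, config.noise_sd, size=n_frames)

    lick_intervals = _lick_process(rng, config)
    events = {
        "lick": EventSeries("lick", intervals=lick_intervals.reshape(-1, 2)),
        "mobility_onset": EventSeries("mobility_onset", times_s=mobility_onsets),
        "immobility_onset": EventSeries(
            "immobility_onset", times_s=bouts.onsets("immobility")),
    }

    rec = InterleavedRecording(
        frame_index=np.arange(n_frames),
        timestamp_s=t_frame,
        led_state=led_state,
        values={"Region0": frame_values},
        channel_map={1 << i: lab for i, lab in enumerate(config.led_channels)},
    )
    truth = GroundTruth(
        transient_times=transient_times,
        transient_amps=transient_amps,
        clean_transient_trace=clean,
        drift_trace=drift,
        artifact_frame=artifact_frame,
        artifact_gains=gains,
        mobility_onsets=mobility_onsets,
        true_lag_s=config.coupling_lag_s,
        lick_intervals=lick_intervals,
        bouts=bouts,
        channel_times=channel_times,
    )
    return rec, track, events, truth


def _lick_process(rng: np.random.Generator, config: SynthConfig) -> np.ndarray:
    p = config.lick_params
    bout_rate = p.get("bout_rate_hz", 0.0)
    if bout_rate <= 0:
        return np.empty((0, 2))
    lick_rate = p["lick_rate_hz"]
    contact = p["contact_dur_s"]
    gap = max(1.0 / lick_rate - contact, 0.01)
    if contact + gap >= 1.0:
        raise ParameterError("lick_params: within-bout inter-lick gap must be < 1 s")
    intervals = []
    t = rng.exponential(1.0 / bout_rate)
    while t < config.duration_s:
        n_licks = max(1, rng.poisson(p["licks_per_bout_mean"]))
        for _ in range(n_licks):
            end = t + contact
            if end > config.duration_s:
                break
            intervals.append((t, end))
            t = end + gap
        # between-bout gap strictly > 1 s by construction
        t += 1.5 + rng.exponential(1.0 / bout_rate)
    return np.array(intervals, dtype=float).reshape(-1, 2)


def generate_lick_train(config: SynthConfig) -> EventSeries:
    """Generate only the lickometer contact intervals of a session."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    return EventSeries("lick", intervals=_lick_process(rng, config))
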