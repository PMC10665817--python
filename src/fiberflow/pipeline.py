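"""End-to-end orchestration: simulate -> preprocess -> events -> peri-event
-> correlation -> opto, from a single declarative config.

Every stage is a pure function of (inputs, parameters, seed); a rerun with
the same config produces byte-identical numeric outputs. Outputs are
stamped with the config hash, seed and package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import yaml

from . import __version__
from .behavior import detect_bouts, detect_consumption, select_events
from .correlation import classify_events, crosscorr_lag, session_pearson
from .datatypes import DataError
from .io import deinterleave, store_session
from .opto import EpochSchedule, consumption_metrics, epoch_metrics
from .perievent import auc, extract, trial_mean, window_table
from .preprocessing import PreprocessParams, compute_zdff
from .synth import SynthConfig, generate_session

__all__ = ["RunConfig", "StageError", "run"]

_STAGES = ("simulate", "preprocess", "events", "perievent", "correlate", "opto")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Declarative description of one pipeline run.

    The zero-override configuration reproduces the reference analysis: all
    thresholds default to the published rules.
    """

    seed: int = 0
    out_path: str | None = None
    stages: tuple[str, ...] = _STAGES
    synth: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    events: dict = field(default_factory=dict)
    perievent: dict = field(default_factory=lambda: {"test": "mobility",
                                                     "pre_s": 5.0, "post_s": 5.0})
    correlate: dict = field(default_factory=lambda: {"window_s": 6.0,
                                                     "max_lag_s": 2.0})
    opto: dict = field(default_factory=lambda: {"epoch_len_s": 120.0})

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise DataError(f"unknown stage(s): {sorted(unknown)}")
        for block in ("perievent", "correlate", "opto"):
            if block in self.stages and getattr(self, block) is None:
                raise DataError(f"missing required config block {block!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DataError(f"unknown config key(s): {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the scientific parameters (paths excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_path", None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns the run report."""
    report: dict = {"config_hash": config.config_hash(), "seed": config.seed,
                    "version": __version__}
    state: dict = {}
    for stage in _STAGES:
        if stage not in config.stages:
            continue
        try:
            _STAGE_FUNCS[stage](config, state, report)
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            _maybe_store(config, state, report)
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
    _maybe_store(config, state, report)
    return report


def _stage_simulate(config: RunConfig, state: dict, report: dict) -> None:
    synth_cfg = SynthConfig(**{**config.synth, "seed": config.seed})
    rec, track, events, truth = generate_session(synth_cfg)
    state.update(rec=rec, track=track, raw_events=events, truth=truth,
                 synth_cfg=synth_cfg)
    report["simulate"] = {"n_frames": len(rec),
                          "n_channels": len(synth_cfg.led_channels),
                          "n_transients": len(truth.transient_times)}


def _stage_preprocess(config: RunConfig, state: dict, report: dict) -> None:
    traces = deinterleave(state["rec"])
    labels = list(state["synth_cfg"].led_channels)
    reference = traces[labels[0]]
    signal = traces[labels[1]]
    params = PreprocessParams(**config.preprocess)
    zdff, fit = compute_zdff(signal, reference, params, return_fit=True)
    state.update(traces=traces, zdff=zdff, fit=fit)
    report["preprocess"] = {"slope_a": fit.slope_a,
                            "intercept_b": fit.intercept_b}


def _stage_events(config: RunConfig, state: dict, report: dict) -> None:
    bouts = detect_bouts(state["track"], **config.events.get("bouts", {}))
    consumption = detect_consumption(state["raw_events"]["lick"],
                                     **config.events.get("consumption", {}))
    kinds = select_events(bouts, seed=config.seed,
                          **config.events.get("select", {}))
    state.update(bouts=bouts, consumption=consumption, event_kinds=kinds)
    report["events"] = {
        "n_immobility_bouts": int((bouts.labels == "immobility").sum()),
        "n_mobility_bouts": int((bouts.labels == "mobility").sum()),
        "n_consumption_events": len(consumption),
        "n_events_per_kind": {k: len(v) for k, v in kinds.items()},
    }


def _stage_perievent(config: RunConfig, state: dict, report: dict) -> None:
    p = config.perievent
    spec = window_table(p.get("test", "mobility"))
    onsets = state["event_kinds"]["mobility_onset"].times_s
    matrix = extract(state["zdff"], onsets, pre_s=p.get("pre_s", 5.0),
                     post_s=p.get("post_s", 5.0))
    mean, sem, n = trial_mean(matrix)
    aucs = {name: auc(matrix, win)[1]
            for name, win in spec.named_windows.items()}
    state.update(peri_matrix=matrix, peri_mean=mean, peri_sem=sem,
                 auc_table=aucs)
    report["perievent"] = {"n_trials": n, "n_dropped": matrix.n_dropped,
                           "auc_norm": aucs}


def _stage_correlate(config: RunConfig, state: dict, report: dict) -> None:
    c = config.correlate
    sess = session_pearson(state["zdff"], state["track"])
    counts = classify_events(state["zdff"], state["track"],
                             state["event_kinds"]["mobility_onset"],
                             window_s=c.get("window_s", 6.0))
    lag = crosscorr_lag(state["zdff"], state["track"],
                        state["event_kinds"]["mobility_onset"],
                        window_s=c.get("window_s", 6.0),
                        max_lag_s=c.get("max_lag_s", 2.0))
    state.update(session_corr=sess, event_classes=counts, lag=lag)
    report["correlate"] = {
        "session_r": sess.r, "session_p": sess.p,
        "fractions": counts.fractions,
        "mean_lag_s": lag.mean_lag_s, "sem_lag_s": lag.sem_lag_s,
    }


def _stage_opto(config: RunConfig, state: dict, report: dict) -> None:
    o = config.opto
    schedule = EpochSchedule.alternating(
        float(state["track"].timestamp_s[-1]), o.get("epoch_len_s", 120.0))
    per_cond = epoch_metrics(state["track"], schedule)
    cons = consumption_metrics(state["consumption"],
                               float(state["track"].timestamp_s[-1]))
    state.update(schedule=schedule, opto_metrics=per_cond,
                 consumption_summary=cons)
    report["opto"] = {
        "n_on_epochs": schedule.n_epochs(True),
        "n_off_epochs": schedule.n_epochs(False),
        "metrics": {("on" if k else "off"): v for k, v in per_cond.items()},
        "consumption": dataclasses.asdict(cons),
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "events": _stage_events,
    "perievent": _stage_perievent,
    "correlate": _stage_correlate,
    "opto": _stage_opto,
}


def _maybe_store(config: RunConfig, state: dict, report: dict) -> None:
    if config.out_path is None:
        return
    traces = {}
    if "traces" in state:
        traces.update(state["traces"])
    if "zdff" in state:
        traces["zdff"] = state["zdff"]
    arrays = {}
    if "peri_matrix" in state:
        arrays["peri/rel_time_s"] = state["peri_matrix"].rel_time_s
        arrays["peri/values"] = state["peri_matrix"].values
        arrays["peri/mean"] = state["peri_mean"]
        arrays["peri/sem"] = state["peri_sem"]
    if "lag" in state:
        arrays["lag/lags_s"] = state["lag"].lags_s
        arrays["lag/corr_vs_lag"] = state["lag"].corr_vs_lag
        arrays["lag/lag_at_max_s"] = state["lag"].lag_at_max_s
    events = dict(state.get("raw_events", {}))
    if "consumption" in state:
        events["consumption"] = state["consumption"]
    store_session(config.out_path, traces=traces,
                  tracks={"mobility": state["track"]} if "track" in state else {},
                  events=events, arrays=arrays)
    with h5py.File(config.out_path, "a") as f:
        f.attrs["config_hash"] = report["config_hash"]
        f.attrs["seed"] = config.seed
        f.attrs["version"] = report["version"]


def report_numeric_digest(report: dict) -> str:
    """Stable hash of every number in a run report (determinism checks)."""
    def _canon(obj):
        if isinstance(obj, dict):
            return {k: _canon(obj[k]) for k in sorted(obj)}
        if isinstance(obj, (list, tuple)):
            return [_canon(v) for v in obj]
        if isinstance(obj, (np.floating, float)):
            return float(np.float64(obj)).hex()
        if isinstance(obj, (np.integer, int)):
            return int(obj)
        return obj
    blob = json.dumps(_canon(report), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()
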