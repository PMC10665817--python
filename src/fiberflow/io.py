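"""Readers/writers for raw interleaved recordings and processed sessions.

The raw dialect is a plain CSV frame table with columns ``FrameCounter``,
``Timestamp``, ``LedState`` and one ``Region<k>`` fluorescence column per
fiber/ROI. Processed sessions round-trip through a single hierarchical
HDF5 container with named groups per trace/track/event-set.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datatypes import (BehaviorTrack, DataError, EventSeries, FormatError,
                        InterleavedRecording, PhotometryTrace)

__all__ = ["read_frames", "write_frames", "deinterleave",
           "store_session", "load_session", "LAYOUT_VERSION"]

LAYOUT_VERSION = 1

_REQUIRED = ("FrameCounter", "Timestamp", "LedState")


def read_frames(source, channel_map: dict[int, str] | None = None) -> InterleavedRecording:
    """Read a raw interleaved frame table from a CSV path or stream.

    ``channel_map`` maps LED-state codes to channel labels; when given,
    unknown codes in the file raise a :class:`DataError`.
    """
    df = pd.read_csv(source, dtype={"LedState": "int64"}, float_precision="round_trip")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    region_cols = [c for c in df.columns if c.startswith("Region")]
    if not region_cols:
        raise FormatError("no RegionN fluorescence column found")
    return InterleavedRecording(
        frame_index=df["FrameCounter"].to_numpy(np.int64),
        timestamp_s=df["Timestamp"].to_numpy(float),
        led_state=df["LedState"].to_numpy(np.int64),
        values={c: df[c].to_numpy(float) for c in region_cols},
        channel_map=dict(channel_map or {}),
    )


def write_frames(rec: InterleavedRecording, dest) -> None:
    """Write a recording back to the CSV frame-table dialect."""
    cols = {"FrameCounter": rec.frame_index, "Timestamp": rec.timestamp_s,
            "LedState": rec.led_state}
    cols.update(rec.values)
    pd.DataFrame(cols).to_csv(dest, index=False)


def deinterleave(rec: InterleavedRecording) -> dict[str, PhotometryTrace]:
    """Split interleaved frames into one trace per (channel, ROI).

    Keys are ``"<channel>/<roi>"`` (just ``"<channel>"`` for a single ROI).
    Every input frame lands in exactly one output trace; the per-trace
    nominal rate is the camera rate (estimated from timestamps) divided by
    the number of active LED codes.
    """
    codes = np.unique(rec.led_state)
    camera_rate = 1.0 / float(np.median(np.diff(rec.timestamp_s)))
    rate = camera_rate / len(codes)
    out: dict[str, PhotometryTrace] = {}
    single_roi = len(rec.values) == 1
    for code in codes:
        sel = rec.led_state == code
        if sel.sum() < 2:
            raise DataError(f"LED code {code} has fewer than 2 frames")
        label = rec.channel_map.get(int(code), str(int(code)))
        for roi, col in rec.values.items():
            key = label if single_roi else f"{label}/{roi}"
            out[key] = PhotometryTrace(
                timestamp_s=rec.timestamp_s[sel],
                value=col[sel],
                channel_label=label,
                roi_label=roi,
                nominal_rate_hz=rate,
            )
    return out


# ---------------------------------------------------------------------------
# HDF5 session store


def _leaf_groups(root, *signatures):
    """Yield (path, group) pairs for groups holding any signature dataset."""
    if root is None:
        return
    stack = [("", root)]
    while stack:
        prefix, node = stack.pop()
        for key, child in node.items():
            path = f"{prefix}{key}"
            if isinstance(child, h5py.Group):
                if any(sig <= set(child.keys()) for sig in signatures):
                    yield path, child
                else:
                    stack.append((path + "/", child))


def _write_trace(grp: h5py.Group, trace: PhotometryTrace) -> None:
    grp.create_dataset("timestamp_s", data=trace.timestamp_s)
    grp.create_dataset("value", data=trace.value)
    grp.attrs["channel_label"] = trace.channel_label
    grp.attrs["roi_label"] = trace.roi_label
    grp.attrs["nominal_rate_hz"] = trace.nominal_rate_hz


def _read_trace(grp: h5py.Group) -> PhotometryTrace:
    return PhotometryTrace(
        grp["timestamp_s"][()], grp["value"][()],
        channel_label=str(grp.attrs.get("channel_label", "")),
        roi_label=str(grp.attrs.get("roi_label", "")),
        nominal_rate_hz=float(grp.attrs.get("nominal_rate_hz", 0.0)),
    )


def store_session(path, *, traces: dict[str, PhotometryTrace] | None = None,
                  tracks: dict[str, BehaviorTrack] | None = None,
                  events: dict[str, EventSeries] | None = None,
                  arrays: dict[str, np.ndarray] | None = None) -> None:
    """Store named traces/tracks/events/result arrays in one HDF5 file."""
    with h5py.File(path, "w") as f:
        f.attrs["layout_version"] = LAYOUT_VERSION
        for name, tr in (traces or {}).items():
            _write_trace(f.create_group(f"traces/{name}"), tr)
        for name, tk in (tracks or {}).items():
            g = f.create_group(f"tracks/{name}")
            g.create_dataset("timestamp_s", data=tk.timestamp_s)
            g.create_dataset("mobility", data=tk.mobility)
            if tk.raw_speed is not None:
                g.create_dataset("raw_speed", data=tk.raw_speed)
        for name, ev in (events or {}).items():
            g = f.create_group(f"events/{name}")
            g.attrs["label"] = ev.label
            if ev.is_intervals:
                g.create_dataset("intervals", data=ev.intervals)
            else:
                g.create_dataset("times_s", data=ev.times_s)
        for name, arr in (arrays or {}).items():
            f.create_dataset(f"arrays/{name}", data=np.asarray(arr))


def load_session(path):
    """Load a stored session; inverse of :func:`store_session`.

    Returns ``(traces, tracks, events, arrays)`` dicts. A file without the
    layout-version attribute (or a newer version) raises FormatError; a
    requested group absent from the file simply yields an empty dict.
    """
    if not Path(path).exists():
        raise FileNotFoundError(path)
    traces, tracks, events, arrays = {}, {}, {}, {}
    with h5py.File(path, "r") as f:
        version = f.attrs.get("layout_version")
        if version is None:
            raise FormatError("session store lacks a layout_version attribute")
        if int(version) > LAYOUT_VERSION:
            raise FormatError(f"unsupported layout version {version}")
        # stored names may contain '/', which HDF5 maps to nested groups;
        # walk leaves and reassemble the dotted-path keys
        for name, grp in _leaf_groups(f.get("traces"), {"timestamp_s", "value"}):
            traces[name] = _read_trace(grp)
        for name, grp in _leaf_groups(f.get("tracks"),
                                      {"timestamp_s", "mobility"}):
            tracks[name] = BehaviorTrack(
                grp["timestamp_s"][()], grp["mobility"][()],
                raw_speed=grp["raw_speed"][()] if "raw_speed" in grp else None)
        for name, grp in _leaf_groups(f.get("events"), {"intervals"},
                                      {"times_s"}):
            label = str(grp.attrs.get("label", name))
            if "intervals" in grp:
                events[name] = EventSeries(label, intervals=grp["intervals"][()])
            else:
                events[name] = EventSeries(label, times_s=grp["times_s"][()])
        grp = f.get("arrays")
        if grp is not None:
            def _collect(prefix, node):
                for key, child in node.items():
                    path = f"{prefix}{key}"
                    if isinstance(child, h5py.Dataset):
                        arrays[path] = child[()]
                    else:
                        _collect(path + "/", child)
            _collect("", grp)
    return traces, tracks, events, arrays


def roundtrip_csv(rec: InterleavedRecording,
                  channel_map: dict[int, str] | None = None) -> InterleavedRecording:
    """Write a recording to CSV in memory and read it back (test helper)."""
    buf = _io.StringIO()
    write_frames(rec, buf)
    buf.seek(0)
    return read_frames(buf, channel_map or rec.channel_map)
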