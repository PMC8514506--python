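"""Uniformly sampled time traces and their CSV / HDF5 interchange.

A :class:`TimeTrace` is the raw material of every pipeline stage: a trap
position, bead position, or force channel sampled on a uniform grid.  The
channel name carries the unit (``*_um``, ``*_v``, ``*_pn``); conversions
between volt and physical channels happen only through a trap calibration.

CSV layout: ``# key: value`` metadata comment lines, then ``time_s,value``
columns.  HDF5 layout mirrors a dual-trap instrument export, one group per
channel with ``time_s``/``value`` datasets and attributes for metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

CHANNELS = (
    "trap_position_um",
    "trap_position_v",
    "bead_position_um",
    "bead_position_v",
    "force_pn",
    "force_v",
)

# relative jitter tolerance on the uniform time grid
_GRID_RTOL = 1e-9


@dataclass(frozen=True)
class TimeTrace:
    """One uniformly sampled channel with provenance metadata."""

    t0: float
    dt: float
    values: np.ndarray
    channel: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if v.ndim != 1 or v.size < 2:
            raise ValueError("a trace needs at least 2 samples")
        if not np.all(np.isfinite(v)):
            raise ValueError("trace values must be finite")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Measurement span dt*(n-1), in s."""
        return self.dt * (self.n - 1)

    @property
    def sampling_rate(self) -> float:
        return 1.0 / self.dt

    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n)

    def with_values(self, values, channel: str | None = None, **meta) -> "TimeTrace":
        return TimeTrace(self.t0, self.dt, np.asarray(values, dtype=float),
                         channel or self.channel, {**self.meta, **meta})


def _check_uniform(t: np.ndarray) -> float:
    """Return dt, raising (with the offending row) on a non-uniform grid."""
    dt = np.diff(t)
    if np.any(dt <= 0):
        bad = int(np.nonzero(dt <= 0)[0][0]) + 2  # 1-based offending sample
        raise ValueError(f"time column not increasing at row {bad}")
    med = float(np.median(dt))
    jitter = np.abs(dt - med) > _GRID_RTOL * med + 1e-15
    if np.any(jitter):
        bad = int(np.nonzero(jitter)[0][0]) + 2
        raise ValueError(f"non-uniform sampling at row {bad}: dt={dt[bad-2]:g} vs {med:g}")
    return med


def write_trace(trace: TimeTrace, path) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5", ".hdf"):
        write_traces_hdf5({trace.channel: trace}, path)
        return
    with open(path, "w") as fh:
        fh.write(f"# channel: {trace.channel}\n")
        fh.write(f"# t0_s: {trace.t0!r}\n")
        for k, v in trace.meta.items():
            fh.write(f"# meta {k}: {json.dumps(v)}\n")
        fh.write("time_s,value\n")
        t = trace.times()
        for ti, vi in zip(t, trace.values):
            fh.write(f"{float(ti)!r},{float(vi)!r}\n")


def read_trace(path, channel: str | None = None) -> TimeTrace:
    """Read a trace from CSV (or a single-channel HDF5 container)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5", ".hdf"):
        traces = read_traces_hdf5(path)
        if channel is not None:
            return traces[channel]
        if len(traces) != 1:
            raise ValueError("HDF5 container holds several channels; pass channel=")
        return next(iter(traces.values()))
    meta: dict = {}
    ch = channel
    with open(path) as fh:
        header: list[str] = []
        for line in fh:
            if line.startswith("#"):
                header.append(line[1:].strip())
            else:
                break
    for item in header:
        if item.startswith("channel:"):
            ch = item.split(":", 1)[1].strip()
        elif item.startswith("meta "):
            k, v = item[5:].split(":", 1)
            try:
                meta[k.strip()] = json.loads(v.strip())
            except json.JSONDecodeError:
                meta[k.strip()] = v.strip()
    if ch is None:
        raise ValueError(f"{path}: no channel in header and none supplied")
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    t = df["time_s"].to_numpy(dtype=float)
    dt = _check_uniform(t)
    return TimeTrace(float(t[0]), dt, df["value"].to_numpy(dtype=float), ch, meta)


def write_traces_hdf5(traces: dict[str, TimeTrace], path) -> None:
    """Write named traces to an HDF5 container, one group per name
    (e.g. /trap_position, /force1, /force2)."""
    with h5py.File(path, "w") as f:
        for name, tr in traces.items():
            g = f.create_group(name.lstrip("/"))
            g.create_dataset("time_s", data=tr.times())
            g.create_dataset("value", data=tr.values)
            g.attrs["channel"] = tr.channel
            g.attrs["t0_s"] = tr.t0
            g.attrs["dt_s"] = tr.dt
            g.attrs["meta_json"] = json.dumps(tr.meta)


def read_traces_hdf5(path) -> dict[str, TimeTrace]:
    out: dict[str, TimeTrace] = {}
    with h5py.File(path, "r") as f:
        for name, g in f.items():
            t = np.asarray(g["time_s"])
            dt = _check_uniform(t)
            meta = json.loads(g.attrs.get("meta_json", "{}"))
            out[name] = TimeTrace(float(t[0]), dt, np.asarray(g["value"]),
                                  str(g.attrs["channel"]), meta)
    return out
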