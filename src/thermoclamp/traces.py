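"""Core sweep and protocol types with plain-text readers/writers.

A *sweep* is one uniformly sampled channel trace (membrane voltage in mV,
clamp current in pA, or temperature in degC) together with the stimulus
protocol and recording metadata. On disk a sweep is a two-column CSV
(``time_s,value``) plus a JSON sidecar holding rate, units, channel,
protocol and metadata; a *family* of sweeps sharing a protocol is a
directory with a ``manifest.json`` listing the ordered sweep files.

Conventions: time in seconds, voltage in mV, current in pA, temperature in
degC; sample index 0-based; analysis windows are half-open ``[t0, t1)``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Any, Sequence, Union

import numpy as np

from .errors import TraceFormatError

__all__ = [
    "Sweep",
    "StepProtocol",
    "RampProtocol",
    "VClampProtocol",
    "SweepFamily",
    "read_sweep",
    "write_sweep",
    "read_family",
    "write_family",
    "validate_family",
    "sweep_checksum",
]

#: canonical units per channel
_CHANNEL_UNITS = {"voltage": "mV", "current": "pA", "temperature": "degC"}
_UNIT_ALIASES = {"°C": "degC", "C": "degC"}


@dataclass(frozen=True)
class StepProtocol:
    """Rectangular current step riding on an optional conditioning DC offset.

    ``conditioning_pa`` sets the pre-step membrane potential (e.g. the
    hyperpolarized / rest / depolarized levels used for input-resistance
    probes); ``baseline_pa`` is any additional pre-step level.
    """

    amplitude_pa: float
    onset_s: float
    duration_s: float
    baseline_pa: float = 0.0
    conditioning_pa: float = 0.0

    def __post_init__(self):
        if self.onset_s < 0:
            raise ValueError("onset_s must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")

    def current_pa(self, t: np.ndarray) -> np.ndarray:
        """Injected current (pA) at times ``t`` (holding current excluded)."""
        i = np.full_like(t, self.baseline_pa + self.conditioning_pa, dtype=float)
        on = (t >= self.onset_s) & (t < self.onset_s + self.duration_s)
        i[on] += self.amplitude_pa
        return i


@dataclass(frozen=True)
class RampProtocol:
    """Linear current ramp from ``start_pa`` with slope ``slope_pa_per_s``."""

    start_pa: float
    slope_pa_per_s: float
    onset_s: float
    duration_s: float

    def __post_init__(self):
        if self.onset_s < 0:
            raise ValueError("onset_s must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")

    def current_pa(self, t: np.ndarray) -> np.ndarray:
        i = np.zeros_like(t, dtype=float)
        on = (t >= self.onset_s) & (t < self.onset_s + self.duration_s)
        i[on] = self.start_pa + self.slope_pa_per_s * (t[on] - self.onset_s)
        return i

    def current_at(self, t: float) -> float:
        """Ramp current at a single time, clipped to the ramp extent."""
        if t < self.onset_s or t >= self.onset_s + self.duration_s:
            raise ValueError("time outside ramp extent")
        return self.start_pa + self.slope_pa_per_s * (t - self.onset_s)


@dataclass(frozen=True)
class VClampProtocol:
    """Voltage-step family: hold, step to each command, return to hold.

    Defaults mirror the standard protocol: holding -75 mV, commands
    -85 .. +10 mV in 5 mV increments, 500 ms steps. ``ttx`` flags the
    condition in which fast sodium current is pharmacologically blocked.
    """

    commands_mv: tuple = tuple(np.arange(-85.0, 10.0 + 2.5, 5.0))
    holding_mv: float = -75.0
    step_duration_s: float = 0.5
    onset_s: float = 0.1
    tail_s: float = 0.1
    ttx: bool = False

    def __post_init__(self):
        object.__setattr__(self, "commands_mv", tuple(float(c) for c in self.commands_mv))
        if len(self.commands_mv) == 0:
            raise ValueError("commands_mv must be non-empty")
        if np.any(np.diff(self.commands_mv) <= 0):
            raise ValueError("commands_mv must be strictly increasing")
        if not (-120.0 <= self.holding_mv <= 0.0):
            raise ValueError("holding_mv must lie in [-120, 0] mV")
        if self.step_duration_s <= 0 or self.onset_s < 0 or self.tail_s < 0:
            raise ValueError("invalid step timing")

    @property
    def sweep_duration_s(self) -> float:
        return self.onset_s + self.step_duration_s + self.tail_s


Protocol = Union[StepProtocol, RampProtocol, VClampProtocol]

_PROTOCOL_TAGS = {"step": StepProtocol, "ramp": RampProtocol, "vclamp": VClampProtocol}


def protocol_to_dict(protocol: Protocol | None) -> dict | None:
    if protocol is None:
        return None
    for tag, cls in _PROTOCOL_TAGS.items():
        if isinstance(protocol, cls):
            d = dataclasses.asdict(protocol)
            if isinstance(protocol, VClampProtocol):
                d["commands_mv"] = list(protocol.commands_mv)
            d["kind"] = tag
            return d
    raise TypeError(f"unknown protocol type {type(protocol)!r}")


def protocol_from_dict(d: dict | None) -> Protocol | None:
    if d is None:
        return None
    d = dict(d)
    try:
        cls = _PROTOCOL_TAGS[d.pop("kind")]
    except KeyError as exc:
        raise TraceFormatError(f"protocol dict missing/unknown kind: {exc}") from exc
    if cls is VClampProtocol and "commands_mv" in d:
        d["commands_mv"] = tuple(d["commands_mv"])
    return cls(**d)


@dataclass(frozen=True)
class Sweep:
    """One uniformly sampled trace plus protocol and metadata.

    Analysis code treats sweeps as immutable; the underlying arrays are
    flagged read-only at construction.
    """

    time_s: np.ndarray
    values: np.ndarray
    units: str
    channel: str
    rate_hz: float = 2.0e4
    protocol: Protocol | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        time_s = np.asarray(self.time_s, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "time_s", time_s)
        object.__setattr__(self, "values", values)
        units = _UNIT_ALIASES.get(self.units, self.units)
        object.__setattr__(self, "units", units)
        if time_s.ndim != 1 or values.ndim != 1 or time_s.shape != values.shape:
            raise TraceFormatError("time and value columns must be 1-D and equal length")
        if len(values) < 2:
            raise TraceFormatError("a sweep needs at least 2 samples")
        if not np.all(np.isfinite(values)) or not np.all(np.isfinite(time_s)):
            raise TraceFormatError("sweep contains non-finite samples")
        if self.rate_hz <= 0:
            raise TraceFormatError("rate_hz must be positive")
        dt = 1.0 / self.rate_hz
        ideal = time_s[0] + np.arange(len(time_s)) * dt
        span = max(time_s[-1] - time_s[0], dt)
        if np.max(np.abs(time_s - ideal)) / span > 1e-9:
            raise TraceFormatError("time column is not uniform at 1/rate_hz spacing")
        if self.channel not in _CHANNEL_UNITS:
            raise TraceFormatError(f"unknown channel {self.channel!r}")
        if units != _CHANNEL_UNITS[self.channel]:
            raise TraceFormatError(
                f"units {units!r} inconsistent with channel {self.channel!r}"
            )
        time_s.setflags(write=False)
        values.setflags(write=False)

    @classmethod
    def from_values(
        cls,
        values: Sequence[float],
        rate_hz: float = 2.0e4,
        channel: str = "voltage",
        units: str | None = None,
        protocol: Protocol | None = None,
        meta: dict | None = None,
    ) -> "Sweep":
        """Build a sweep on the implied ``arange(n)/rate_hz`` time base."""
        values = np.asarray(values, dtype=float)
        time_s = np.arange(len(values)) / rate_hz
        if units is None:
            units = _CHANNEL_UNITS[channel]
        return cls(time_s, values, units, channel, rate_hz, protocol, dict(meta or {}))

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.rate_hz

    @property
    def dt_s(self) -> float:
        return 1.0 / self.rate_hz

    def index_at(self, t: float) -> int:
        """Sample index of time ``t`` relative to the sweep start (rounded)."""
        return int(round((t - self.time_s[0]) * self.rate_hz))

    def window(self, t0: float, t1: float) -> np.ndarray:
        """Samples with time in the half-open window ``[t0, t1)``."""
        i0 = max(self.index_at(t0), 0)
        i1 = min(self.index_at(t1), len(self.values))
        return self.values[i0:i1]


@dataclass
class SweepFamily:
    """Ordered sweeps index-aligned with the entries of a shared protocol."""

    protocol: Union[VClampProtocol, list]
    sweeps: list

    def __len__(self) -> int:
        return len(self.sweeps)

    def n_entries(self) -> int:
        if isinstance(self.protocol, VClampProtocol):
            return len(self.protocol.commands_mv)
        return len(self.protocol)

    def sweep_for_command(self, command_mv: float) -> Sweep:
        if not isinstance(self.protocol, VClampProtocol):
            raise TraceFormatError("family protocol is not a voltage-clamp protocol")
        cmds = np.asarray(self.protocol.commands_mv)
        idx = int(np.argmin(np.abs(cmds - command_mv)))
        if abs(cmds[idx] - command_mv) > 1e-6:
            raise TraceFormatError(f"command {command_mv} mV not in family")
        return self.sweeps[idx]


def validate_family(family: SweepFamily) -> list:
    """Return a list of human-readable invariant violations (empty iff valid)."""
    report: list[str] = []
    n_prot = family.n_entries()
    if len(family.sweeps) != n_prot:
        report.append(
            f"sweep count {len(family.sweeps)} does not match protocol entries {n_prot}"
        )
    if family.sweeps:
        rates = {s.rate_hz for s in family.sweeps}
        if len(rates) > 1:
            report.append(f"mixed sampling rates {sorted(rates)}")
        units = {s.units for s in family.sweeps}
        if len(units) > 1:
            report.append(f"mixed units {sorted(units)}")
        lengths = {len(s.values) for s in family.sweeps}
        if len(lengths) > 1:
            report.append(f"mixed sweep lengths {sorted(lengths)}")
    if isinstance(family.protocol, VClampProtocol):
        dur = family.protocol.sweep_duration_s
        for k, s in enumerate(family.sweeps):
            if abs(s.duration_s - dur) > s.dt_s:
                report.append(
                    f"sweep {k} duration {s.duration_s:.6g} s does not match protocol "
                    f"{dur:.6g} s"
                )
    return report


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_META_KEYS = ("temperature_c", "condition", "cell_id", "seed")


def _split_path(path: str) -> tuple[str, str]:
    base = path[:-4] if path.endswith(".csv") else path
    return base + ".csv", base + ".json"


def write_sweep(sweep: Sweep, path: str) -> None:
    """Write ``<name>.csv`` (columns ``time_s,value``) and its JSON sidecar.

    Numeric text carries 12 significant digits so the round trip preserves
    values to better than one part in 1e9.
    """
    csv_path, json_path = _split_path(path)
    with open(csv_path, "w", newline="\n") as fh:
        fh.write("time_s,value\n")
        for t, v in zip(sweep.time_s, sweep.values):
            fh.write(f"{t:.12g},{v:.12g}\n")
    meta = dict(sweep.meta)
    sidecar: dict[str, Any] = {
        "rate_hz": sweep.rate_hz,
        "units": sweep.units,
        "channel": sweep.channel,
        "protocol": protocol_to_dict(sweep.protocol),
    }
    for key in _META_KEYS:
        sidecar[key] = meta.pop(key, None)
    if meta:
        sidecar["extra"] = meta
    with open(json_path, "w", newline="\n") as fh:
        json.dump(sidecar, fh, indent=1)
        fh.write("\n")


def read_sweep(path: str) -> Sweep:
    """Read a sweep written by :func:`write_sweep`.

    Raises :class:`TraceFormatError` if the sidecar is missing, the time
    column is non-uniform (relative jitter > 1e-9), or units and channel
    disagree.
    """
    csv_path, json_path = _split_path(path)
    if not os.path.exists(json_path):
        raise TraceFormatError(f"missing sidecar {json_path}")
    if not os.path.exists(csv_path):
        raise TraceFormatError(f"missing trace file {csv_path}")
    with open(json_path) as fh:
        sidecar = json.load(fh)
    try:
        data = np.loadtxt(csv_path, delimiter=",", skiprows=1, ndmin=2)
    except ValueError as exc:
        raise TraceFormatError(f"malformed CSV {csv_path}: {exc}") from exc
    if data.shape[1] != 2:
        raise TraceFormatError(f"{csv_path}: expected 2 columns, got {data.shape[1]}")
    meta = {k: sidecar.get(k) for k in _META_KEYS if sidecar.get(k) is not None}
    meta.update(sidecar.get("extra", {}))
    try:
        return Sweep(
            time_s=data[:, 0],
            values=data[:, 1],
            units=sidecar["units"],
            channel=sidecar["channel"],
            rate_hz=float(sidecar["rate_hz"]),
            protocol=protocol_from_dict(sidecar.get("protocol")),
            meta=meta,
        )
    except KeyError as exc:
        raise TraceFormatError(f"sidecar {json_path} missing key {exc}") from exc


def write_family(family: SweepFamily, dirpath: str) -> None:
    """Write a family as a directory with ``manifest.json`` plus sweep files."""
    os.makedirs(dirpath, exist_ok=True)
    names = [f"sweep_{k:03d}" for k in range(len(family.sweeps))]
    for name, sweep in zip(names, family.sweeps):
        write_sweep(sweep, os.path.join(dirpath, name))
    if isinstance(family.protocol, VClampProtocol):
        prot = protocol_to_dict(family.protocol)
    else:
        prot = [protocol_to_dict(p) for p in family.protocol]
    manifest = {"protocol": prot, "sweeps": [n + ".csv" for n in names]}
    with open(os.path.join(dirpath, "manifest.json"), "w", newline="\n") as fh:
        json.dump(manifest, fh, indent=1)
        fh.write("\n")


def read_family(dirpath: str) -> SweepFamily:
    manifest_path = os.path.join(dirpath, "manifest.json")
    if not os.path.exists(manifest_path):
        raise TraceFormatError(f"missing manifest {manifest_path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    prot = manifest["protocol"]
    protocol = (
        [protocol_from_dict(p) for p in prot]
        if isinstance(prot, list)
        else protocol_from_dict(prot)
    )
    sweeps = [read_sweep(os.path.join(dirpath, name)) for name in manifest["sweeps"]]
    return SweepFamily(protocol=protocol, sweeps=sweeps)


def sweep_checksum(sweep: Sweep) -> str:
    """SHA-256 over samples and metadata; used to assert analyses mutate nothing."""
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(sweep.time_s).tobytes())
    h.update(np.ascontiguousarray(sweep.values).tobytes())
    h.update(json.dumps(sweep.meta, sort_keys=True, default=str).encode())
    return h.hexdigest()
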