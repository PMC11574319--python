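"""Voltage-clamp family analysis: steady-state I/V, leak model, Kv kinetics.

The steady-state I/V takes the mean current 400-450 ms into each voltage
step. The leak model is built from the small steps at -70, -65 and -60 mV
around a -75 mV holding potential: per-step conductances are combined with
driving-force weights (5:10:15), and a per-sample leak *template*,
normalized to unit driving force and zero-phase low-pass filtered at
150 Hz, is scaled by each command's driving force and subtracted to expose
the voltage-gated potassium current. The Kv time constant at each command
is the time at which the leak-subtracted current first reaches
``(1 - 1/e)`` of its maximum over the 150 ms after step onset.

Both the conductance estimate and the template work on baseline-subtracted
currents (each sweep's pre-onset mean removed), which makes the template
zero before the step and the subtraction insensitive to the holding
current.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

from .errors import DegenerateInputError, ProtocolError, WindowError
from .traces import Sweep, SweepFamily, VClampProtocol

__all__ = [
    "IVCurve",
    "LeakModel",
    "KvTauEntry",
    "KvTauResult",
    "steady_state_iv",
    "estimate_leak",
    "subtract_leak",
    "kv_time_constant",
]

IV_WINDOW_S = (0.400, 0.450)  # relative to step onset, half-open
DEFAULT_LEAK_STEPS_MV = (-70.0, -65.0, -60.0)
DEFAULT_KV_COMMANDS_MV = (-10.0, -5.0, 0.0, 5.0, 10.0)
KV_WINDOW_S = 0.150
ONE_MINUS_1_OVER_E = 1.0 - 1.0 / math.e


def _require_vclamp(family: SweepFamily) -> VClampProtocol:
    if not isinstance(family.protocol, VClampProtocol):
        raise ProtocolError("expected a voltage-clamp family")
    if len(family.sweeps) != len(family.protocol.commands_mv):
        raise ProtocolError("family sweep count does not match command count")
    return family.protocol


def _baseline(sweep: Sweep, onset_s: float) -> float:
    base = sweep.window(0.0, onset_s)
    if base.size == 0:
        raise WindowError("no pre-onset baseline samples")
    return float(np.mean(base))


@dataclass(frozen=True)
class IVCurve:
    """Steady-state current per command over the 400-450 ms window."""

    commands_mv: np.ndarray
    i_ss_pa: np.ndarray
    window_s: tuple = IV_WINDOW_S
    sem_pa: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "commands_mv", np.asarray(self.commands_mv, dtype=float))
        object.__setattr__(self, "i_ss_pa", np.asarray(self.i_ss_pa, dtype=float))
        if len(self.commands_mv) != len(self.i_ss_pa):
            raise ValueError("commands and currents must have equal length")

    def at(self, command_mv: float) -> float:
        idx = int(np.argmin(np.abs(self.commands_mv - command_mv)))
        if abs(self.commands_mv[idx] - command_mv) > 1e-6:
            raise KeyError(f"command {command_mv} mV not in curve")
        return float(self.i_ss_pa[idx])


def steady_state_iv(family: SweepFamily) -> IVCurve:
    """Mean current in ``[onset+0.400, onset+0.450)`` per command (raw, pA)."""
    protocol = _require_vclamp(family)
    if protocol.step_duration_s < IV_WINDOW_S[1]:
        raise WindowError(
            f"step duration {protocol.step_duration_s} s shorter than the "
            f"{IV_WINDOW_S[1]} s steady-state window"
        )
    t0 = protocol.onset_s + IV_WINDOW_S[0]
    t1 = protocol.onset_s + IV_WINDOW_S[1]
    i_ss = [float(np.mean(s.window(t0, t1))) for s in family.sweeps]
    return IVCurve(np.asarray(protocol.commands_mv), np.asarray(i_ss))


@dataclass(frozen=True)
class LeakModel:
    """Ohmic leak estimate plus a unit-driving-force leak template."""

    g_leak_ns_hat: float
    template: np.ndarray  # pA per mV of driving force, one sample per sweep sample
    holding_mv: float
    leak_steps_mv: tuple = DEFAULT_LEAK_STEPS_MV
    lp_cutoff_hz: float = 150.0
    weights: tuple = field(default=())

    def predicted_leak_pa(self, command_mv: float) -> np.ndarray:
        """Per-sample leak current at a command (baseline-subtracted scale)."""
        return self.template * (command_mv - self.holding_mv)


def make_lowpass(cutoff_hz: float, rate_hz: float, order: int = 2):
    """Zero-phase low-pass (−3 dB at ``cutoff_hz``) as an array filter."""
    b, a = butter(order, cutoff_hz, fs=rate_hz)
    return lambda x: filtfilt(b, a, x)


def estimate_leak(
    family: SweepFamily,
    leak_steps_mv: tuple = DEFAULT_LEAK_STEPS_MV,
    lp_cutoff_hz: float = 150.0,
    weighting: str = "driving_force",
) -> LeakModel:
    """Build the leak model from the small steps near holding.

    ``weighting='driving_force'`` weights each step's conductance estimate
    by its driving force |V - holding| (5:10:15 for the default steps);
    ``'uniform'`` averages them equally.
    """
    protocol = _require_vclamp(family)
    hold = protocol.holding_mv
    t0 = protocol.onset_s + IV_WINDOW_S[0]
    t1 = protocol.onset_s + IV_WINDOW_S[1]

    g_hats, drives, templates = [], [], []
    for v_step in leak_steps_mv:
        try:
            sweep = family.sweep_for_command(v_step)
        except Exception as exc:
            raise ProtocolError(f"leak step {v_step} mV missing from family") from exc
        drive = v_step - hold
        if abs(drive) < 1.0:
            raise DegenerateInputError(f"driving force |{drive}| mV < 1 mV at {v_step} mV")
        base = _baseline(sweep, protocol.onset_s)
        i_ss = float(np.mean(sweep.window(t0, t1))) - base
        g_hats.append(i_ss / drive)
        drives.append(abs(drive))
        templates.append((sweep.values - base) / drive)

    if weighting == "driving_force":
        w = np.asarray(drives)
    elif weighting == "uniform":
        w = np.ones(len(drives))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    w = w / w.sum()
    g_hat = float(np.dot(w, g_hats))
    template = np.average(np.vstack(templates), axis=0, weights=w)
    template = make_lowpass(lp_cutoff_hz, family.sweeps[0].rate_hz)(template)
    return LeakModel(
        g_leak_ns_hat=g_hat,
        template=template,
        holding_mv=hold,
        leak_steps_mv=tuple(leak_steps_mv),
        lp_cutoff_hz=lp_cutoff_hz,
        weights=tuple(w),
    )


def subtract_leak(family: SweepFamily, leak: LeakModel) -> SweepFamily:
    """Subtract the scaled leak template from every sweep of the family.

    Each corrected trace is the baseline-subtracted raw current minus
    ``template * (command - holding)``.
    """
    protocol = _require_vclamp(family)
    corrected = []
    for cmd, sweep in zip(protocol.commands_mv, family.sweeps):
        if len(sweep.values) != len(leak.template):
            raise ProtocolError(
                f"sweep length {len(sweep.values)} does not match template "
                f"length {len(leak.template)}"
            )
        base = _baseline(sweep, protocol.onset_s)
        values = (sweep.values - base) - leak.predicted_leak_pa(cmd)
        meta = dict(sweep.meta)
        meta["leak_subtracted"] = True
        corrected.append(
            Sweep.from_values(values, sweep.rate_hz, "current", protocol=protocol, meta=meta)
        )
    return SweepFamily(protocol=protocol, sweeps=corrected)


@dataclass(frozen=True)
class KvTauEntry:
    """Kv kinetics at one command: peak current and 1-1/e crossing time."""

    command_mv: float
    i_max_pa: float
    tau_ms: float | None
    crossing_index: int | None
    note: str = ""


@dataclass(frozen=True)
class KvTauResult:
    entries: tuple

    def tau_for(self, command_mv: float) -> float | None:
        for e in self.entries:
            if abs(e.command_mv - command_mv) < 1e-6:
                return e.tau_ms
        raise KeyError(f"command {command_mv} mV not in result")


def kv_time_constant(
    corrected: SweepFamily,
    commands_in_scope: tuple = DEFAULT_KV_COMMANDS_MV,
    interpolate: bool = False,
) -> KvTauResult:
    """Kv time constant per command from a leak-subtracted family.

    ``i_max`` is the maximum over the 150 ms following step onset and tau
    is the time (relative to onset) of the first sample at or above
    ``(1 - 1/e) * i_max``. With ``interpolate=True`` the crossing is
    refined by linear interpolation between the bracketing samples. A
    command with non-positive peak current is recorded with ``tau_ms=None``
    rather than raising.
    """
    protocol = _require_vclamp(corrected)
    entries = []
    for cmd in commands_in_scope:
        sweep = corrected.sweep_for_command(cmd)
        i_on = sweep.index_at(protocol.onset_s)
        i_end = min(i_on + int(round(KV_WINDOW_S * sweep.rate_hz)), len(sweep.values))
        seg = sweep.values[i_on:i_end]
        i_max = float(np.max(seg))
        if i_max <= 0:
            entries.append(KvTauEntry(cmd, i_max, None, None, note="no outward current"))
            continue
        thr = ONE_MINUS_1_OVER_E * i_max
        k = int(np.argmax(seg >= thr))  # first sample at or above threshold
        tau_ms = k / sweep.rate_hz * 1000.0
        if interpolate and k > 0:
            frac = (thr - seg[k - 1]) / (seg[k] - seg[k - 1])
            tau_ms = (k - 1 + frac) / sweep.rate_hz * 1000.0
        entries.append(KvTauEntry(cmd, i_max, float(tau_ms), k))
    return KvTauResult(entries=tuple(entries))
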