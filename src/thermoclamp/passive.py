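"""Passive membrane properties: input resistance and membrane time constant.

Input resistance is the chord resistance ``R = dV_ss / dI`` of a small probe
current step, measured at three conditioning levels (hyperpolarizing DC, no
DC, depolarizing subthreshold DC) around a -75 mV holding potential. The
steady-state deflection is the mean over the last 20% of the probe minus an
equal-length pre-probe baseline.

The membrane time constant comes from a double-exponential least-squares
fit to the relaxation after a brief (5 ms) hyperpolarizing pulse from rest;
the reported value is the slow component, matching the convention of
separating fast (pipette/charging) and slow (membrane) relaxation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import ContaminationError, DegenerateInputError, FitError, ProtocolError, WindowError
from .excitability import detect_spikes
from .traces import StepProtocol, Sweep

__all__ = ["RinLevel", "RinResult", "TauFit", "input_resistance", "membrane_time_constant"]

LEVELS = ("hyperpolarized", "rest", "depolarized")


@dataclass(frozen=True)
class RinLevel:
    """Chord resistance at one conditioning level."""

    label: str
    r_mohm: float
    baseline_mv: float
    probe_window_s: tuple
    baseline_window_s: tuple

    def __post_init__(self):
        if not (np.isfinite(self.r_mohm) and self.r_mohm > 0):
            raise ValueError(f"resistance at {self.label} must be positive and finite")


@dataclass(frozen=True)
class RinResult:
    """Input resistance at the three conditioning levels."""

    hyperpolarized: RinLevel
    rest: RinLevel
    depolarized: RinLevel

    @property
    def r_hyperpolarized_mohm(self) -> float:
        return self.hyperpolarized.r_mohm

    @property
    def r_rest_mohm(self) -> float:
        return self.rest.r_mohm

    @property
    def r_depolarized_mohm(self) -> float:
        return self.depolarized.r_mohm


def _classify_level(protocol: StepProtocol) -> str:
    if protocol.conditioning_pa < 0:
        return "hyperpolarized"
    if protocol.conditioning_pa > 0:
        return "depolarized"
    return "rest"


def input_resistance(sweeps: list, protocols: list) -> RinResult:
    """Chord input resistance (MΩ) per conditioning level.

    ``sweeps`` and ``protocols`` are index-aligned; the three conditioning
    levels (negative, zero, positive ``conditioning_pa``) must each appear
    exactly once. Spikes inside a measurement window raise
    :class:`ContaminationError`; a zero probe amplitude raises
    :class:`DegenerateInputError`.
    """
    if len(sweeps) != len(protocols):
        raise ProtocolError("sweeps and protocols must be index-aligned")
    by_level: dict[str, tuple[Sweep, StepProtocol]] = {}
    for sweep, prot in zip(sweeps, protocols):
        if not isinstance(prot, StepProtocol):
            raise ProtocolError("input resistance expects step protocols")
        label = _classify_level(prot)
        if label in by_level:
            raise ProtocolError(f"duplicate conditioning level {label!r}")
        by_level[label] = (sweep, prot)
    missing = [lv for lv in LEVELS if lv not in by_level]
    if missing:
        raise ProtocolError(f"missing conditioning level(s): {missing}")

    levels = {}
    for label in LEVELS:
        sweep, prot = by_level[label]
        if prot.amplitude_pa == 0:
            raise DegenerateInputError(f"probe amplitude is zero at level {label!r}")
        w = 0.2 * prot.duration_s
        probe_win = (prot.onset_s + prot.duration_s - w, prot.onset_s + prot.duration_s)
        base_win = (prot.onset_s - w, prot.onset_s)
        if base_win[0] < 0:
            raise WindowError("pre-probe baseline window precedes the sweep start")
        spikes = detect_spikes(sweep)
        for t0, t1 in (base_win, probe_win):
            if np.any((spikes.spike_times_s >= t0) & (spikes.spike_times_s < t1)):
                raise ContaminationError(
                    f"spike inside measurement window [{t0:.3f}, {t1:.3f}) at level {label!r}"
                )
        dv = float(np.mean(sweep.window(*probe_win)) - np.mean(sweep.window(*base_win)))
        r_mohm = dv / prot.amplitude_pa * 1000.0  # mV/pA = GΩ -> MΩ
        levels[label] = RinLevel(
            label=label,
            r_mohm=r_mohm,
            baseline_mv=float(np.mean(sweep.window(*base_win))),
            probe_window_s=probe_win,
            baseline_window_s=base_win,
        )
    return RinResult(levels["hyperpolarized"], levels["rest"], levels["depolarized"])


# ---------------------------------------------------------------------------
# membrane time constant
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TauFit:
    """Double-exponential fit ``v_ss + a_f e^(-t/tau_f) + a_s e^(-t/tau_s)``."""

    a_fast_mv: float
    tau_fast_ms: float
    a_slow_mv: float
    tau_slow_ms: float
    v_ss_mv: float
    rss: float

    def __post_init__(self):
        if not (0 < self.tau_fast_ms <= self.tau_slow_ms):
            raise ValueError("need 0 < tau_fast <= tau_slow")

    @property
    def reported_tau_ms(self) -> float:
        """The membrane time constant: the slow component."""
        return self.tau_slow_ms

    def predict(self, t_ms: np.ndarray) -> np.ndarray:
        return (
            self.v_ss_mv
            + self.a_fast_mv * np.exp(-t_ms / self.tau_fast_ms)
            + self.a_slow_mv * np.exp(-t_ms / self.tau_slow_ms)
        )


_TAU_BOUNDS_MS = (0.05, 500.0)
_TAU_GRID_MS = np.geomspace(0.2, 50.0, 8)


def _fit_once(t_ms, v, x0):
    lo = [-np.inf, _TAU_BOUNDS_MS[0], -np.inf, _TAU_BOUNDS_MS[0], -np.inf]
    hi = [np.inf, _TAU_BOUNDS_MS[1], np.inf, _TAU_BOUNDS_MS[1], np.inf]

    def resid(x):
        af, tf, as_, ts, vss = x
        return vss + af * np.exp(-t_ms / tf) + as_ * np.exp(-t_ms / ts) - v

    return least_squares(resid, x0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12)


def membrane_time_constant(
    sweep: Sweep,
    pulse: StepProtocol,
    fit_duration_s: float | None = None,
    starts: np.ndarray = _TAU_GRID_MS,
) -> TauFit:
    """Fit the post-pulse relaxation with a double exponential.

    The fit segment starts two samples after pulse offset (skipping the
    stimulus edge) and must span at least 50 ms. Eight multi-start
    initializations on a log-spaced slow-tau grid are tried; the lowest
    residual sum of squares wins, with ties broken toward the smaller slow
    tau. Components are ordered so ``tau_fast <= tau_slow``.
    """
    if pulse.amplitude_pa >= 0:
        raise ProtocolError("membrane time constant requires a hyperpolarizing pulse")
    offset_s = pulse.onset_s + pulse.duration_s
    i0 = sweep.index_at(offset_s) + 2
    i1 = len(sweep.values) if fit_duration_s is None else min(
        len(sweep.values), i0 + int(round(fit_duration_s * sweep.rate_hz))
    )
    if (i1 - i0) / sweep.rate_hz < 0.050:
        raise WindowError("relaxation segment shorter than 50 ms")
    spikes = detect_spikes(sweep)
    if np.any(spikes.spike_times_s >= sweep.time_s[i0]):
        raise ContaminationError("spike inside the relaxation segment")

    t_ms = (sweep.time_s[i0:i1] - sweep.time_s[i0]) * 1000.0
    v = sweep.values[i0:i1]
    v_ss0 = float(np.mean(v[-max(len(v) // 10, 1) :]))
    amp0 = float(v[0] - v_ss0)

    candidates = []
    for ts0 in starts:
        tf0 = max(ts0 / 5.0, _TAU_BOUNDS_MS[0] * 1.2)
        x0 = [0.0, tf0, amp0, ts0, v_ss0]
        res = _fit_once(t_ms, v, x0)
        if res.status <= 0 or not np.isfinite(res.cost):
            continue
        af, tf, as_, ts, vss = res.x
        if tf > ts:  # enforce fast < slow by swapping components
            af, tf, as_, ts = as_, ts, af, tf
        if abs(as_) < 1e-4 * abs(af):
            # effectively single-exponential with the mass in the fast slot:
            # relabel the dominant component as the (reported) slow one
            as_, ts, af, tf = af, tf, 0.0, tf
        candidates.append((2.0 * res.cost, ts, af, tf, as_, vss))
    if not candidates:
        raise FitError("double-exponential fit failed to converge from any start")
    best_rss = min(c[0] for c in candidates)
    tol = best_rss * (1.0 + 1e-9) + 1e-300
    rss, ts, af, tf, as_, vss = min(
        (c for c in candidates if c[0] <= tol), key=lambda c: c[1]
    )
    return TauFit(
        a_fast_mv=float(af),
        tau_fast_ms=float(tf),
        a_slow_mv=float(as_),
        tau_slow_ms=float(ts),
        v_ss_mv=float(vss),
        rss=float(rss),
    )
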