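"""Thermal-log analysis: stability, equilibration, duty ratio, look-up table.

All statistics are pure functions of the logged samples (no interpolation).
The default assessment window mirrors bench practice: a 5-minute window
starting 20 minutes after heater activation (about 10 minutes of ramp-up
plus 10 minutes of equilibration). The look-up table maps perfusate flow
rate to the heater setpoint required for a target bath temperature, found
by bisection against the thermostat simulator — with the temperature probe
on the heater block, higher flow rates need higher setpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import CapacityError, WindowError
from .thermostat import ThermalParams, ThermalTrace, simulate_thermostat

__all__ = [
    "ChannelStats",
    "ThermalStats",
    "LookupRow",
    "LookupTable",
    "stability_metrics",
    "equilibration_time",
    "duty_ratio",
    "build_lookup_table",
    "DEFAULT_ASSESSMENT_WINDOW_S",
]

#: 5 minutes starting 20 minutes after activation
DEFAULT_ASSESSMENT_WINDOW_S = (1200.0, 1500.0)


@dataclass(frozen=True)
class ChannelStats:
    mean_c: float
    sd_c: float
    min_c: float
    max_c: float

    @property
    def range_c(self) -> float:
        return self.max_c - self.min_c


@dataclass(frozen=True)
class ThermalStats:
    """Descriptive statistics per channel over an assessment window."""

    bath: ChannelStats
    heater: ChannelStats
    window_s: tuple
    n_samples: int


def _window_mask(trace: ThermalTrace, window: tuple) -> np.ndarray:
    t0, t1 = window
    mask = (trace.time_s >= t0) & (trace.time_s < t1)
    if not np.any(mask):
        raise WindowError(f"no log samples in window [{t0}, {t1})")
    return mask


def _channel_stats(x: np.ndarray) -> ChannelStats:
    # population sd: these are descriptive statistics of the logged window
    return ChannelStats(
        mean_c=float(np.mean(x)),
        sd_c=float(np.std(x)),
        min_c=float(np.min(x)),
        max_c=float(np.max(x)),
    )


def stability_metrics(trace: ThermalTrace, window: tuple) -> ThermalStats:
    """Mean/sd/min/max/range of bath and heater over ``[t0, t1)``."""
    mask = _window_mask(trace, window)
    return ThermalStats(
        bath=_channel_stats(trace.t_bath_c[mask]),
        heater=_channel_stats(trace.t_heater_c[mask]),
        window_s=tuple(window),
        n_samples=int(mask.sum()),
    )


def equilibration_time(
    trace: ThermalTrace, band_c: float, hold_s: float
) -> float | None:
    """First time the bath stays within ±band of its final mean for ``hold_s``.

    The reference is the mean bath temperature over the trailing ``hold_s``
    of the trace. Returns ``None`` if the bath never holds the band.
    """
    if band_c <= 0:
        raise ValueError("band_c must be positive")
    t = trace.time_s
    if hold_s > t[-1] - t[0]:
        raise WindowError("hold_s longer than the trace")
    ref = float(np.mean(trace.t_bath_c[t >= t[-1] - hold_s]))
    ok = np.abs(trace.t_bath_c - ref) <= band_c
    for i in range(len(t)):
        if t[i] + hold_s > t[-1] + 1e-9:
            break  # hold window no longer fully observable
        j = int(np.searchsorted(t, t[i] + hold_s, side="left"))
        if np.all(ok[i:max(j, i + 1)]):
            return float(t[i])
    return None


def duty_ratio(trace: ThermalTrace, window: tuple) -> float:
    """Fraction of window log samples with the heating relay closed."""
    mask = _window_mask(trace, window)
    return float(np.mean(trace.relay[mask]))


@dataclass(frozen=True)
class LookupRow:
    flow_ml_per_min: float
    setpoint_c: float
    achieved_bath_c: float

    @property
    def differential_c(self) -> float:
        return self.setpoint_c - self.achieved_bath_c


@dataclass(frozen=True)
class LookupTable:
    """Flow-rate → heater-setpoint map for a fixed target bath temperature."""

    target_bath_c: float
    rows: tuple

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "flow_ml_per_min": [r.flow_ml_per_min for r in self.rows],
                "setpoint_c": [r.setpoint_c for r in self.rows],
                "achieved_bath_c": [r.achieved_bath_c for r in self.rows],
                "differential_c": [r.differential_c for r in self.rows],
            }
        )


def _steady_bath(params: ThermalParams, sim_duration_s: float) -> float:
    trace = simulate_thermostat(params, sim_duration_s)
    i0 = int(0.75 * len(trace.time_s))  # last 25% of the run
    return float(np.mean(trace.t_bath_c[i0:]))


def build_lookup_table(
    thermal: ThermalParams,
    target_bath_c: float,
    flows: tuple,
    tolerance_c: float = 0.05,
    max_iter: int = 40,
    sim_duration_s: float = 3600.0,
) -> LookupTable:
    """Bisection on the setpoint until the steady-state bath hits the target.

    Bounds are ``[target, target + 60]`` degC. Raises
    :class:`CapacityError` if the model cannot reach the target even at
    the upper bound.
    """
    if target_bath_c <= thermal.t_ambient_c:
        raise ValueError("target must be above ambient")
    rows = []
    for flow in sorted(flows):
        p = replace(thermal, flow_ml_per_min=flow)
        lo, hi = target_bath_c, target_bath_c + 60.0
        if _steady_bath(replace(p, setpoint_c=hi), sim_duration_s) < target_bath_c - tolerance_c:
            raise CapacityError(
                f"target {target_bath_c} degC unreachable at flow {flow} ml/min "
                f"with setpoint bound {hi} degC"
            )
        achieved = None
        setpoint = hi
        for _ in range(max_iter):
            mid = 0.5 * (lo + hi)
            bath = _steady_bath(replace(p, setpoint_c=mid), sim_duration_s)
            if abs(bath - target_bath_c) <= tolerance_c:
                setpoint, achieved = mid, bath
                break
            if bath < target_bath_c:
                lo = mid
            else:
                hi = mid
        if achieved is None:
            raise CapacityError(
                f"bisection did not converge to ±{tolerance_c} degC at flow {flow}"
            )
        rows.append(LookupRow(flow, setpoint, achieved))
    return LookupTable(target_bath_c=target_bath_c, rows=tuple(rows))
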