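"""Bang-bang (hysteresis) perfusion-heater simulator.

Lumped two-node thermal model of an in-line perfusate heater feeding a
recording bath:

* heater block: ``C_h dT_h/dt = P*relay - k_ha (T_h - T_amb) - W``
* bath:        ``C_b dT_b/dt = D - k_ba (T_b - T_amb)``

where the perfusate (volumetric heat-capacity rate ``C_q = rho*c*Q``, with
``rho*c`` = 4.186 J/(ml*K) for water) enters the exchanger at ambient
temperature, leaves it at ``T_out = T_amb + eps (T_h - T_amb)`` with
exchanger effectiveness ``eps(Q) = 1 - exp(-k_exchange / C_q)``, draws
``W = eps C_q (T_h - T_amb)`` from the heater block, and delivers
``D = C_q (T_out - T_b)`` to the bath.

The relay follows the hysteresis rule of an off-the-shelf thermostat: it
closes when the heater probe falls to ``setpoint - hysteresis`` and opens
when it reaches the setpoint. Integration is explicit Euler at
``dt_s <= 0.1 s``; temperatures are logged every ``log_interval_s``
(10 s by default, the cadence of a bench multichannel thermometer).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import StabilityError

__all__ = [
    "ThermalParams",
    "ThermalTrace",
    "simulate_thermostat",
    "WATER_RHO_C_J_PER_ML_K",
]

#: volumetric heat capacity of water, J/(ml*K)
WATER_RHO_C_J_PER_ML_K = 4.186


@dataclass(frozen=True)
class ThermalParams:
    """Lumped thermal-model and controller parameters (SI, flow in ml/min)."""

    c_heater_j_per_k: float = 80.0
    c_bath_j_per_k: float = 40.0
    p_on_w: float = 25.0
    k_heater_amb_w_per_k: float = 0.3
    k_bath_amb_w_per_k: float = 0.05
    k_exchange_w_per_k: float = 0.18
    flow_ml_per_min: float = 6.5
    t_ambient_c: float = 23.0
    setpoint_c: float = 57.0
    hysteresis_c: float = 0.3
    dt_s: float = 0.1
    log_interval_s: float = 10.0

    def __post_init__(self):
        for name in (
            "c_heater_j_per_k", "c_bath_j_per_k", "p_on_w",
            "k_heater_amb_w_per_k", "k_bath_amb_w_per_k", "k_exchange_w_per_k",
            "flow_ml_per_min",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.hysteresis_c <= 0:
            raise ValueError("hysteresis_c must be positive")
        if self.dt_s <= 0 or self.dt_s > self.log_interval_s:
            raise ValueError("need 0 < dt_s <= log_interval_s")

    @property
    def flow_heat_rate_w_per_k(self) -> float:
        """Perfusate heat-capacity rate rho*c*Q in W/K."""
        return WATER_RHO_C_J_PER_ML_K * self.flow_ml_per_min / 60.0

    @property
    def effectiveness(self) -> float:
        """Heat-exchanger effectiveness eps(Q) in (0, 1)."""
        return 1.0 - math.exp(-self.k_exchange_w_per_k / self.flow_heat_rate_w_per_k)


@dataclass
class ThermalTrace:
    """Logged heater/bath temperatures with relay state, at the log cadence."""

    time_s: np.ndarray
    t_heater_c: np.ndarray
    t_bath_c: np.ndarray
    relay: np.ndarray
    flow_ml_per_min: float
    setpoint_c: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.t_heater_c = np.asarray(self.t_heater_c, dtype=float)
        self.t_bath_c = np.asarray(self.t_bath_c, dtype=float)
        self.relay = np.asarray(self.relay, dtype=int)
        n = len(self.time_s)
        if not (len(self.t_heater_c) == len(self.t_bath_c) == len(self.relay) == n):
            raise ValueError("all channels must have equal length")
        if not np.all(np.isin(self.relay, (0, 1))):
            raise ValueError("relay samples must be 0 or 1")

    def to_csv(self, path: str) -> None:
        pd.DataFrame(
            {
                "time_s": self.time_s,
                "t_heater_c": self.t_heater_c,
                "t_bath_c": self.t_bath_c,
                "relay": self.relay,
            }
        ).to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def from_csv(
        cls, path: str, flow_ml_per_min: float = float("nan"), setpoint_c: float = float("nan")
    ) -> "ThermalTrace":
        df = pd.read_csv(path)
        return cls(
            df["time_s"].to_numpy(),
            df["t_heater_c"].to_numpy(),
            df["t_bath_c"].to_numpy(),
            df["relay"].to_numpy(),
            flow_ml_per_min,
            setpoint_c,
        )


def simulate_thermostat(
    params: ThermalParams,
    duration_s: float,
    t0_heater_c: float | None = None,
    t0_bath_c: float | None = None,
) -> ThermalTrace:
    """Integrate the thermal model for ``duration_s`` and log the channels.

    Initial temperatures default to ambient (a cold start). Raises
    :class:`StabilityError` if a single Euler step would move a temperature
    by more than 5 degC.
    """
    th = params.t_ambient_c if t0_heater_c is None else t0_heater_c
    tb = params.t_ambient_c if t0_bath_c is None else t0_bath_c
    dt = params.dt_s
    cq = params.flow_heat_rate_w_per_k
    eps = params.effectiveness
    k_ha = params.k_heater_amb_w_per_k
    k_ba = params.k_bath_amb_w_per_k
    t_amb = params.t_ambient_c
    on_below = params.setpoint_c - params.hysteresis_c
    off_at = params.setpoint_c

    n_steps = int(round(duration_s / dt))
    log_every = int(round(params.log_interval_s / dt))
    relay = 1 if th <= on_below else 0

    times, heaters, baths, relays = [0.0], [th], [tb], [relay]
    for k in range(1, n_steps + 1):
        if th <= on_below:
            relay = 1
        elif th >= off_at:
            relay = 0
        w_draw = eps * cq * (th - t_amb)
        t_out = t_amb + eps * (th - t_amb)
        delivery = cq * (t_out - tb)
        dth = (params.p_on_w * relay - k_ha * (th - t_amb) - w_draw) / params.c_heater_j_per_k * dt
        dtb = (delivery - k_ba * (tb - t_amb)) / params.c_bath_j_per_k * dt
        if abs(dth) > 5.0 or abs(dtb) > 5.0:
            raise StabilityError(
                f"state change {max(abs(dth), abs(dtb)):.2f} degC in one step at "
                f"t = {k * dt:.1f} s; reduce dt_s"
            )
        th += dth
        tb += dtb
        if k % log_every == 0:
            times.append(k * dt)
            heaters.append(th)
            baths.append(tb)
            relays.append(relay)
    return ThermalTrace(
        np.array(times), np.array(heaters), np.array(baths), np.array(relays),
        params.flow_ml_per_min, params.setpoint_c,
        meta={"t_ambient_c": t_amb, "hysteresis_c": params.hysteresis_c},
    )
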