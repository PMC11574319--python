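"""Temperature-scaled conductance-model neuron for synthetic patch-clamp data.

Single-compartment membrane with four currents:

* ohmic leak ``g_l (V - E_l)``,
* inward-rectifier potassium current ``g_kir kir_inf(V) (V - E_K)`` with an
  instantaneous Boltzmann activation that deactivates on depolarization
  (this produces the characteristic rise of input resistance with
  depolarization of striatal projection neurons),
* fast sodium current ``g_na m^3 h (V - E_Na)``,
* delayed-rectifier potassium current ``g_kv n^4 (V - E_K)``,

with classic squid-style rate functions shifted so the spike threshold sits
near -45 mV. Temperature enters through two Q10 factors relative to a
reference temperature: ``q10_rates`` multiplies every gating rate constant
and ``q10_cond`` multiplies every maximal conductance by
``q10^((T - T_ref)/10)``.

Current-clamp sweeps are integrated with fixed-step 4th-order Runge-Kutta at
dt = 0.01 ms (numba-compiled) and decimated to the 20 kHz acquisition rate.
Under ideal voltage clamp the membrane potential is piecewise constant, so
each gating ODE is linear with constant coefficients and the same RK4
discretization collapses to an exact geometric recurrence, which is what
:func:`simulate_voltage_clamp` evaluates.

The default parameter set is an artifact choice (documented in the methods
note), tuned to the qualitative phenotype of a striatal medium spiny neuron:
resting potential near -85 mV before holding current, input resistance near
90 MΩ at -75 mV, and strong inward rectification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numba import njit
from scipy.optimize import brentq

from .errors import SimulationError
from .traces import RampProtocol, StepProtocol, Sweep, SweepFamily, VClampProtocol

__all__ = [
    "NeuronParams",
    "MSN_DEFAULTS",
    "simulate_current_clamp",
    "simulate_voltage_clamp",
    "resting_potential",
    "holding_current",
    "steady_state_current",
]

#: rate functions are evaluated at V - V_SHIFT_MV; +10 mV moves the classic
#: squid threshold (~ -55 mV) to ~ -45 mV, appropriate for MSNs
V_SHIFT_MV = 10.0

_DT_MS = 0.01  # fine integration step, ms


@dataclass(frozen=True)
class NeuronParams:
    """Conductance-model parameters (pF, nS, mV) plus Q10 specification."""

    c_pf: float = 100.0
    g_leak_ns: float = 4.7
    e_leak_mv: float = -70.0
    g_kir_ns: float = 25.0
    kir_vhalf_mv: float = -80.0
    kir_slope_mv: float = 20.0
    e_k_mv: float = -90.0
    g_na_ns: float = 3600.0
    e_na_mv: float = 60.0
    g_kv_ns: float = 360.0
    q10_rates: float = 3.0
    q10_cond: float = 1.4
    t_ref_c: float = 23.0

    def __post_init__(self):
        if self.c_pf <= 0:
            raise ValueError("capacitance must be positive")
        for name in ("g_leak_ns", "g_kir_ns", "g_na_ns", "g_kv_ns"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.q10_rates < 1 or self.q10_cond < 1:
            raise ValueError("Q10 factors must be >= 1")
        if self.kir_slope_mv <= 0:
            raise ValueError("kir_slope_mv must be positive")

    def temperature_factors(self, temperature_c: float) -> tuple[float, float]:
        """(rate multiplier, conductance multiplier) at ``temperature_c``."""
        d = (temperature_c - self.t_ref_c) / 10.0
        return self.q10_rates**d, self.q10_cond**d

    @classmethod
    def passive(cls, r_mohm: float, c_pf: float, e_leak_mv: float = -75.0) -> "NeuronParams":
        """Purely passive RC cell with input resistance ``r_mohm``."""
        return cls(
            c_pf=c_pf,
            g_leak_ns=1000.0 / r_mohm,
            e_leak_mv=e_leak_mv,
            g_kir_ns=0.0,
            g_na_ns=0.0,
            g_kv_ns=0.0,
        )

    def with_ttx(self) -> "NeuronParams":
        """Copy with sodium conductance blocked."""
        return replace(self, g_na_ns=0.0)


#: default medium-spiny-neuron-like parameter set
MSN_DEFAULTS = NeuronParams()


# ---------------------------------------------------------------------------
# gating rate functions (V in mV, rates in 1/ms); callable from Python & numba
# ---------------------------------------------------------------------------


@njit(cache=True)
def _vtrap(x: float, y: float) -> float:
    # x / (1 - exp(-x/y)) with the removable singularity at x = 0 filled in
    if abs(x / y) < 1e-6:
        return y * (1.0 + x / (2.0 * y))
    return x / (1.0 - math.exp(-x / y))


@njit(cache=True)
def _alpha_m(vs: float) -> float:
    return 0.1 * _vtrap(vs + 40.0, 10.0)


@njit(cache=True)
def _beta_m(vs: float) -> float:
    return 4.0 * math.exp(-(vs + 65.0) / 18.0)


@njit(cache=True)
def _alpha_h(vs: float) -> float:
    return 0.07 * math.exp(-(vs + 65.0) / 20.0)


@njit(cache=True)
def _beta_h(vs: float) -> float:
    return 1.0 / (1.0 + math.exp(-(vs + 35.0) / 10.0))


@njit(cache=True)
def _alpha_n(vs: float) -> float:
    return 0.01 * _vtrap(vs + 55.0, 10.0)


@njit(cache=True)
def _beta_n(vs: float) -> float:
    return 0.125 * math.exp(-(vs + 65.0) / 80.0)


@njit(cache=True)
def _kir_inf(v: float, vhalf: float, slope: float) -> float:
    return 1.0 / (1.0 + math.exp((v - vhalf) / slope))


def gate_steady_state(v_mv: float) -> tuple[float, float, float]:
    """Steady-state (m, h, n) at membrane potential ``v_mv``."""
    vs = v_mv - V_SHIFT_MV
    m = _alpha_m(vs) / (_alpha_m(vs) + _beta_m(vs))
    h = _alpha_h(vs) / (_alpha_h(vs) + _beta_h(vs))
    n = _alpha_n(vs) / (_alpha_n(vs) + _beta_n(vs))
    return m, h, n


def steady_state_current(params: NeuronParams, temperature_c: float, v_mv: float) -> float:
    """Total steady-state ionic current (pA, outward positive) at ``v_mv``.

    All gates at their voltage-dependent steady state; used by the
    holding-current solver and by finite-difference oracles in tests.
    """
    _, kg = params.temperature_factors(temperature_c)
    m, h, n = gate_steady_state(v_mv)
    i = params.g_leak_ns * (v_mv - params.e_leak_mv)
    i += params.g_kir_ns * _kir_inf(v_mv, params.kir_vhalf_mv, params.kir_slope_mv) * (
        v_mv - params.e_k_mv
    )
    i += params.g_na_ns * m**3 * h * (v_mv - params.e_na_mv)
    i += params.g_kv_ns * n**4 * (v_mv - params.e_k_mv)
    return kg * i


def resting_potential(
    params: NeuronParams,
    temperature_c: float,
    i_dc_pa: float = 0.0,
    v_bounds: tuple[float, float] = (-120.0, -48.0),
) -> float:
    """Resting potential under DC current ``i_dc_pa``, from the current balance.

    Solves ``I_ss(V) = i_dc`` on the subthreshold branch where the
    steady-state I-V curve is monotone.
    """
    lo, hi = v_bounds
    f = lambda v: steady_state_current(params, temperature_c, v) - i_dc_pa
    if f(lo) > 0 or f(hi) < 0:
        raise SimulationError(
            f"no subthreshold resting potential in [{lo}, {hi}] mV for {i_dc_pa} pA"
        )
    return float(brentq(f, lo, hi, xtol=1e-10))


def holding_current(
    params: NeuronParams,
    temperature_c: float,
    target_mv: float = -75.0,
    tol_mv: float = 0.05,
    max_iter: int = 80,
) -> float:
    """DC holding current (pA) that rests the cell within ``tol_mv`` of target.

    Bisection on the injected DC current; the resting potential for each
    candidate current comes from the steady-state current balance.
    """
    i_lo = steady_state_current(params, temperature_c, target_mv - 25.0)
    i_hi = steady_state_current(params, temperature_c, target_mv + 15.0)
    for _ in range(max_iter):
        i_mid = 0.5 * (i_lo + i_hi)
        v = resting_potential(params, temperature_c, i_mid)
        if abs(v - target_mv) <= tol_mv:
            return i_mid
        if v < target_mv:
            i_lo = i_mid
        else:
            i_hi = i_mid
    raise SimulationError("holding-current bisection did not converge")


# ---------------------------------------------------------------------------
# current clamp: fixed-step RK4 at dt = 0.01 ms, decimated to the output rate
# ---------------------------------------------------------------------------


@njit(cache=True)
def _derivs(v, m, h, n, i_inj, gl, el, gkir, vh, ks, ek, gna, ena, gkv, c, kr):
    vs = v - V_SHIFT_MV
    i_ion = gl * (v - el)
    i_ion += gkir * _kir_inf(v, vh, ks) * (v - ek)
    i_ion += gna * m * m * m * h * (v - ena)
    i_ion += gkv * n * n * n * n * (v - ek)
    dv = (i_inj - i_ion) / c
    dm = kr * (_alpha_m(vs) * (1.0 - m) - _beta_m(vs) * m)
    dh = kr * (_alpha_h(vs) * (1.0 - h) - _beta_h(vs) * h)
    dn = kr * (_alpha_n(vs) * (1.0 - n) - _beta_n(vs) * n)
    return dv, dm, dh, dn


@njit(cache=True)
def _inj_current(t_ms, i_dc, kind, p0, p1, onset_ms, dur_ms):
    # kind 0: step of amplitude p0; kind 1: ramp from p0 at slope p1 (pA/ms)
    if onset_ms <= t_ms < onset_ms + dur_ms:
        if kind == 0:
            return i_dc + p0
        return i_dc + p0 + p1 * (t_ms - onset_ms)
    return i_dc


@njit(cache=True)
def _integrate_cc(
    v0, m0, h0, n0,
    gl, el, gkir, vh, ks, ek, gna, ena, gkv, c, kr,
    i_dc, kind, p0, p1, onset_ms, dur_ms,
    dt, decim, out,
):
    v, m, h, n = v0, m0, h0, n0
    out[0] = v
    n_fine = (out.shape[0] - 1) * decim
    for k in range(n_fine):
        t = k * dt
        i1 = _inj_current(t, i_dc, kind, p0, p1, onset_ms, dur_ms)
        i2 = _inj_current(t + 0.5 * dt, i_dc, kind, p0, p1, onset_ms, dur_ms)
        i3 = _inj_current(t + dt, i_dc, kind, p0, p1, onset_ms, dur_ms)
        a1, b1, c1, d1 = _derivs(v, m, h, n, i1, gl, el, gkir, vh, ks, ek, gna, ena, gkv, c, kr)
        a2, b2, c2, d2 = _derivs(
            v + 0.5 * dt * a1, m + 0.5 * dt * b1, h + 0.5 * dt * c1, n + 0.5 * dt * d1,
            i2, gl, el, gkir, vh, ks, ek, gna, ena, gkv, c, kr,
        )
        a3, b3, c3, d3 = _derivs(
            v + 0.5 * dt * a2, m + 0.5 * dt * b2, h + 0.5 * dt * c2, n + 0.5 * dt * d2,
            i2, gl, el, gkir, vh, ks, ek, gna, ena, gkv, c, kr,
        )
        a4, b4, c4, d4 = _derivs(
            v + dt * a3, m + dt * b3, h + dt * c3, n + dt * d3,
            i3, gl, el, gkir, vh, ks, ek, gna, ena, gkv, c, kr,
        )
        v = v + dt / 6.0 * (a1 + 2.0 * a2 + 2.0 * a3 + a4)
        m = m + dt / 6.0 * (b1 + 2.0 * b2 + 2.0 * b3 + b4)
        h = h + dt / 6.0 * (c1 + 2.0 * c2 + 2.0 * c3 + c4)
        n = n + dt / 6.0 * (d1 + 2.0 * d2 + 2.0 * d3 + d4)
        if not (math.isfinite(v) and math.isfinite(m) and math.isfinite(h) and math.isfinite(n)):
            return k + 1
        if (k + 1) % decim == 0:
            out[(k + 1) // decim] = v
    return 0


def simulate_current_clamp(
    params: NeuronParams,
    stimulus: StepProtocol | RampProtocol,
    temperature_c: float = 23.0,
    holding_target_mv: float = -75.0,
    seed: int = 0,
    rate_hz: float = 2.0e4,
    tail_s: float = 0.1,
) -> Sweep:
    """Simulate a current-clamp sweep at the given bath temperature.

    A DC holding current is solved first so the cell rests within 0.5 mV of
    ``holding_target_mv``; the stimulus rides on top of it. The sweep spans
    ``[0, onset + duration + tail)`` and is sampled at ``rate_hz``. The
    simulation is deterministic; ``seed`` is recorded in the metadata for
    provenance only.
    """
    kr, kg = params.temperature_factors(temperature_c)
    i_hold = holding_current(params, temperature_c, holding_target_mv)

    if isinstance(stimulus, StepProtocol):
        kind, p0, p1 = 0, stimulus.amplitude_pa, 0.0
        i_dc = i_hold + stimulus.baseline_pa + stimulus.conditioning_pa
    elif isinstance(stimulus, RampProtocol):
        kind, p0, p1 = 1, stimulus.start_pa, stimulus.slope_pa_per_s / 1000.0
        i_dc = i_hold
    else:
        raise TypeError("stimulus must be a StepProtocol or RampProtocol")

    v0 = resting_potential(params, temperature_c, i_dc)
    m0, h0, n0 = gate_steady_state(v0)

    duration_s = stimulus.onset_s + stimulus.duration_s + tail_s
    n_out = int(round(duration_s * rate_hz))
    dt_out_ms = 1000.0 / rate_hz
    decim = int(round(dt_out_ms / _DT_MS))
    out = np.empty(n_out, dtype=np.float64)
    bad = _integrate_cc(
        v0, m0, h0, n0,
        kg * params.g_leak_ns, params.e_leak_mv,
        kg * params.g_kir_ns, params.kir_vhalf_mv, params.kir_slope_mv, params.e_k_mv,
        kg * params.g_na_ns, params.e_na_mv, kg * params.g_kv_ns,
        params.c_pf, kr,
        i_dc, kind, p0, p1, stimulus.onset_s * 1000.0, stimulus.duration_s * 1000.0,
        _DT_MS, decim, out,
    )
    if bad:
        raise SimulationError(
            f"non-finite state at integration step {bad} (t = {bad * _DT_MS:.3f} ms)"
        )
    meta = {
        "temperature_c": temperature_c,
        "seed": seed,
        "holding_pa": i_hold,
        "holding_target_mv": holding_target_mv,
    }
    return Sweep.from_values(out, rate_hz, "voltage", protocol=stimulus, meta=meta)


# ---------------------------------------------------------------------------
# voltage clamp: exact RK4 propagator of the linear gating ODEs
# ---------------------------------------------------------------------------


def _rk4_factor(b: float, dt: float, nsub: int) -> float:
    """Per-output-sample amplification of RK4 applied to y' = -b (y - y_inf)."""
    z = -b * dt
    phi = 1.0 + z + z**2 / 2.0 + z**3 / 6.0 + z**4 / 24.0
    return phi**nsub


def _gate_segment(
    x0: float, v_mv: float, kr: float, n_samples: int, rates, rate_hz: float
) -> np.ndarray:
    """Gate trajectory at the output rate over a constant-voltage segment."""
    alpha_f, beta_f = rates
    vs = v_mv - V_SHIFT_MV
    a, b = alpha_f(vs) * kr, beta_f(vs) * kr
    tot = a + b
    x_inf = a / tot
    nsub = int(round((1000.0 / rate_hz) / _DT_MS))  # fine steps per output sample
    r = _rk4_factor(tot, _DT_MS, nsub)
    k = np.arange(n_samples)
    return x_inf + (x0 - x_inf) * np.power(r, k)


def simulate_voltage_clamp(
    params: NeuronParams,
    protocol: VClampProtocol = VClampProtocol(),
    temperature_c: float = 23.0,
    seed: int = 0,
    rate_hz: float = 2.0e4,
) -> SweepFamily:
    """Simulate an ideal-clamp voltage-step family (one current sweep/command).

    The clamp is ideal: the membrane potential equals the command instantly,
    so within each hold/step/tail segment the gating ODEs are linear and are
    advanced with the exact propagator of the RK4 discretization at
    dt = 0.01 ms. With ``protocol.ttx`` the sodium conductance is zero.
    """
    kr, kg = params.temperature_factors(temperature_c)
    p = params.with_ttx() if protocol.ttx else params
    hold = protocol.holding_mv

    n_total = int(round(protocol.sweep_duration_s * rate_hz))
    i_on = int(round(protocol.onset_s * rate_hz))
    i_off = int(round((protocol.onset_s + protocol.step_duration_s) * rate_hz))

    m_rates = (_alpha_m, _beta_m)
    h_rates = (_alpha_h, _beta_h)
    n_rates = (_alpha_n, _beta_n)
    m0, h0, n0 = gate_steady_state(hold)

    sweeps = []
    for cmd in protocol.commands_mv:
        v = np.empty(n_total)
        v[:i_on] = hold
        v[i_on:i_off] = cmd
        v[i_off:] = hold
        m = np.empty(n_total)
        h = np.empty(n_total)
        n = np.empty(n_total)
        for (x, x0, rates) in ((m, m0, m_rates), (h, h0, h_rates), (n, n0, n_rates)):
            x[:i_on] = x0
            seg = _gate_segment(x0, cmd, kr, i_off - i_on + 1, rates, rate_hz)
            x[i_on:i_off] = seg[:-1]
            x[i_off:] = _gate_segment(seg[-1], hold, kr, n_total - i_off, rates, rate_hz)
        i_pa = p.g_leak_ns * (v - p.e_leak_mv)
        kir = 1.0 / (1.0 + np.exp((v - p.kir_vhalf_mv) / p.kir_slope_mv))
        i_pa += p.g_kir_ns * kir * (v - p.e_k_mv)
        i_pa += p.g_na_ns * m**3 * h * (v - p.e_na_mv)
        i_pa += p.g_kv_ns * n**4 * (v - p.e_k_mv)
        i_pa *= kg
        if not np.all(np.isfinite(i_pa)):
            bad = int(np.flatnonzero(~np.isfinite(i_pa))[0])
            raise SimulationError(f"non-finite clamp current at sample {bad}")
        meta = {"temperature_c": temperature_c, "seed": seed, "command_mv": cmd}
        sweeps.append(Sweep.from_values(i_pa, rate_hz, "current", protocol=protocol, meta=meta))
    return SweepFamily(protocol=protocol, sweeps=sweeps)
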