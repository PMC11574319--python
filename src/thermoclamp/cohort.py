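"""Paired-cohort driver: simulate cells at two temperatures, measure all properties.

This is the glue between the synthetic neuron and the analysis modules: for
each simulated cell it runs the standard session — input-resistance probes
at three conditioning levels, the 5 ms time-constant pulse, the rheobase
ramp, and the TTX voltage-clamp family — at both bath temperatures, and
returns per-cell property dicts ready for
:func:`thermoclamp.stats.compare_conditions`.

Cohort heterogeneity is multiplicative log-normal jitter (default 10% CV)
on capacitance and all maximal conductances, fixed per cell so the same
cell is measured at both temperatures (the paired design of a recording
held while the bath temperature is changed).
"""

from __future__ import annotations

import numpy as np

from .errors import ThermoclampError
from .excitability import detect_spikes, rheobase_from_ramp
from .neuron import MSN_DEFAULTS, NeuronParams, simulate_current_clamp, simulate_voltage_clamp
from .passive import input_resistance, membrane_time_constant
from .traces import RampProtocol, StepProtocol, VClampProtocol
from .vclamp import estimate_leak, kv_time_constant, subtract_leak

__all__ = [
    "RIN_CONDITIONING_PA",
    "rin_probe_protocol",
    "TAU_PULSE",
    "RHEOBASE_RAMP",
    "jitter_params",
    "generate_cohort",
    "measure_cell",
    "run_paired_study",
]

#: DC offsets establishing the hyperpolarized / rest / depolarized levels
RIN_CONDITIONING_PA = (-100.0, 0.0, 100.0)
#: brief hyperpolarizing pulse for the membrane time constant
TAU_PULSE = StepProtocol(amplitude_pa=-100.0, onset_s=0.1, duration_s=0.005)
#: depolarizing ramp for rheobase / maximum firing rate (artifact choice:
#: the experimental slope and duration are not standardized)
RHEOBASE_RAMP = RampProtocol(start_pa=0.0, slope_pa_per_s=1000.0, onset_s=0.1, duration_s=1.2)


def rin_probe_protocol(conditioning_pa: float) -> StepProtocol:
    """The -50 pA, 500 ms probe riding on a conditioning DC offset."""
    return StepProtocol(
        amplitude_pa=-50.0, onset_s=0.2, duration_s=0.5, conditioning_pa=conditioning_pa
    )


def jitter_params(base: NeuronParams, rng: np.random.Generator, cv: float = 0.1) -> NeuronParams:
    """Log-normal multiplicative jitter on capacitance and conductances."""
    from dataclasses import replace

    f = lambda: float(np.exp(rng.normal(0.0, cv)))
    return replace(
        base,
        c_pf=base.c_pf * f(),
        g_leak_ns=base.g_leak_ns * f(),
        g_kir_ns=base.g_kir_ns * f(),
        g_na_ns=base.g_na_ns * f(),
        g_kv_ns=base.g_kv_ns * f(),
    )


def generate_cohort(
    n_cells: int = 15,
    base: NeuronParams = MSN_DEFAULTS,
    seed: int = 0,
    cv: float = 0.1,
) -> dict:
    """Deterministic cohort of jittered cells keyed by cell id."""
    rng = np.random.default_rng(seed)
    return {f"cell_{k:02d}": jitter_params(base, rng, cv) for k in range(n_cells)}


def measure_cell(
    params: NeuronParams, temperature_c: float, seed: int = 0
) -> dict:
    """Run the full measurement session on one cell at one temperature.

    A property whose measurement fails (e.g. no spike reached during the
    ramp) is recorded as ``None``, so downstream tables carry per-property
    n rather than dropping the cell.
    """
    out: dict = {}
    try:
        sweeps, protocols = [], []
        for cond in RIN_CONDITIONING_PA:
            prot = rin_probe_protocol(cond)
            sweeps.append(simulate_current_clamp(params, prot, temperature_c, seed=seed))
            protocols.append(prot)
        rin = input_resistance(sweeps, protocols)
        out["r_hyperpolarized_mohm"] = rin.r_hyperpolarized_mohm
        out["r_rest_mohm"] = rin.r_rest_mohm
        out["r_depolarized_mohm"] = rin.r_depolarized_mohm
    except ThermoclampError:
        out.update(
            r_hyperpolarized_mohm=None, r_rest_mohm=None, r_depolarized_mohm=None
        )

    try:
        sweep = simulate_current_clamp(params, TAU_PULSE, temperature_c, seed=seed)
        out["tau_ms"] = membrane_time_constant(sweep, TAU_PULSE).reported_tau_ms
    except ThermoclampError:
        out["tau_ms"] = None

    try:
        sweep = simulate_current_clamp(params, RHEOBASE_RAMP, temperature_c, seed=seed)
        train = detect_spikes(sweep)
        rheo = rheobase_from_ramp(sweep, RHEOBASE_RAMP, train)
        out["rheobase_pa"] = rheo.rheobase_pa
        out["fmax_hz"] = rheo.fmax_hz
    except ThermoclampError:
        out["rheobase_pa"] = None
        out["fmax_hz"] = None

    try:
        family = simulate_voltage_clamp(
            params, VClampProtocol(ttx=True), temperature_c, seed=seed
        )
        leak = estimate_leak(family)
        corrected = subtract_leak(family, leak)
        kv = kv_time_constant(corrected)
        out["kv_tau_ms"] = {e.command_mv: e.tau_ms for e in kv.entries}
    except ThermoclampError:
        out["kv_tau_ms"] = None
    return out


def run_paired_study(
    n_cells: int = 15,
    seed: int = 0,
    base: NeuronParams = MSN_DEFAULTS,
    temperatures: tuple = (23.0, 34.0),
    cv: float = 0.1,
) -> tuple[dict, dict]:
    """Measure a jittered cohort at both temperatures (paired by cell id)."""
    cohort = generate_cohort(n_cells, base, seed, cv)
    t_a, t_b = temperatures
    results_a = {cid: measure_cell(p, t_a, seed=seed) for cid, p in cohort.items()}
    results_b = {cid: measure_cell(p, t_b, seed=seed) for cid, p in cohort.items()}
    return results_a, results_b
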