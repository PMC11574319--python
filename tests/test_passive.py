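"""Input resistance and membrane time constant."""

import dataclasses

import numpy as np
import pytest

from thermoclamp.errors import ContaminationError, DegenerateInputError, ProtocolError
from thermoclamp.neuron import MSN_DEFAULTS, NeuronParams, resting_potential, simulate_current_clamp
from thermoclamp.passive import input_resistance, membrane_time_constant
from thermoclamp.traces import StepProtocol

from conftest import make_sweep

PROBE = -50.0


def _rin_session(params, temperature, conditioning=(-100.0, 0.0, 100.0), probe=PROBE):
    sweeps, protocols = [], []
    for cond in conditioning:
        prot = StepProtocol(probe, 0.2, 0.5, conditioning_pa=cond)
        sweeps.append(simulate_current_clamp(params, prot, temperature))
        protocols.append(prot)
    return sweeps, protocols


def test_ohmic_cell_reads_100_mohm_at_all_levels(passive_cell):
    rin = input_resistance(*_rin_session(passive_cell, 23.0))
    for r in (rin.r_hyperpolarized_mohm, rin.r_rest_mohm, rin.r_depolarized_mohm):
        assert r == pytest.approx(100.0, rel=0.01)


def test_kir_cell_matches_steady_state_finite_difference():
    """Chord resistance equals ΔV/ΔI from direct steady-state solves (2%)."""
    cell = dataclasses.replace(MSN_DEFAULTS, g_na_ns=0.0, g_kv_ns=0.0)
    sweeps, protocols = _rin_session(cell, 23.0)
    rin = input_resistance(sweeps, protocols)
    from thermoclamp.neuron import holding_current

    i_hold = holding_current(cell, 23.0, -75.0)
    for level, cond in zip(
        (rin.hyperpolarized, rin.rest, rin.depolarized), (-100.0, 0.0, 100.0)
    ):
        v0 = resting_potential(cell, 23.0, i_hold + cond)
        v1 = resting_potential(cell, 23.0, i_hold + cond + PROBE)
        r_oracle = (v1 - v0) / PROBE * 1000.0
        assert level.r_mohm == pytest.approx(r_oracle, rel=0.02)


@pytest.mark.parametrize("temp", [23.0, 34.0])
def test_msn_resistance_increases_with_depolarization(temp):
    rin = input_resistance(*_rin_session(MSN_DEFAULTS, temp))
    assert rin.r_depolarized_mohm > rin.r_rest_mohm > rin.r_hyperpolarized_mohm


def test_probe_scale_equivariance(passive_cell):
    r1 = input_resistance(*_rin_session(passive_cell, 23.0, probe=-50.0)).r_rest_mohm
    r2 = input_resistance(*_rin_session(passive_cell, 23.0, probe=-100.0)).r_rest_mohm
    assert r2 == pytest.approx(r1, rel=0.005)


def test_spike_in_window_raises_contamination():
    prot = StepProtocol(PROBE, 0.2, 0.5, conditioning_pa=0.0)
    s = simulate_current_clamp(NeuronParams.passive(100.0, 100.0), prot, 23.0)
    v = s.values.copy()
    k = s.index_at(0.65)  # inside the probe steady-state window
    v[k : k + 20] += np.linspace(0.0, 120.0, 20)  # fake AP upstroke above 0 mV
    bad = make_sweep(v, protocol=prot)
    protocols = [StepProtocol(PROBE, 0.2, 0.5, conditioning_pa=c) for c in (-100.0, 100.0)]
    sweeps = [
        simulate_current_clamp(NeuronParams.passive(100.0, 100.0), p, 23.0) for p in protocols
    ]
    with pytest.raises(ContaminationError):
        input_resistance(sweeps + [bad], protocols + [prot])


def test_zero_probe_is_degenerate():
    with pytest.raises((DegenerateInputError, ProtocolError)):
        input_resistance(*_rin_session(NeuronParams.passive(100, 100), 23.0, probe=0.0))


# ---------------------------------------------------------------------------
# membrane time constant
# ---------------------------------------------------------------------------

TAU_PULSE = StepProtocol(-100.0, 0.1, 0.005)


def test_rc_cell_tau_is_rc(passive_cell):
    """R = 100 MΩ, C = 100 pF -> reported tau = 10 ms; fast component degenerate."""
    s = simulate_current_clamp(passive_cell, TAU_PULSE, 23.0)
    fit = membrane_time_constant(s, TAU_PULSE)
    assert fit.reported_tau_ms == pytest.approx(10.0, rel=0.05)
    assert abs(fit.a_fast_mv) < 0.01 * abs(fit.a_slow_mv)


def test_two_compartment_taus_match_eigenvalues():
    """Both fitted taus within 5% of the eigenvalues of the 2x2 passive system."""
    # soma (1) coupled to a passive compartment (2); values in nS, pF
    g1, g2, gc, c1, c2 = 10.0, 4.0, 8.0, 80.0, 150.0
    A = np.array(
        [[-(g1 + gc) / c1, gc / c1], [gc / c2, -(g2 + gc) / c2]]
    )  # 1/ms since nS/pF = 1/ms
    lam, vec = np.linalg.eig(A)
    taus = np.sort(-1.0 / lam)  # ms, ascending = (fast, slow)
    # initial condition: soma deflected by a brief somatic pulse
    x0 = np.array([-5.0, -1.0])
    coef = np.linalg.solve(vec, x0)
    rate = 2.0e4
    n = int(0.2 * rate)
    t_ms = np.arange(n) / rate * 1000.0
    v1 = sum(
        coef[i] * vec[0, i] * np.exp(lam[i] * t_ms) for i in range(2)
    ).real
    # embed as the relaxation phase after a 5 ms pulse
    pulse = StepProtocol(-100.0, 0.01, 0.005)
    offset_idx = int(round((pulse.onset_s + pulse.duration_s) * rate)) + 2
    v = np.full(offset_idx + n, -75.0)
    v[offset_idx:] = -75.0 + v1
    fit = membrane_time_constant(make_sweep(v, rate_hz=rate), pulse)
    assert fit.tau_fast_ms == pytest.approx(taus[0], rel=0.05)
    assert fit.tau_slow_ms == pytest.approx(taus[1], rel=0.05)


@pytest.mark.parametrize("tau_ms", [2.0, 10.0, 40.0])
def test_single_exponential_consistency(tau_ms):
    """Noiseless single exponential: reported tau within one sample period."""
    rate = 2.0e4
    pulse = StepProtocol(-100.0, 0.01, 0.005)
    i0 = int(round(0.015 * rate)) + 2
    n = i0 + int(0.35 * rate)
    t_ms = np.arange(n - i0) / rate * 1000.0
    v = np.full(n, -75.0)
    v[i0:] = -75.0 - 6.0 * np.exp(-t_ms / tau_ms)
    fit = membrane_time_constant(make_sweep(v, rate_hz=rate), pulse)
    assert abs(fit.reported_tau_ms - tau_ms) < 1000.0 / rate


def test_fit_idempotence(passive_cell):
    s = simulate_current_clamp(passive_cell, TAU_PULSE, 23.0)
    fit = membrane_time_constant(s, TAU_PULSE)
    refit = membrane_time_constant(
        s, TAU_PULSE, starts=np.array([fit.tau_slow_ms])
    )
    assert refit.reported_tau_ms == pytest.approx(fit.reported_tau_ms, rel=1e-6)


def test_msn_tau_shorter_at_physiological_temperature():
    taus = {}
    for temp in (23.0, 34.0):
        s = simulate_current_clamp(MSN_DEFAULTS, TAU_PULSE, temp)
        taus[temp] = membrane_time_constant(s, TAU_PULSE).reported_tau_ms
    assert taus[34.0] < taus[23.0]


def test_depolarizing_pulse_rejected(passive_cell):
    s = simulate_current_clamp(passive_cell, TAU_PULSE, 23.0)
    with pytest.raises(ProtocolError):
        membrane_time_constant(s, StepProtocol(100.0, 0.1, 0.005))
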