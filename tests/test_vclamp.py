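"""Steady-state I/V, leak model and subtraction, Kv time constant."""

import dataclasses
import math

import numpy as np
import pytest

from thermoclamp.neuron import NeuronParams, simulate_voltage_clamp
from thermoclamp.traces import SweepFamily, VClampProtocol
from thermoclamp.vclamp import (
    estimate_leak,
    kv_time_constant,
    make_lowpass,
    steady_state_iv,
    subtract_leak,
)

from conftest import make_sweep

RATE = 2.0e4
LEAK_PROT = VClampProtocol(
    commands_mv=(-70.0, -65.0, -60.0), onset_s=0.1, step_duration_s=0.5, tail_s=0.05
)


def _family_from_values(protocol, values_per_cmd):
    sweeps = [
        make_sweep(v, rate_hz=RATE, channel="current", protocol=protocol)
        for v in values_per_cmd
    ]
    return SweepFamily(protocol=protocol, sweeps=sweeps)


def _step_trace(protocol, amplitude, n=None):
    n = n or int(protocol.sweep_duration_s * RATE)
    v = np.zeros(n)
    i0 = int(protocol.onset_s * RATE)
    i1 = int((protocol.onset_s + protocol.step_duration_s) * RATE)
    v[i0:i1] = amplitude
    return v


class TestSteadyStateIV:
    def test_constant_trace(self):
        prot = VClampProtocol(commands_mv=(0.0,), onset_s=0.0, step_duration_s=0.5, tail_s=0.0)
        fam = _family_from_values(prot, [np.full(int(0.5 * RATE), 100.0)])
        assert steady_state_iv(fam).i_ss_pa[0] == pytest.approx(100.0)

    def test_linear_ramp_trace_means_to_425(self):
        prot = VClampProtocol(commands_mv=(0.0,), onset_s=0.0, step_duration_s=0.5, tail_s=0.0)
        t_ms = np.arange(int(0.5 * RATE)) / RATE * 1000.0
        fam = _family_from_values(prot, [t_ms * 1.0])  # 1 pA/ms from onset
        assert steady_state_iv(fam).i_ss_pa[0] == pytest.approx(425.0, abs=0.05)

    def test_leak_only_family_is_ohmic(self):
        cell = NeuronParams(
            g_leak_ns=2.0, e_leak_mv=-75.0, g_kir_ns=0.0, g_na_ns=0.0, g_kv_ns=0.0
        )
        prot = VClampProtocol(onset_s=0.05, tail_s=0.05)
        iv = steady_state_iv(simulate_voltage_clamp(cell, prot, 23.0))
        expected = 2.0 * (iv.commands_mv + 75.0)
        assert np.max(np.abs(iv.i_ss_pa - expected)) < 0.5


class TestEstimateLeak:
    def test_ohmic_cell_exact(self):
        cell = NeuronParams(
            g_leak_ns=2.0, e_leak_mv=-75.0, g_kir_ns=0.0, g_na_ns=0.0, g_kv_ns=0.0
        )
        fam = simulate_voltage_clamp(cell, LEAK_PROT, 23.0)
        leak = estimate_leak(fam)
        assert leak.g_leak_ns_hat == pytest.approx(2.0, abs=1e-9)
        # predicted leak at +10 mV: g * 85 mV = 170 pA over the step plateau
        pred = leak.predicted_leak_pa(10.0)
        plateau = pred[int(0.3 * RATE) : int(0.5 * RATE)]
        assert np.mean(plateau) == pytest.approx(170.0, rel=1e-6)

    def test_noisy_ohmic_matches_weighted_regression_oracle(self):
        rng = np.random.default_rng(3)
        g_true, hold = 2.0, LEAK_PROT.holding_mv
        values = []
        for cmd in LEAK_PROT.commands_mv:
            v = _step_trace(LEAK_PROT, g_true * (cmd - hold))
            values.append(v + rng.normal(0.0, 2.0, len(v)))
        fam = _family_from_values(LEAK_PROT, values)
        leak = estimate_leak(fam)
        # oracle: weighted least squares through the origin on (drive, i_ss)
        drives, iss = [], []
        for cmd, s in zip(LEAK_PROT.commands_mv, fam.sweeps):
            base = np.mean(s.window(0.0, LEAK_PROT.onset_s))
            drives.append(cmd - hold)
            iss.append(np.mean(s.window(0.5, 0.55)) - base)
        w = 1.0 / np.abs(drives)  # driving-force weighting of per-step conductances
        d, i = np.asarray(drives), np.asarray(iss)
        g_wls = float(np.sum(w * d * i) / np.sum(w * d * d))
        assert leak.g_leak_ns_hat == pytest.approx(g_wls, rel=0.03)

    def test_lowpass_filter_contract(self):
        """-3 dB point at 150 Hz: 500 Hz falls by >= 15 dB, 10 Hz by <= 1 dB."""
        lp = make_lowpass(150.0, RATE)
        t = np.arange(int(2 * RATE)) / RATE
        for freq, check in ((500.0, lambda db: db >= 15.0), (10.0, lambda db: db <= 1.0)):
            x = np.sin(2 * np.pi * freq * t)
            y = lp(x)[int(0.5 * RATE) : int(1.5 * RATE)]  # avoid edges
            db = -20.0 * math.log10(np.sqrt(2.0) * np.std(y))
            assert check(db), f"{freq} Hz attenuated by {db:.2f} dB"


class TestSubtractLeak:
    def test_leak_only_self_subtraction(self):
        cell = NeuronParams(
            g_leak_ns=2.0, e_leak_mv=-75.0, g_kir_ns=0.0, g_na_ns=0.0, g_kv_ns=0.0
        )
        prot = VClampProtocol(onset_s=0.1, tail_s=0.05)
        fam = simulate_voltage_clamp(cell, prot, 23.0)
        corrected = subtract_leak(fam, estimate_leak(fam))
        iv = steady_state_iv(corrected)
        raw_max = np.max(np.abs(steady_state_iv(fam).i_ss_pa))
        assert np.max(np.abs(iv.i_ss_pa)) < 0.01 * raw_max

    def test_zero_template_is_identity(self):
        from thermoclamp.vclamp import LeakModel

        prot = VClampProtocol(commands_mv=(-10.0, 0.0), onset_s=0.1, step_duration_s=0.5)
        values = [_step_trace(prot, 100.0), _step_trace(prot, 200.0)]
        fam = _family_from_values(prot, values)
        zero = LeakModel(
            g_leak_ns_hat=0.0,
            template=np.zeros(len(values[0])),
            holding_mv=prot.holding_mv,
        )
        corrected = subtract_leak(fam, zero)
        for raw, cor in zip(fam.sweeps, corrected.sweeps):
            base = np.mean(raw.window(0.0, prot.onset_s))
            np.testing.assert_allclose(cor.values, raw.values - base, atol=1e-12)

    def test_subtraction_linearity(self):
        cell = NeuronParams(
            g_leak_ns=2.0, e_leak_mv=-75.0, g_kir_ns=0.0, g_na_ns=0.0, g_kv_ns=120.0
        )
        prot = VClampProtocol(commands_mv=(-70.0, -65.0, -60.0, 0.0), onset_s=0.1,
                              step_duration_s=0.5, tail_s=0.05)
        fam = simulate_voltage_clamp(cell, prot, 23.0)
        a = 2.5
        scaled = SweepFamily(
            protocol=prot,
            sweeps=[
                make_sweep(a * s.values, rate_hz=RATE, channel="current", protocol=prot)
                for s in fam.sweeps
            ],
        )
        c1 = subtract_leak(scaled, estimate_leak(scaled))
        c2 = subtract_leak(fam, estimate_leak(fam))
        for s1, s2 in zip(c1.sweeps, c2.sweeps):
            np.testing.assert_allclose(s1.values, a * s2.values, atol=1e-6)


class TestKvTimeConstant:
    def _mono_exp_family(self, taus_ms, amp=100.0):
        prot = VClampProtocol(
            commands_mv=tuple(sorted(-10.0 + 5.0 * k for k in range(len(taus_ms)))),
            onset_s=0.05, step_duration_s=0.4, tail_s=0.0,
        )
        values = []
        n = int(prot.sweep_duration_s * RATE)
        i0 = int(prot.onset_s * RATE)
        t_ms = np.arange(n - i0) / RATE * 1000.0
        for tau in taus_ms:
            v = np.zeros(n)
            v[i0:] = amp * (1.0 - np.exp(-t_ms / tau))
            values.append(v)
        return _family_from_values(prot, values), prot

    def test_mono_exponential_crossing(self):
        fam, prot = self._mono_exp_family([5.0, 5.0, 5.0])
        res = kv_time_constant(fam, commands_in_scope=prot.commands_mv)
        for e in res.entries:
            assert e.tau_ms == pytest.approx(5.0, abs=1000.0 / RATE)

    def test_instant_step_gives_zero_tau(self):
        prot = VClampProtocol(commands_mv=(0.0,), onset_s=0.05, step_duration_s=0.4, tail_s=0.0)
        fam = _family_from_values(prot, [_step_trace(prot, 100.0)])
        res = kv_time_constant(fam, commands_in_scope=(0.0,))
        assert res.entries[0].tau_ms == 0.0

    def test_no_outward_current_recorded_not_fatal(self):
        prot = VClampProtocol(commands_mv=(0.0,), onset_s=0.05, step_duration_s=0.4, tail_s=0.0)
        fam = _family_from_values(prot, [_step_trace(prot, -50.0)])
        res = kv_time_constant(fam, commands_in_scope=(0.0,))
        assert res.entries[0].tau_ms is None
        assert "no outward" in res.entries[0].note

    def test_temperature_ratio_follows_rate_q10(self):
        """Kv tau(23)/tau(34) tracks 3^1.1 under pure n^4 gating (10%)."""
        cell = NeuronParams(g_leak_ns=0.0, g_kir_ns=0.0, g_na_ns=0.0, g_kv_ns=360.0,
                            q10_rates=3.0, q10_cond=1.4)
        prot = VClampProtocol(commands_mv=(0.0,), onset_s=0.05, step_duration_s=0.3)
        taus = {}
        for temp in (23.0, 34.0):
            fam = simulate_voltage_clamp(cell, prot, temp)
            taus[temp] = kv_time_constant(fam, commands_in_scope=(0.0,)).entries[0].tau_ms
        assert taus[23.0] / taus[34.0] == pytest.approx(3.0**1.1, rel=0.10)

    def test_tau_nonincreasing_in_rate_q10(self):
        taus = []
        for q10 in (1.0, 2.0, 3.0):
            cell = NeuronParams(g_leak_ns=0.0, g_kir_ns=0.0, g_na_ns=0.0, g_kv_ns=360.0,
                                q10_rates=q10, q10_cond=1.0)
            prot = VClampProtocol(commands_mv=(0.0,), onset_s=0.05, step_duration_s=0.3)
            fam = simulate_voltage_clamp(cell, prot, 34.0)
            taus.append(kv_time_constant(fam, commands_in_scope=(0.0,)).entries[0].tau_ms)
        assert taus[0] >= taus[1] >= taus[2]
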