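"""Synthetic voltage traces: Poisson EPSP trains on white recording noise.

Emulates a current-clamp recording of a quiescent cell at a stable holding
potential that receives random excitatory post-synaptic potentials (EPSPs):
a 0 mV baseline, double-exponential EPSP waveforms at Poisson event times,
and i.i.d. Gaussian sample noise. Everything is deterministic given the
seed; Poisson event times are drawn by inversion (cumulative sum of
exponential inter-event gaps) so the event count is exactly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .traces import Sweep

__all__ = ["NoiseSpec", "generate_noise_trace"]


@dataclass(frozen=True)
class NoiseSpec:
    """Parameters of the EPSP/noise trace generator."""

    sigma_mv: float = 0.1
    epsp_rate_hz: float = 5.0
    epsp_amp_mv: float = 0.5
    epsp_tau_rise_ms: float = 1.0
    epsp_tau_decay_ms: float = 10.0
    duration_s: float = 10.0
    seed: int = 0
    rate_hz: float = 2.0e4

    def __post_init__(self):
        if self.sigma_mv < 0:
            raise ValueError("sigma_mv must be >= 0")
        if self.epsp_rate_hz < 0:
            raise ValueError("epsp_rate_hz must be >= 0")
        if self.epsp_tau_rise_ms <= 0 or self.epsp_tau_decay_ms <= self.epsp_tau_rise_ms:
            raise ValueError("need 0 < tau_rise < tau_decay")
        if self.duration_s <= 0 or self.rate_hz <= 0:
            raise ValueError("duration and rate must be positive")


def _epsp_kernel(spec: NoiseSpec) -> np.ndarray:
    """Unit-peak double-exponential waveform sampled at the trace rate."""
    tr, td = spec.epsp_tau_rise_ms / 1000.0, spec.epsp_tau_decay_ms / 1000.0
    # analytic peak time and height of exp(-t/td) - exp(-t/tr)
    t_peak = tr * td / (td - tr) * math.log(td / tr)
    peak = math.exp(-t_peak / td) - math.exp(-t_peak / tr)
    t = np.arange(0.0, 8.0 * td, 1.0 / spec.rate_hz)
    return spec.epsp_amp_mv / peak * (np.exp(-t / td) - np.exp(-t / tr))


def generate_noise_trace(spec: NoiseSpec) -> Sweep:
    """Generate the EPSP-bearing noise trace described by ``spec``."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.rate_hz))
    v = np.zeros(n)

    event_times: list[float] = []
    if spec.epsp_rate_hz > 0:
        # inversion: exponential gaps from uniforms, accumulated until the end
        t = 0.0
        while True:
            t += -math.log(1.0 - rng.random()) / spec.epsp_rate_hz
            if t >= spec.duration_s:
                break
            event_times.append(t)
        kernel = _epsp_kernel(spec)
        for te in event_times:
            i0 = int(round(te * spec.rate_hz))
            seg = min(len(kernel), n - i0)
            v[i0 : i0 + seg] += kernel[:seg]

    if spec.sigma_mv > 0:
        v += rng.normal(0.0, spec.sigma_mv, size=n)

    meta = {
        "seed": spec.seed,
        "n_epsps": len(event_times),
        "epsp_times_s": [round(t, 9) for t in event_times],
        "sigma_mv": spec.sigma_mv,
    }
    return Sweep.from_values(v, spec.rate_hz, "voltage", meta=meta)
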