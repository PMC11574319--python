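"""Spike detection, ramp rheobase, and maximum firing rate.

A spike is an upward crossing of a dV/dt threshold (default 20 mV/ms)
followed by a voltage excursion above 0 mV within 2 ms; its time is the
voltage peak. The onset of the first spike is the inflection point of the
upstroke — the maximum of the second derivative in the 2 ms preceding the
threshold crossing — mirroring common practice for ramp-rheobase
measurements. The rheobase is the ramp current at that onset time, and the
maximum firing rate is the reciprocal of the smallest inter-spike interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NoSpikeError, ProtocolError
from .traces import RampProtocol, Sweep

__all__ = ["SpikeTrain", "RheobaseResult", "detect_spikes", "rheobase_from_ramp"]

DEFAULT_DVDT_THRESHOLD = 20.0  # mV/ms
_PEAK_SEARCH_S = 2e-3  # spike peak must exceed 0 mV within this window
_MERGE_S = 1e-3  # refractory merge window
_ONSET_SEARCH_S = 2e-3


@dataclass
class SpikeTrain:
    """Ordered spike peak times with the first spike's inflection onset."""

    spike_times_s: np.ndarray
    onset_time_s: float | None
    dvdt_threshold_mv_per_ms: float
    peak_indices: np.ndarray

    def __post_init__(self):
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)
        if len(self.spike_times_s) > 1 and np.any(np.diff(self.spike_times_s) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.spike_times_s)


@dataclass(frozen=True)
class RheobaseResult:
    """Ramp current at spike onset, and max rate from the minimum ISI."""

    rheobase_pa: float
    fmax_hz: float | None


def _second_derivative(v: np.ndarray, dt_ms: float) -> np.ndarray:
    """d2V/dt2 (mV/ms^2) by central differences with 5-point smoothing."""
    dv = np.gradient(v, dt_ms)
    d2v = np.gradient(dv, dt_ms)
    kernel = np.ones(5) / 5.0
    return np.convolve(d2v, kernel, mode="same")


def detect_spikes(
    sweep: Sweep, dvdt_threshold: float = DEFAULT_DVDT_THRESHOLD
) -> SpikeTrain:
    """Detect action potentials in a voltage sweep.

    An empty train is a valid result (no error for subthreshold traces).
    """
    if sweep.channel != "voltage":
        raise ProtocolError("spike detection requires a voltage sweep")
    v = sweep.values
    dt_ms = 1000.0 / sweep.rate_hz
    dvdt = np.gradient(v, dt_ms)  # mV/ms
    w_peak = max(int(round(_PEAK_SEARCH_S * sweep.rate_hz)), 1)
    w_merge = max(int(round(_MERGE_S * sweep.rate_hz)), 1)

    crossings = np.flatnonzero((dvdt[:-1] < dvdt_threshold) & (dvdt[1:] >= dvdt_threshold)) + 1
    peaks: list[int] = []
    first_crossing: int | None = None
    for i in crossings:
        seg = v[i : i + w_peak + 1]
        if seg.size == 0 or seg.max() <= 0.0:
            continue
        p = i + int(np.argmax(seg))
        if peaks and (i - peaks[-1] < w_merge or p == peaks[-1]):
            continue  # refractory merge: crossing belongs to the previous spike
        peaks.append(p)
        if first_crossing is None:
            first_crossing = i

    onset_time = None
    if first_crossing is not None:
        w_on = max(int(round(_ONSET_SEARCH_S * sweep.rate_hz)), 2)
        j0 = max(first_crossing - w_on, 0)
        d2v = _second_derivative(v[max(j0 - 5, 0) : first_crossing + 5], dt_ms)
        off = j0 - max(j0 - 5, 0)
        seg = d2v[off : off + (first_crossing - j0)]
        onset_idx = j0 + int(np.argmax(seg)) if seg.size else first_crossing
        onset_time = float(sweep.time_s[onset_idx])

    return SpikeTrain(
        spike_times_s=sweep.time_s[np.asarray(peaks, dtype=int)],
        onset_time_s=onset_time,
        dvdt_threshold_mv_per_ms=dvdt_threshold,
        peak_indices=np.asarray(peaks, dtype=int),
    )


def rheobase_from_ramp(
    sweep: Sweep, ramp: RampProtocol, train: SpikeTrain
) -> RheobaseResult:
    """Rheobase (ramp current at first-spike onset) and maximum firing rate."""
    if ramp.slope_pa_per_s <= 0:
        raise ProtocolError("rheobase needs a depolarizing ramp (positive slope)")
    if len(train) == 0 or train.onset_time_s is None:
        raise NoSpikeError("no spikes detected during the ramp")
    onset = train.onset_time_s
    if onset < ramp.onset_s:
        raise ProtocolError(
            f"spike onset {onset:.4f} s precedes ramp onset {ramp.onset_s:.4f} s"
        )
    if onset >= ramp.onset_s + ramp.duration_s:
        raise ProtocolError("spike onset falls after the end of the ramp")
    rheobase = ramp.start_pa + ramp.slope_pa_per_s * (onset - ramp.onset_s)
    fmax = None
    if len(train) >= 2:
        fmax = float(1.0 / np.min(np.diff(train.spike_times_s)))
    return RheobaseResult(rheobase_pa=float(rheobase), fmax_hz=fmax)
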