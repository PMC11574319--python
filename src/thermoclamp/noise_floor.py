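"""Recording noise floor from the residual of a short smoothing filter.

The trace is mean-adjusted to zero and passed through a causal 1-D filter —
a 10-sample (0.5 ms at 20 kHz) moving average, i.e. a rational transfer
function with feed-forward coefficients ``1/N`` and unit feedback — and the
residual (raw minus filtered) isolates the high-frequency noise riding on
slow physiological signals such as EPSPs. The noise level is the standard
deviation of that residual over 10 s of continuous data.

For i.i.d. noise of standard deviation sigma the residual has standard
deviation ``sigma * sqrt((N-1)/N)`` (the filter removes the 1/N of the
variance it tracks), which the tests use as a closed-form check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .errors import WindowError
from .traces import Sweep

__all__ = ["NoiseResult", "isolate_noise"]

DEFAULT_FILTER_LEN = 10
DEFAULT_SPAN_S = 10.0


@dataclass(frozen=True)
class NoiseResult:
    """Residual noise trace and its standard deviation over the span."""

    residual: np.ndarray
    sd: float
    span_s: float
    filter_len_samples: int

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def isolate_noise(
    sweep: Sweep,
    filter_len: int = DEFAULT_FILTER_LEN,
    span_s: float = DEFAULT_SPAN_S,
) -> NoiseResult:
    """Isolate high-frequency noise and report its standard deviation.

    The first ``filter_len - 1`` residual samples (the causal filter's
    warm-up) are discarded; the standard deviation is taken over the first
    ``span_s`` seconds of the retained residual. Raises
    :class:`WindowError` if the trace is shorter than warm-up plus span.
    """
    if filter_len < 2:
        raise ValueError("filter_len must be >= 2 samples")
    n_span = int(round(span_s * sweep.rate_hz))
    if len(sweep.values) < n_span + filter_len - 1:
        raise WindowError(
            f"trace of {len(sweep.values)} samples shorter than required "
            f"span {n_span} + warm-up {filter_len - 1}"
        )
    x = sweep.values - np.mean(sweep.values)
    y = lfilter(np.ones(filter_len) / filter_len, [1.0], x)
    residual = (x - y)[filter_len - 1 :]
    sd = float(np.std(residual[:n_span]))
    return NoiseResult(
        residual=residual, sd=sd, span_s=span_s, filter_len_samples=filter_len
    )
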