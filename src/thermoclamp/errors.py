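"""Exception hierarchy shared by the analysis and simulation modules."""


class ThermoclampError(Exception):
    """Base class for all package-specific errors."""


class TraceFormatError(ThermoclampError):
    """A trace file or sidecar is missing, malformed, or internally inconsistent."""


class ProtocolError(ThermoclampError):
    """A protocol is invalid or does not match the sweep it is paired with."""


class ContaminationError(ThermoclampError):
    """A spike (or other artifact) was detected inside a measurement window."""


class DegenerateInputError(ThermoclampError):
    """Input is technically valid but carries no information (e.g. zero probe)."""


class FitError(ThermoclampError):
    """Nonlinear fit failed to converge; carries the best residual found."""

    def __init__(self, message: str, best_rss: float | None = None):
        super().__init__(message)
        self.best_rss = best_rss


class SimulationError(ThermoclampError):
    """Numerical integration produced a non-finite state."""


class StabilityError(ThermoclampError):
    """Integration step too large for the requested dynamics."""


class WindowError(ThermoclampError):
    """A requested analysis window falls outside the available data."""


class PairingError(ThermoclampError):
    """Paired-condition data could not be matched cell-by-cell."""


class CapacityError(ThermoclampError):
    """The thermal model cannot reach the requested target temperature."""


class NoSpikeError(ThermoclampError):
    """An operation requiring at least one spike received an empty train."""
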