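"""Exception types raised by the model and inference code."""


class SbscallError(Exception):
    """Base class for package-specific errors."""


class DegenerateTransitionError(SbscallError):
    """Density-decay transition has zero variance (d = 1 or lambda = 0)."""


class DegenerateWeightsError(SbscallError):
    """All particle weights vanished numerically.

    Carries the 1-based cycle index at which the ensemble collapsed.
    """

    def __init__(self, cycle: int, message: str | None = None):
        self.cycle = cycle
        super().__init__(message or f"all particle weights are zero at cycle {cycle}")


class ParseError(SbscallError):
    """Malformed input file; message names the offending record."""
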