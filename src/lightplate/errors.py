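"""Exception hierarchy shared across the package."""


class LightplateError(Exception):
    """Base class for all package-specific errors."""


class DomainError(LightplateError, ValueError):
    """An argument is outside its physically meaningful domain."""


class InfeasibleFluxError(LightplateError, ValueError):
    """A commanded photon flux exceeds what the hardware can emit."""


class CapacityError(LightplateError, ValueError):
    """A design requires more wells/channels than the plate has."""


class LPFParseError(LightplateError, ValueError):
    """A binary light-program stream is malformed.

    Parameters
    ----------
    message : str
    offset : int, optional
        Byte offset at which the problem was detected.
    """

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (byte offset {offset})"
        super().__init__(message)


class CalibrationFileError(LightplateError, ValueError):
    """A calibration text file is malformed (carries the line number)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class FitError(LightplateError, RuntimeError):
    """A least-squares fit failed to converge or is not identifiable."""


class ResolutionError(LightplateError, ValueError):
    """Numerical integration step too coarse for the requested tolerance."""
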