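"""Exception hierarchy shared across the package."""


class SuperbarcodeError(ValueError):
    """Base class for all package-specific errors."""


class AlignmentError(SuperbarcodeError):
    """Malformed alignment input (ragged rows, unmapped samples, ...)."""


class SaturationError(SuperbarcodeError):
    """K2P distance undefined because a log argument is non-positive.

    Carries the offending pair of sample ids when raised from a matrix build.
    """

    def __init__(self, message: str, pair: tuple[str, str] | None = None):
        super().__init__(message)
        self.pair = pair


class TreeError(SuperbarcodeError):
    """Tree input inconsistent with the sample map or too small to compare."""
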