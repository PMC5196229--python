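"""Exception types shared across the package."""


class AquadiffError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(AquadiffError, ValueError):
    """A parameter combination is physically or numerically invalid."""


class FittingError(AquadiffError, RuntimeError):
    """A curve fit could not be performed or did not converge."""


class EstimationError(AquadiffError, RuntimeError):
    """An estimator could not produce a valid result from the given ensemble."""


class OutOfRangeError(AquadiffError, ValueError):
    """A lookup/inversion fell outside the tabulated range (no extrapolation)."""
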