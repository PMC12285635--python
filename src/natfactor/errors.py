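"""Exception hierarchy.

All domain errors derive from :class:`NatFactorError` so callers can catch
the whole family; each concrete class maps to one failure mode of the
pipeline (bad image, too few samples, zero-variance statistics, ...).
"""


class NatFactorError(Exception):
    """Base class for all errors raised by natfactor."""


class InvalidImageError(NatFactorError, ValueError):
    """Input image violates a structural requirement (shape, range, channels)."""


class InvalidInputError(NatFactorError, ValueError):
    """Non-image input violates a precondition (shape mismatch, empty sequence)."""


class InsufficientDataError(NatFactorError, ValueError):
    """Too few samples to form a meaningful empirical distribution."""


class DegenerateDistributionError(NatFactorError, ValueError):
    """All probability mass sits at zero; the scale parameter is undefined."""


class DegenerateInputError(NatFactorError, ValueError):
    """Input carries no signal at all (e.g. an all-zero image)."""


class MissingMetadataError(NatFactorError, ValueError):
    """Required metadata (e.g. physical pixel size) is absent."""


class UndefinedPSNRError(NatFactorError, ZeroDivisionError):
    """PSNR requested for identical images (MSE = 0)."""
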