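"""Exception hierarchy shared across the pipeline stages."""


class PolypFeatError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(PolypFeatError, ValueError):
    """An argument violates a documented precondition."""


class SegmentationError(PolypFeatError, RuntimeError):
    """Mask segmentation failed (e.g. constant image, no clusters)."""


class DegenerateShapeError(PolypFeatError, RuntimeError):
    """A shape descriptor cannot be normalized (empty effective sample)."""


class DegenerateDistributionError(PolypFeatError, RuntimeError):
    """Distribution fitting is undefined (e.g. zero-variance sample)."""


class UnbalancedDesignError(PolypFeatError, ValueError):
    """A factorial design cell is empty."""
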