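"""Exception hierarchy for ratparc."""


class RatparcError(Exception):
    """Base class for all ratparc-specific errors."""


class DimensionalityError(RatparcError):
    """Input has the wrong number of spatial dimensions."""


class FormatError(RatparcError):
    """File is not a readable NIfTI-1 image or lookup table."""


class GeometryError(RatparcError):
    """Two objects do not live on compatible grids."""


class RegistrationError(RatparcError):
    """Registration could not be estimated (degenerate input, bad metric)."""


class ConvergenceError(RatparcError):
    """Iterative inversion failed to reach the requested residual."""


class MaskingError(RatparcError):
    """Brain-mask extraction failed (e.g. constant image)."""


class EmptyAtlasError(RatparcError):
    """Atlas contains no nonzero labels."""


class EmptyROIError(RatparcError):
    """Requested ROI has no voxels in the parcellation."""


class UndefinedDiceError(RatparcError):
    """Dice coefficient undefined: both masks empty."""
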