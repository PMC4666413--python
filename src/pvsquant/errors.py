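"""Exception hierarchy for pvsquant.

Every precondition violation raises a distinct, named error so callers
(and the CLI) can distinguish bad inputs from genuine bugs.
"""


class PvsQuantError(Exception):
    """Base class for all pvsquant errors."""


class ImageReadError(PvsQuantError):
    """A volume file could not be read."""


class NonVolumeImageError(ImageReadError):
    """The image on disk does not have exactly three axes."""


class InvalidSpacingError(ImageReadError):
    """Voxel dimensions in the header are absent, zero or negative."""


class ZeroDynamicRangeError(PvsQuantError):
    """All intensities in the adjustment domain are equal."""


class EmptyDomainError(PvsQuantError):
    """A domain mask selects fewer than two voxels."""


class NegativeIntensityError(PvsQuantError):
    """The self-product combination requires non-negative input."""


class RoiError(PvsQuantError):
    """Base class for region-of-interest construction problems."""


class RoiOverlapError(RoiError):
    """The two ovoid regions overlap or touch."""


class RoiBoundsError(RoiError):
    """An ovoid extends beyond the slice bounds."""


class EmptyMaskError(RoiError):
    """A mask contains no foreground pixels."""


class ShapeMismatchError(PvsQuantError):
    """Slice, ROI and exclusion mask shapes are inconsistent."""


class PlacementError(PvsQuantError):
    """Phantom object placement failed after bounded retries."""


class InsufficientDataError(PvsQuantError):
    """Too few observations for the requested statistic."""


class ConstantPredictorError(PvsQuantError):
    """Regression predictor has zero variance."""
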