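"""Exception hierarchy.

Every error raised by this package derives from :class:`AvveError`, so callers
can catch one type at a pipeline boundary while still discriminating causes.
"""


class AvveError(Exception):
    """Base class for all errors raised by avve."""


class UnsupportedImageError(AvveError):
    """Input image payload is not a 3D scalar volume (e.g. 4D or multi-channel)."""


class InvalidGeometryError(AvveError):
    """Non-invertible affine, non-positive spacing, or a degenerate output grid."""


class DegenerateHistogramError(AvveError):
    """Histogram cannot be formed (constant image, too few bins)."""


class ParcellationFailureError(AvveError):
    """Fewer than four curvature peaks found after exhausting the threshold schedule."""


class GridAlignmentError(AvveError):
    """Two volumes/masks expected on the same voxel grid are not."""


class DegenerateLabelsError(AvveError):
    """A supervised operation received rows from a single class only."""


class DegenerateFeatureError(AvveError):
    """A feature column has zero variance on the fitting rows."""


class MissingFeatureError(AvveError):
    """A trained estimator requested a feature volume that was not supplied."""


class InvalidSplitError(AvveError):
    """A subject split would leave an empty train or test side."""


class InvalidSpecError(AvveError):
    """A phantom specification violates its geometric or intensity invariants."""
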