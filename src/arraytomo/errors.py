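"""Exception hierarchy shared across the package."""


class ArrayTomoError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(ArrayTomoError, ValueError):
    """Invalid voxel geometry (non-positive counts or voxel dimensions)."""


class ChannelNotFoundError(ArrayTomoError, KeyError):
    """Requested channel name or numeric token does not exist."""


class RangeError(ArrayTomoError, IndexError):
    """Cutout range falls outside the (resolution-scaled) volume bounds."""


class CompositeError(ArrayTomoError, ValueError):
    """Invalid false-color composite request (arity or all placeholders)."""


class ShapeMismatchError(ArrayTomoError, ValueError):
    """Two images/volumes that must be congruent are not."""


class NoSignalError(ArrayTomoError, ValueError):
    """An image required to carry signal has zero variance."""


class FlatMapError(ArrayTomoError, ValueError):
    """Cross-correlation map has no peak above its background level."""


class StitchGraphError(ArrayTomoError, ValueError):
    """Pairwise-offset graph of a mosaic is not connected."""


class InsufficientPointsError(ArrayTomoError, ValueError):
    """Too few correspondences to estimate a transform."""


class NoConsensusError(ArrayTomoError, ValueError):
    """RANSAC failed to find a consensus set of inliers."""


class DegenerateInputError(ArrayTomoError, ValueError):
    """Input is degenerate for the requested operation (e.g. constant
    image for background subtraction, all-zero paired differences)."""
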