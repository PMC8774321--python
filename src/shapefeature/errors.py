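"""Exception hierarchy for the shapefeature package."""


class ShapeFeatureError(Exception):
    """Base class for all package-specific failures."""


class VolumeIOError(ShapeFeatureError):
    """Raised when a volume file cannot be read or written as a 3-D image."""


class EmptyMaskError(ShapeFeatureError):
    """Raised when an operation requiring geometry receives an empty mask."""


class EmptyVOIError(ShapeFeatureError):
    """Raised when thresholding leaves no voxel above threshold.

    Carries the offending threshold so batch drivers can report it.
    """

    def __init__(self, threshold: float, k: float):
        self.threshold = threshold
        self.k = k
        super().__init__(
            f"no VOI above threshold {threshold:.6g} (k={k:g} times the non-zero SUV mean)"
        )


class MeshExtractionError(ShapeFeatureError):
    """Raised when a mask is too thin or degenerate for iso-surface extraction."""
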