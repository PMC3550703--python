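"""Exception hierarchy for scarchar.

Every reader/operation fails loudly with a specific subclass of
:class:`ScarCharError`; nothing silently substitutes defaults.
"""


class ScarCharError(Exception):
    """Base class for all scarchar errors."""


class GeometryError(ScarCharError):
    """Degenerate or invalid geometry (epi <= endo, self-intersecting polygon, ...)."""


class MetadataError(ScarCharError):
    """Required image geometry metadata (spacing, slice thickness) is missing."""


class SchemaError(ScarCharError):
    """Input file does not conform to the documented schema."""


class ContainmentError(ScarCharError):
    """Endocardial contour not contained within the epicardial contour."""


class LandmarkError(ScarCharError):
    """A required anatomical landmark (LV center, RV insertion) is missing."""


class AlignmentError(ScarCharError):
    """Two label/intensity volumes do not share a voxel grid."""


class ROIError(ScarCharError):
    """Hyperenhancement ROI does not intersect the myocardium."""


class ThresholdError(ScarCharError):
    """Signal-intensity threshold is non-positive or otherwise unusable."""


class PartitionError(ScarCharError):
    """Coronary-territory sets do not partition the 17 segments."""


class DomainError(ScarCharError):
    """Numeric argument outside its valid domain."""


class DegenerateVarianceError(ScarCharError):
    """Two-sample t test requested on constant, identical samples."""
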