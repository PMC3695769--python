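"""Exception hierarchy shared by all analysis modules."""


class CMRPostError(Exception):
    """Base class for all package errors."""


class InvalidContourError(CMRPostError):
    """Contour is degenerate: fewer than 3 vertices, self-intersecting, or zero area."""


class ContourTopologyError(CMRPostError):
    """Contours violate required topology (e.g. endocardium not inside epicardium)."""


class MissingContourError(CMRPostError):
    """A required contour is absent from the stack."""


class InsufficientCoverageError(CMRPostError):
    """Too few usable slices to build a segment model."""


class InvalidRingError(CMRPostError):
    """Slice mapped to a ring that the segment model does not contain."""


class UnreliableReferenceError(CMRPostError):
    """Reference ROI too small or otherwise unusable for robust statistics."""


class NoContrastArrivalError(CMRPostError):
    """No frame of an SI-time curve exceeds the contrast-arrival threshold."""


class UndefinedRatioError(CMRPostError):
    """A ratio quantity is requested with a zero denominator."""


class FitFailureError(CMRPostError):
    """A model fit diverged or produced a non-physical parameter."""


class UnsupportedFieldError(CMRPostError):
    """Field strength for which the quantitative method is not validated."""


class InvalidWindowError(CMRPostError):
    """Velocity window inconsistent with the VENC dynamic range."""


class UnreliableFitError(CMRPostError):
    """Background-offset fit attempted on too few stationary pixels."""


class GeometryError(CMRPostError):
    """Generic geometric failure (shape mismatch, line misses contour, empty mask)."""


class DomainError(CMRPostError):
    """Numeric input outside the operation's domain."""


class ValidationError(CMRPostError):
    """Schema validation of an external file failed; message names the field."""
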