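"""Exception hierarchy for rtkquant.

All errors raised by the library derive from :class:`RtkQuantError` so that
callers (and the CLI) can catch analysis failures without masking genuine
programming errors.
"""


class RtkQuantError(Exception):
    """Base class for all rtkquant errors."""


class GeometryError(RtkQuantError):
    """ROI polygon is invalid, empty, or outside the image bounds."""


class ValidationError(RtkQuantError):
    """Input data or configuration violates a documented contract."""


class InsufficientDataError(RtkQuantError):
    """Too few observations for the requested fit or test."""


class CorrectionError(RtkQuantError):
    """Background/photofading correction is undefined (non-positive denominator)."""


class FitError(RtkQuantError):
    """A nonlinear fit failed to converge or is degenerate."""


class NoBleachError(FitError):
    """No detectable bleach depth in the post-bleach frame."""


class NoRiseError(RtkQuantError):
    """Time course peaks at the first observation; rise slope undefined."""
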