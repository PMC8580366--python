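"""Exception hierarchy for entropimg.

All package errors derive from :class:`EntropimgError` so callers (and the
CLI) can catch one base class. Degenerate numerical conditions that the
imaging pipeline tolerates (zero-variance windows, undefined sample entropy)
are signalled with NaN markers rather than exceptions; the exceptions below
mark conditions the caller must fix.
"""


class EntropimgError(Exception):
    """Base class for all entropimg errors."""


class DegenerateSeriesError(EntropimgError):
    """Series has zero variance where variability is required."""


class SeriesTooShortError(EntropimgError):
    """Series shorter than the minimum length for the requested embedding."""


class ParameterError(EntropimgError):
    """A parameter value is outside its valid domain."""


class FormatError(EntropimgError):
    """RF container file or sidecar is malformed or inconsistent."""


class GeometryError(EntropimgError):
    """Analysis window does not fit the frame."""


class DegenerateImageError(EntropimgError):
    """Image content is degenerate (e.g. all-zero envelope, all-missing map)."""


class MaskError(EntropimgError):
    """ROI mask is empty or incompatible with the image."""


class InsufficientDataError(EntropimgError):
    """Too few usable frames/subjects for the requested statistic."""


class ClassError(EntropimgError):
    """Binary-label vector does not contain both classes."""


class PairingError(EntropimgError):
    """Paired score vectors do not align subject-for-subject."""
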