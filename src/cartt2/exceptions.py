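"""Exception hierarchy for the cartt2 package."""


class CartT2Error(Exception):
    """Base class for all package errors."""


class ConfigurationError(CartT2Error):
    """A configuration field is missing, out of range, or inconsistent."""


class GeometryError(CartT2Error):
    """Requested cartilage-band geometry does not fit the image grid."""


class InputError(CartT2Error):
    """Input data violate a precondition (shape mismatch, too few echoes, ...)."""


class EmptyROIError(CartT2Error):
    """A region of interest contains no usable pixels or pixel pairs."""


class ValidationError(CartT2Error):
    """An ordinal lesion score is not on its declared scale."""


class DegenerateDataError(CartT2Error):
    """Data are degenerate for the requested statistic (zero variance, separation, ...)."""
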