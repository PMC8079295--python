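"""Exception hierarchy for the shuttlebox package."""


class ShuttleboxError(Exception):
    """Base class for all package-specific errors."""


class ProtocolError(ShuttleboxError):
    """Invalid dissolved-oxygen trial protocol (e.g. non-decreasing step targets)."""


class FormatError(ShuttleboxError):
    """Malformed position-log or recording file; message names the offending line."""


class GeometryError(ShuttleboxError):
    """Invalid arena geometry or a point outside the arena footprint."""


class ConfigError(ShuttleboxError):
    """Invalid simulation or analysis configuration."""


class InsufficientDataError(ShuttleboxError):
    """Not enough observations / DO levels for the requested model."""


class DegenerateTestError(ShuttleboxError):
    """A hypothesis test cannot be computed (e.g. all differences are zero)."""
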