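"""Exception hierarchy for oxishelf.

Every error raised deliberately by the package derives from
:class:`OxishelfError`, so callers (and the CLI) can distinguish domain
failures from programming errors.
"""


class OxishelfError(Exception):
    """Base class for all oxishelf domain errors."""


class ProfileError(OxishelfError):
    """Invalid fatty-acid profile: unknown code, negative or non-numeric
    percentage, or a total exceeding 100% beyond rounding tolerance."""


class ParameterError(OxishelfError):
    """Invalid simulation or model parameter."""


class DetectionError(OxishelfError):
    """Induction-period detection failed on the given curve."""


class NoOnsetError(DetectionError):
    """The two fitted tangents are too nearly parallel: no oxidation onset
    is present in the record."""


class BreakpointOutOfRecordError(DetectionError):
    """The tangent intersection falls outside the recorded time span."""


class InsufficientDataError(OxishelfError):
    """Not enough usable observations for the requested fit."""


class ExtrapolationError(OxishelfError):
    """Shelf-life extrapolation requested at or above the fitted
    temperature range (only downward extrapolation to ambient is valid)."""


class SchemaError(OxishelfError):
    """A CSV/JSON input does not match the expected schema."""
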