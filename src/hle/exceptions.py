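"""Exception hierarchy for the hle package."""


class HleError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(HleError, ValueError):
    """Input data violate a schema or domain constraint."""


class GridMismatchError(ValidationError):
    """Two objects were combined that live on different age grids."""


class DegenerateTableError(HleError):
    """A life table cannot be closed (no mortality in the open interval
    while survivors still reach it)."""
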