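"""Exception types shared across the package."""


class SwathAggError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(SwathAggError):
    """A footprint or polygon is degenerate or otherwise unusable."""


class FormatError(SwathAggError):
    """An input file is missing a required variable/column or attribute."""


class ValidationError(SwathAggError):
    """Input values violate a documented contract (e.g. negative population)."""
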