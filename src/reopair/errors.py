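"""Exception types shared across the package."""


class ReopairError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ReopairError, ValueError):
    """Malformed input: bad tables, duplicate identifiers, missing values,
    unknown features or labels, out-of-range parameters."""


class EmptyResultError(ReopairError):
    """A pipeline stage produced no usable output (e.g. zero candidate
    pairs survived screening)."""
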