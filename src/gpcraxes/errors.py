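"""Exceptions shared across the package."""


class GpcrAxesError(Exception):
    """Base class for package errors."""


class SchemaError(GpcrAxesError):
    """An input table violates its declared schema or an invariant."""


class DegenerateInputError(GpcrAxesError):
    """Input is structurally valid but statistically unusable
    (constant vector, empty stratum, too few samples)."""
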