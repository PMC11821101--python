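"""Exception hierarchy shared across the package."""


class CdkdError(Exception):
    """Base class for all package errors."""


class InputError(CdkdError):
    """Missing, empty, or unreadable input."""


class ShapeError(CdkdError):
    """Array shapes are inconsistent (frames, matrices, vectors)."""


class ValidationError(CdkdError):
    """Content violates a data-model invariant (labels, lengths, symmetry)."""


class ConfigurationError(CdkdError):
    """Parameters are out of range or mutually inconsistent."""


class DegenerateInputError(CdkdError):
    """Input is structurally valid but degenerate for the requested
    operation (e.g. a zero-norm vector passed to cosine similarity)."""
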