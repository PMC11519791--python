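"""Exception types shared across the package."""


class AtriamapError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(AtriamapError, ValueError):
    """A generator or analysis parameter violates its documented preconditions."""


class FormatError(AtriamapError, IOError):
    """A movie stack and its metadata sidecar are missing, inconsistent, or malformed."""


class DegenerateSignalError(AtriamapError, ValueError):
    """A trace has no usable dynamic range (flat, all-noise, or missing a transition)."""
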