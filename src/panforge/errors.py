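"""Exception types shared across the package."""


class PanforgeError(Exception):
    """Base class for package errors."""


class FormatError(PanforgeError):
    """An input file violates the supported format subset."""


class InvalidStateError(PanforgeError):
    """An operation was called before its prerequisites were computed."""


class SaturationError(PanforgeError, ValueError):
    """A distance correction is undefined because divergence is saturated."""
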