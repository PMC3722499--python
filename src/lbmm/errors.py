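"""Exception hierarchy shared by all lbmm modules."""


class LbmmError(Exception):
    """Base class for all toolkit errors."""


class FormatError(LbmmError):
    """An on-disk container is missing or malformed."""


class ValidationError(LbmmError):
    """Data violates a container or contract invariant."""


class ParameterError(LbmmError, ValueError):
    """A user-supplied parameter is out of its valid range."""


class DegenerateInputError(LbmmError, ValueError):
    """Input is numerically degenerate (e.g. zero baseline gravity vector)."""
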