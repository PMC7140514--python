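"""Exception types shared across the package."""


class NeurophenolabError(Exception):
    """Base class for package errors."""


class InvalidConfigError(NeurophenolabError, ValueError):
    """A simulation or analysis configuration violates its invariants."""


class InvalidParameterError(NeurophenolabError, ValueError):
    """An operation was called with parameters outside its valid domain."""


class MissingChannelError(NeurophenolabError, KeyError):
    """A required image channel is absent from the stack."""


class MissingPhaseError(NeurophenolabError, ValueError):
    """An OCR profile lacks one of the four injection phases."""


class MissingReferenceError(NeurophenolabError, ValueError):
    """A Ct table lacks the reference gene or reference condition."""
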