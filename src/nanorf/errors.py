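"""Exception hierarchy."""


class NanoRFError(Exception):
    """Base class for all package errors."""


class FormatError(NanoRFError):
    """An on-disk artifact does not conform to its dialect."""


class ValidationError(NanoRFError):
    """An in-memory object violates an invariant."""


class DesignError(ValidationError):
    """The experiment design is inconsistent with the quantification table."""


class TrainingError(ValidationError):
    """A training set is unusable (too few members after intersection, overlap...)."""
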