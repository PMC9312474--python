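"""Exception hierarchy."""


class TransectVarpartError(Exception):
    """Base class for package errors."""


class FormatError(TransectVarpartError):
    """A delimited-text input does not have the expected layout."""


class IntegrityError(TransectVarpartError):
    """Input data violate a structural invariant of the sampling design."""


class DesignError(TransectVarpartError):
    """The factor layout is not supported (e.g. unbalanced design)."""


class NumericError(TransectVarpartError):
    """A numerical routine failed to converge within its safeguards."""
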