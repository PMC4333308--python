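"""Exception hierarchy for rafkit."""


class CrsError(Exception):
    """Base class for all rafkit errors."""


class ValidationError(CrsError):
    """A CRS violates one or more structural invariants.

    Carries the full list of violation descriptions in ``violations``.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations) or "invalid CRS")


class ParseError(CrsError):
    """Syntax error in a CRS text document; carries the 1-based line number."""

    def __init__(self, message, lineno=None):
        self.lineno = lineno
        if lineno is not None:
            message = f"line {lineno}: {message}"
        super().__init__(message)


class UnknownIdError(CrsError):
    """An operation referenced a molecule or reaction id absent from the CRS."""


class InvalidSpecError(CrsError):
    """Parameters of a generator, family, or boundary spec are out of range."""


class SizeLimitError(CrsError):
    """An exhaustive operation was asked to run above its hard size limit."""


class NoRafError(CrsError):
    """An operation requiring a non-empty maximal RAF found none."""


class PreconditionError(CrsError):
    """An operation's documented precondition does not hold for its inputs."""
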