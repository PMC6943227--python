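"""Exception hierarchy shared across the package.

All errors raised on user input derive from :class:`EngraftError` so callers
can catch one base class; they also derive from the closest builtin
(``ValueError`` / ``KeyError``) so untyped callers behave sensibly.
"""


class EngraftError(Exception):
    """Base class for all errors raised by fmt_engraft."""


class ParseError(EngraftError, ValueError):
    """A file could not be parsed; the message names the offending cell."""


class ValidationError(EngraftError, ValueError):
    """A table or record violates a schema invariant."""


class UndefinedInputError(EngraftError, ValueError):
    """The requested quantity is mathematically undefined for this input
    (e.g. Shannon index of an all-zero profile)."""


class SimSpecError(EngraftError, ValueError):
    """A simulation specification is internally inconsistent."""


class ConfigError(EngraftError, ValueError):
    """A pipeline/CLI configuration is invalid (usage error)."""


class NotFoundError(EngraftError, KeyError):
    """A requested species/sample/subject is absent from the table."""


class DegenerateTargetError(EngraftError, ValueError):
    """A model target is degenerate (single class / constant) and the model
    is skipped; drivers catch this and record the reason."""
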