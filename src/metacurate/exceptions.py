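"""Exception taxonomy shared by all modules.

The CLI maps these onto stable exit codes (see :mod:`metacurate.cli`), so
scripts can distinguish "your file is malformed" from "your vocabulary is
inconsistent" from "a GLP rule was violated".
"""


class MetacurateError(Exception):
    """Base class for every error raised by this package."""


class ParseError(MetacurateError):
    """A delimited-text or JSON input could not be parsed.

    Carries enough context (file, line/row, key) to locate the defect.
    """


class VocabularyValidationError(MetacurateError):
    """A vocabulary violates its structural invariants.

    ``violations`` lists every violation found, not just the first.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            "vocabulary validation failed:\n" + "\n".join(f"  - {v}" for v in violations)
        )


class GLPViolationError(MetacurateError):
    """An action was attempted in GLP mode without a justification."""


class StageError(MetacurateError):
    """A curation operation was called outside its pipeline stage."""


class DecisionError(MetacurateError):
    """A proposal decision is unknown, duplicated, or malformed."""


class IntegrationError(MetacurateError):
    """Integration preconditions not met (dataset count, duplicate ids...)."""


class ReplayError(MetacurateError):
    """An audit record does not apply cleanly during replay.

    ``seq`` identifies the failing record.
    """

    def __init__(self, seq: int, message: str):
        self.seq = seq
        super().__init__(f"replay failed at record seq={seq}: {message}")


class SessionFormatError(MetacurateError):
    """A session file carries an unsupported format version."""
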