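"""Exception hierarchy.

Every error carries a machine-readable ``kind`` alongside the human message,
so callers (and tests) can dispatch on the failure class without string
matching.
"""

from __future__ import annotations


class ScoreKitError(Exception):
    """Base class for all scorekit errors."""

    kind: str = "error"

    def __init__(self, message: str, *, kind: str | None = None):
        super().__init__(message)
        if kind is not None:
            self.kind = kind


class NameParseError(ScoreKitError):
    """A score name does not conform to the naming grammar."""

    kind = "name-parse"


class ParameterError(ScoreKitError):
    """A kernel or transform parameter is out of its admissible range."""

    kind = "parameter"


class SpecificationError(ScoreKitError):
    """A declarative specification (catalog entry, level groups, ...) is
    self-contradictory."""

    kind = "specification"


class ValidationFailure(ScoreKitError):
    """Raised by the engine when input validation reports violations.

    Carries the full structured report; the message lists every violation
    at once rather than failing on the first.
    """

    kind = "validation"

    def __init__(self, violations):
        self.violations = list(violations)
        lines = "; ".join(v.message for v in self.violations)
        super().__init__(f"input validation failed: {lines}")


class LoadError(ScoreKitError):
    """A file could not be loaded into the expected structure."""

    kind = "load"


class NormDomainError(ScoreKitError):
    """A raw score falls outside the norm table's raw-score domain for its
    stratum, or the stratum itself is unknown."""

    kind = "norm-domain"


class ConfigurationError(ScoreKitError):
    """The run or table configuration is incomplete (e.g. no event order
    defined where one is required)."""

    kind = "configuration"
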