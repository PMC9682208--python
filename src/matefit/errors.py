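"""Exception hierarchy shared across matefit modules."""

from __future__ import annotations


class MatefitError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MatefitError):
    """The input table does not conform to the documented column schema."""


class ValidationError(MatefitError):
    """One or more records violate a data-model invariant.

    Carries the full list of violations so callers can report all problems
    at once instead of failing on the first.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        msg = "; ".join(self.violations[:10])
        if len(self.violations) > 10:
            msg += f" (+{len(self.violations) - 10} more)"
        super().__init__(f"{len(self.violations)} validation violation(s): {msg}")


class InsufficientDataError(MatefitError):
    """Fewer observations than the statistic requires (e.g. length < 2)."""


class DegenerateGroupError(MatefitError):
    """A group is degenerate for the requested statistic (e.g. zero mean)."""


class DesignError(MatefitError):
    """The experimental design in the data cannot support the requested fit."""


class CapabilityError(MatefitError):
    """The input dialect lacks the detail required by the requested analysis."""


class StageError(MatefitError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}")
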