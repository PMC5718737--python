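"""Exception hierarchy.

Every error raised on purpose by this package derives from :class:`Tg43Error`,
so callers (and the CLI) can distinguish domain failures from bugs.
"""

from __future__ import annotations


class Tg43Error(Exception):
    """Base class for all errors raised by tg43seed."""


class FormatError(Tg43Error):
    """A file or document could not be parsed against the expected schema."""


class ValidationError(Tg43Error):
    """One or more invariants of a domain object failed.

    Parameters
    ----------
    violations:
        Human-readable description of each failed check.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class DomainError(Tg43Error, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ExtractionError(Tg43Error):
    """A dose-rate grid lacks the structure needed to extract a TG-43 function."""


class DegenerateInputError(Tg43Error):
    """Input is formally valid but degenerate (e.g. zero dose at the reference point)."""


class ExtrapolationError(Tg43Error):
    """A query point lies outside the tabulated range; extrapolation is never silent."""


class CalibrationError(Tg43Error):
    """TLD calibration data is missing or unusable."""


class UnderdeterminedError(Tg43Error):
    """Too few data points to determine the requested fit."""
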