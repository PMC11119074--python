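"""Exception hierarchy for pharmcat.

All errors raised by the library derive from :class:`PharmcatError`, so
callers (including the CLI) can catch a single base class.
"""


class PharmcatError(Exception):
    """Base class for all pharmcat errors."""


class InstrumentSchemaError(PharmcatError):
    """An instrument config document violates the instrument schema."""


class AssessmentValidationError(PharmcatError):
    """An assessment violates the instrument's constraints.

    Carries the list of violations that :func:`validate_assessment` found.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        msg = "; ".join(str(v) for v in self.violations)
        super().__init__(f"invalid assessment: {msg}")


class InsufficientDataError(PharmcatError):
    """Too few observations for the requested statistic."""


class DegenerateDistributionError(PharmcatError):
    """Score distribution too concentrated to split into three categories."""


class UndefinedKappaError(PharmcatError):
    """Weighted kappa is undefined (all mass in one category for both raters)."""

    def __init__(self, msg: str, perfect_agreement: bool = False):
        super().__init__(msg)
        #: True when the table is all-diagonal-in-one-cell, i.e. the raters
        #: agree perfectly but chance-corrected agreement cannot be quantified.
        self.perfect_agreement = perfect_agreement


class ParseError(PharmcatError):
    """A CSV/JSON input could not be parsed; names the offending row/column."""
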