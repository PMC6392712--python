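"""Typed error hierarchy.

Validation is total: malformed input raises one of these, never a silent
coercion. The CLI maps :class:`PhysmigError` to exit code 2 and
:class:`DegenerateStatisticsError` (and subclasses) to exit code 3.
"""


class PhysmigError(Exception):
    """Base class for all package errors."""


class SchemaError(PhysmigError):
    """A required column or field is missing from an input file."""


class IntegrityError(PhysmigError):
    """Duplicate keys or inconsistent identifiers in an input."""


class ValidationError(PhysmigError):
    """A value violates a domain invariant (negative count, bad window...)."""


class DegenerateStatisticsError(PhysmigError):
    """A statistical routine received a degenerate problem."""


class DegenerateDesignError(DegenerateStatisticsError):
    """Constant covariate or too few observations for a regression."""


class CollinearityError(DegenerateStatisticsError):
    """Rank-deficient regression design; carries the dependent columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; linearly dependent columns: "
            + ", ".join(self.columns)
        )
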