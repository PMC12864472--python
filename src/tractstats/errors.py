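"""Exception hierarchy for tractstats.

Every documented failure mode raises one of these, never a bare
``ValueError``/``KeyError``, so callers (and the CLI exit-code mapping)
can distinguish malformed input from degenerate statistics.
"""


class TractStatsError(Exception):
    """Base class for all tractstats errors."""


class SchemaError(TractStatsError):
    """An input table is missing a required column or has an unmappable header."""


class ProfileValidationError(TractStatsError):
    """A tract-profile table violates a dataset invariant.

    Carries ``details``: a list of offending coordinates, e.g. ragged
    (subject, tract) pairs or out-of-range cells.
    """

    def __init__(self, message, details=None):
        super().__init__(message)
        self.details = list(details) if details is not None else []


class DemographicsError(TractStatsError):
    """A demographics row violates a subject-record invariant."""


class MissingProfileError(TractStatsError, KeyError):
    """Lookup of a (subject, tract) profile that is absent from the dataset."""


class GridRangeError(TractStatsError):
    """A node or node interval falls off the dataset's node grid."""


class SingularDesignError(TractStatsError):
    """Design matrix is rank deficient; ``terms`` names the collinear columns."""

    def __init__(self, message, terms=None):
        super().__init__(message)
        self.terms = list(terms) if terms is not None else []


class DegenerateDataError(TractStatsError):
    """A statistic is undefined on the data (zero variance, zero residuals...)."""


class SampleSizeError(TractStatsError):
    """Too few observations for the requested analysis."""


class ConfigError(TractStatsError):
    """Invalid run or simulation configuration."""


class ReconciliationError(TractStatsError):
    """Subject ids do not match across input files; ``orphans`` lists them."""

    def __init__(self, message, orphans=None):
        super().__init__(message)
        self.orphans = list(orphans) if orphans is not None else []
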