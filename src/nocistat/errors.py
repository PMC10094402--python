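"""Exception hierarchy for nocistat.

All domain errors derive from :class:`NocistatError` so callers can catch
one base class at pipeline boundaries.
"""


class NocistatError(Exception):
    """Base class for all nocistat domain errors."""


class ValidationError(NocistatError, ValueError):
    """Input data violates a schema or domain invariant."""


class UndefinedStatisticError(NocistatError, ZeroDivisionError):
    """A ratio statistic is undefined (zero denominator)."""


class InsufficientDataError(NocistatError, ValueError):
    """Too few points / groups to fit the requested model."""


class RankDeficiencyError(NocistatError, ValueError):
    """Design matrix is rank deficient (e.g. all doses identical)."""


class NoAsymptoteError(NocistatError, ValueError):
    """Double-reciprocal regression has a non-positive intercept, so no
    finite maximal effect exists."""


class UndefinedED50Error(NocistatError, ValueError):
    """Dose-response slope is zero; no dose attains the target effect."""


class UndefinedRatioError(NocistatError, ValueError):
    """Common slope is numerically zero; relative potency undefined."""


class UnsupportedDesignError(NocistatError, ValueError):
    """ANOVA design is unbalanced or otherwise unsupported."""
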