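"""Exception hierarchy shared across the package."""


class VancoTDMError(Exception):
    """Base class for all package errors."""


class InvalidInputError(VancoTDMError, ValueError):
    """A value violates a precondition (non-positive weight, negative CrCl, ...)."""


class NonPhysiologicLevelsError(VancoTDMError, ValueError):
    """A serum-level pair cannot arise from first-order elimination
    (e.g. the later level is not lower), so it is unusable for estimation."""


class DegenerateTableError(VancoTDMError, ValueError):
    """A 2x2 contingency table has a zero marginal, so the chi-square
    statistic is undefined."""


class CohortSchemaError(VancoTDMError):
    """A cohort file is missing a required column or is otherwise unreadable."""
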