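"""Contingency tests and descriptive statistics for stratified attainment data.

The 2x2 chi-square is the uncorrected Pearson statistic
``N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))`` on 1 df — no Yates continuity
correction. The Fisher exact test is two-sided under the probability-mass
convention (sum of hypergeometric probabilities of all tables with the
observed margins that are no more probable than the observed table).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

from .errors import DegenerateTableError, InvalidInputError

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "NumericSummary",
    "chi_square_2x2",
    "fisher_exact_2x2",
    "describe_numeric",
    "format_p",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows are strata, columns are outcomes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise InvalidInputError(f"count {name} must be a non-negative integer, got {v!r}")
        if self.n < 1:
            raise InvalidInputError("table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def row_sums(self) -> tuple[int, int]:
        return (self.a + self.b, self.c + self.d)

    @property
    def col_sums(self) -> tuple[int, int]:
        return (self.a + self.c, self.b + self.d)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class TestResult:
    """A test statistic (chi-square only; None for Fisher) and its p-value."""

    statistic: float | None
    p_value: float
    method: Literal["pearson_chi2", "fisher_exact_two_sided"]


def chi_square_2x2(table: ContingencyTable2x2) -> TestResult:
    """Uncorrected Pearson chi-square on a 2x2 table, p from chi2(1 df).

    Raises :class:`DegenerateTableError` if any row or column sum is zero.
    """
    if min(table.row_sums) == 0 or min(table.col_sums) == 0:
        raise DegenerateTableError(f"zero marginal in table {table}")
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    n = a + b + c + d
    statistic = n * (a * d - b * c) ** 2 / (
        (a + b) * (c + d) * (a + c) * (b + d)
    )
    p = float(sps.chi2.sf(statistic, df=1))
    return TestResult(statistic=statistic, p_value=p, method="pearson_chi2")


def fisher_exact_2x2(table: ContingencyTable2x2) -> TestResult:
    """Two-sided Fisher exact test (probability-mass convention).

    A table with a zero marginal is deterministic given its margins, so
    p = 1 by convention.
    """
    if min(table.row_sums) == 0 or min(table.col_sums) == 0:
        return TestResult(statistic=None, p_value=1.0, method="fisher_exact_two_sided")
    _, p = sps.fisher_exact(table.as_array(), alternative="two-sided")
    return TestResult(statistic=None, p_value=float(min(p, 1.0)), method="fisher_exact_two_sided")


@dataclass(frozen=True)
class NumericSummary:
    mean: float
    sd: float
    median: float
    iqr: float
    q1: float
    q3: float
    minimum: float
    maximum: float
    n: int


def describe_numeric(values: Sequence[float]) -> NumericSummary:
    """Mean, sample SD (n-1 denominator; 0 for a single value), median and
    IQR (Q3 - Q1 with linear-interpolation quantiles) of a nonempty sample."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise InvalidInputError("cannot summarize an empty sample")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("sample contains non-finite values")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    q1, med, q3 = (float(q) for q in np.percentile(arr, [25, 50, 75], method="linear"))
    return NumericSummary(
        mean=float(np.mean(arr)), sd=sd, median=med, iqr=q3 - q1,
        q1=q1, q3=q3, minimum=float(arr.min()), maximum=float(arr.max()),
        n=int(arr.size),
    )


def format_p(p: float) -> str:
    """p to 4 decimal places, or '<0.00001' below that resolution."""
    if p < 1e-5:
        return "<0.00001"
    return f"{p:.4f}"
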