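"""Published stratified counts from the motivating retrospective cohort.

A 305-order retrospective review of trough-based vancomycin dosing at a
city hospital reported AUC/MIC target attainment (400-600 mg.h/L, MIC
assumed 1 mg/L) stratified by obesity, plus AKI rates and an
attainment-by-renal-function comparison. These counts are shipped as
reference data so the contingency engine can be exercised against the
published statistics; patient-level data were never released, so the
counts — not raw orders — are the reproducible input.

Table orientation: rows = stratum, columns = (in category, not in category).
"""

from __future__ import annotations

from .stats import ContingencyTable2x2, TestResult, chi_square_2x2, fisher_exact_2x2

__all__ = [
    "REFERENCE_COHORT_N",
    "REFERENCE_CATEGORY_COUNTS",
    "ATTAINMENT_BY_OBESITY",
    "ATTAINMENT_BY_CRCL30",
    "reference_contingency_results",
]

#: Orders in the published cohort.
REFERENCE_COHORT_N = 305

#: Overall category counts (of 305): below <400, therapeutic 400-600, above >600,
#: plus AKI events.
REFERENCE_CATEGORY_COUNTS = {
    "below": 106,
    "therapeutic": 85,
    "above": 114,
    "aki": 8,
}

#: Obese (n=75) vs non-obese (n=230) counts for each binary outcome.
ATTAINMENT_BY_OBESITY = {
    "below_goal": ContingencyTable2x2(a=51, b=24, c=55, d=175),
    "above_goal": ContingencyTable2x2(a=9, b=66, c=105, d=125),
    "therapeutic": ContingencyTable2x2(a=15, b=60, c=70, d=160),
    "aki": ContingencyTable2x2(a=4, b=71, c=4, d=226),
}

#: Target attainment (attained / not) for CrCl < 30 mL/min (n=19, all
#: above-goal, none attained) vs CrCl >= 30 mL/min (n=286, 85 attained).
ATTAINMENT_BY_CRCL30 = ContingencyTable2x2(a=0, b=19, c=85, d=201)


def reference_contingency_results() -> dict[str, TestResult]:
    """Run the published stratified counts through the stats engine.

    Returns chi-square results for each obesity-stratified outcome and the
    Fisher exact result for attainment by renal function, computed fresh.
    """
    results: dict[str, TestResult] = {
        f"chi2_{name}_by_obesity": chi_square_2x2(table)
        for name, table in ATTAINMENT_BY_OBESITY.items()
    }
    results["fisher_attainment_by_crcl30"] = fisher_exact_2x2(ATTAINMENT_BY_CRCL30)
    return results
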