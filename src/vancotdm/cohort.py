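"""Order-level cohort pipeline: eligibility, level selection, AUC/MIC
classification, stratification, and AKI detection.

The pipeline mirrors a retrospective therapeutic-drug-monitoring review:
orders are excluded (one-time dose, age < 18, no usable level,
hemodialysis), the earliest steady-state levels are selected, AUC24 is
estimated with the two-level chain when a peak/trough pair exists and the
one-level Matzke chain otherwise, and each order is classified against the
guideline AUC/MIC target of 400-600 mg.h/L and stratified by obesity
(BMI >= 30), baseline renal function, and indication.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from . import pk
from .errors import InvalidInputError, NonPhysiologicLevelsError
from .stats import NumericSummary, describe_numeric

__all__ = [
    "VancoOrder",
    "OrderResult",
    "CohortSummary",
    "PipelineConfig",
    "LevelSelection",
    "ExclusionReason",
    "apply_exclusions",
    "select_levels",
    "classify_target",
    "detect_aki",
    "classify_obesity",
    "stratify_renal",
    "classify_indication",
    "run_pipeline",
    "summarize_cohort",
]

ExclusionReason = Literal["one_time_dose", "age_lt_18", "no_level", "hemodialysis"]
Category = Literal["below", "therapeutic", "above"]
RenalStratum = Literal["lt30", "30to59", "ge60"]
IndicationClass = Literal["uncomplicated", "complicated", "unknown"]

#: Case-insensitive keywords mapping free-text indications to the two
#: published classes; anything unmatched is "unknown".
UNCOMPLICATED_KEYWORDS = (
    "cellulitis", "uti", "urinary", "skin", "ssti", "soft tissue",
)
COMPLICATED_KEYWORDS = (
    "cns", "central nervous", "meningitis",
    "pna", "pneumonia",
    "bone", "joint", "osteomyelitis",
    "bsi", "bloodstream", "bacteremia",
    "sepsis", "septic",
)


@dataclass(frozen=True)
class VancoOrder:
    """One vancomycin order: patient, regimen, measured levels, serial SCr
    (``(day, mg/dL)`` pairs sorted by day, day 0 = baseline), indication
    text, and exclusion flags."""

    order_id: str
    demo: pk.PatientDemographics
    regimen: pk.DosingRegimen
    levels: tuple[pk.SerumLevel, ...]
    scr_series: tuple[tuple[int, float], ...]
    indication_text: str = ""
    one_time_dose: bool = False
    hemodialysis: bool = False

    def __post_init__(self) -> None:
        days = [day for day, _ in self.scr_series]
        if days != sorted(days):
            raise InvalidInputError(f"order {self.order_id}: scr_series must be sorted by day")


@dataclass(frozen=True)
class LevelSelection:
    """The levels chosen for estimation: a peak/trough pair or a lone trough."""

    mode: Literal["two_level", "one_level"]
    levels: tuple[pk.SerumLevel, ...]


@dataclass(frozen=True)
class OrderResult:
    """Per-order pipeline output; excluded orders carry an exclusion reason
    and no estimate, eligible orders the reverse."""

    order_id: str
    eligible: bool
    exclusion_reason: ExclusionReason | None = None
    pk_estimate: pk.PKEstimate | None = None
    crcl: float | None = None
    bmi: float | None = None
    auc_mic: float | None = None
    category: Category | None = None
    obese: bool | None = None
    renal_stratum: RenalStratum | None = None
    indication_class: IndicationClass | None = None
    aki: bool | None = None

    def __post_init__(self) -> None:
        if self.eligible == (self.exclusion_reason is not None):
            raise InvalidInputError("exactly one of exclusion_reason / estimate must be set")
        if self.eligible and self.pk_estimate is None:
            raise InvalidInputError("eligible orders must carry a PK estimate")


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis settings: MIC assumption, guideline AUC/MIC window,
    steady-state dose threshold, and Cockcroft-Gault weight basis."""

    mic: float = 1.0
    target_low: float = 400.0
    target_high: float = 600.0
    ss_dose_threshold: int = 4
    weight_basis: pk.WeightBasis = "actual"
    obesity_bmi_threshold: float = 30.0
    constants: pk.PKConstants = field(default_factory=pk.PKConstants)


def apply_exclusions(
    orders: Iterable[VancoOrder],
) -> tuple[list[VancoOrder], list[tuple[str, ExclusionReason]]]:
    """Split orders into eligible and excluded.

    The first matching rule wins, in the fixed order: one-time dose,
    age < 18, no level available, hemodialysis.
    """
    eligible: list[VancoOrder] = []
    excluded: list[tuple[str, ExclusionReason]] = []
    for order in orders:
        if order.one_time_dose:
            excluded.append((order.order_id, "one_time_dose"))
        elif order.demo.age < 18:
            excluded.append((order.order_id, "age_lt_18"))
        elif len(order.levels) == 0:
            excluded.append((order.order_id, "no_level"))
        elif order.hemodialysis:
            excluded.append((order.order_id, "hemodialysis"))
        else:
            eligible.append(order)
    return eligible, excluded


def select_levels(order: VancoOrder, ss_dose_threshold: int = 4) -> LevelSelection | None:
    """Pick the earliest steady-state levels for estimation.

    Steady state is operationalized as ``dose_number >= ss_dose_threshold``.
    Preference: the earliest interval containing both a peak and a trough
    (two-level branch); otherwise the earliest steady-state trough
    (one-level branch). Ties on draw time break by dose number, then by
    label with trough preferred. Returns None when no steady-state trough
    or pair exists (the order is then excluded as having no usable level).
    """
    ss_levels = [lv for lv in order.levels if lv.dose_number >= ss_dose_threshold]
    by_interval: dict[int, list[pk.SerumLevel]] = {}
    for lv in ss_levels:
        by_interval.setdefault(lv.dose_number, []).append(lv)

    label_rank = {"trough": 0, "peak": 1, "random": 2}

    def order_key(lv: pk.SerumLevel) -> tuple:
        return (lv.draw_time, lv.dose_number, label_rank[lv.label])

    for dose_number in sorted(by_interval):
        group = by_interval[dose_number]
        peaks = sorted((lv for lv in group if lv.label == "peak"), key=order_key)
        troughs = sorted((lv for lv in group if lv.label == "trough"), key=order_key)
        if peaks and troughs:
            return LevelSelection(mode="two_level", levels=(peaks[0], troughs[0]))

    troughs = sorted((lv for lv in ss_levels if lv.label == "trough"), key=order_key)
    if troughs:
        return LevelSelection(mode="one_level", levels=(troughs[0],))
    return None


def classify_target(auc24: float, mic: float = 1.0,
                    low: float = 400.0, high: float = 600.0) -> Category:
    """Classify AUC24/MIC against the guideline window (endpoints inclusive)."""
    if not auc24 > 0 or not mic > 0:
        raise InvalidInputError(f"auc24 and mic must be > 0, got {auc24}, {mic}")
    ratio = auc24 / mic
    if ratio < low:
        return "below"
    if ratio > high:
        return "above"
    return "therapeutic"


def detect_aki(scr_series: Sequence[tuple[int, float]], baseline_scr: float) -> bool:
    """Acute kidney injury per the TDM-guideline creatinine rule.

    True iff two consecutive days each show a serum creatinine rise of at
    least 0.5 mg/dL over baseline or at least 50% over baseline.
    """
    if not baseline_scr > 0:
        raise InvalidInputError(f"baseline SCr must be > 0, got {baseline_scr}")
    if len(scr_series) == 0:
        raise InvalidInputError("scr_series is empty")

    def qualifies(scr: float) -> bool:
        return scr - baseline_scr >= 0.5 or scr >= 1.5 * baseline_scr

    series = sorted(scr_series)
    for (day1, scr1), (day2, scr2) in zip(series, series[1:]):
        if day2 == day1 + 1 and qualifies(scr1) and qualifies(scr2):
            return True
    return False


def classify_obesity(bmi: float, threshold: float = 30.0) -> bool:
    """Obesity: BMI of at least 30 kg/m2 (threshold inclusive)."""
    if not bmi > 0:
        raise InvalidInputError(f"bmi must be > 0, got {bmi}")
    return bmi >= threshold


def stratify_renal(crcl: float) -> RenalStratum:
    """Baseline renal strata: < 30, 30-59, >= 60 mL/min (30 belongs to 30-59)."""
    if crcl < 0:
        raise InvalidInputError(f"crcl must be >= 0, got {crcl}")
    if crcl < 30:
        return "lt30"
    if crcl < 60:
        return "30to59"
    return "ge60"


def classify_indication(text: str) -> IndicationClass:
    """Keyword match of free-text indication into uncomplicated (cellulitis,
    UTI/skin) vs complicated (CNS, pneumonia, bone/joint, bloodstream,
    sepsis); unmatched or empty text is unknown."""
    lowered = (text or "").lower()
    if any(kw in lowered for kw in COMPLICATED_KEYWORDS):
        return "complicated"
    if any(kw in lowered for kw in UNCOMPLICATED_KEYWORDS):
        return "uncomplicated"
    return "unknown"


def _estimate_order(order: VancoOrder, selection: LevelSelection,
                    config: PipelineConfig) -> OrderResult:
    renal = pk.cockcroft_gault(order.demo, config.weight_basis, config.constants)
    if selection.mode == "two_level":
        estimate = pk.estimate_pk_two_level(selection.levels, order.regimen)
    else:
        estimate = pk.estimate_pk_one_level(
            selection.levels[0], renal, order.regimen, config.constants
        )
    bmi = pk.compute_bmi(order.demo.weight, order.demo.height)
    auc_mic = estimate.auc24 / config.mic
    return OrderResult(
        order_id=order.order_id,
        eligible=True,
        pk_estimate=estimate,
        crcl=renal.crcl,
        bmi=bmi,
        auc_mic=auc_mic,
        category=classify_target(estimate.auc24, config.mic,
                                 config.target_low, config.target_high),
        obese=classify_obesity(bmi, config.obesity_bmi_threshold),
        renal_stratum=stratify_renal(renal.crcl),
        indication_class=classify_indication(order.indication_text),
        aki=detect_aki(order.scr_series, order.demo.baseline_scr),
    )


def run_pipeline(
    orders: Sequence[VancoOrder],
    config: PipelineConfig = PipelineConfig(),
) -> list[OrderResult]:
    """Run the full analysis over a cohort; every input order yields exactly
    one :class:`OrderResult` (excluded or estimated)."""
    eligible, excluded = apply_exclusions(orders)
    results: dict[str, OrderResult] = {
        oid: OrderResult(order_id=oid, eligible=False, exclusion_reason=reason)
        for oid, reason in excluded
    }
    for order in eligible:
        selection = select_levels(order, config.ss_dose_threshold)
        if selection is None:
            results[order.order_id] = OrderResult(
                order_id=order.order_id, eligible=False, exclusion_reason="no_level"
            )
            continue
        try:
            results[order.order_id] = _estimate_order(order, selection, config)
        except NonPhysiologicLevelsError:
            # an inverted peak/trough pair is unusable; fall back to the
            # trough-only branch, else treat the order as having no usable level
            trough = next((lv for lv in selection.levels if lv.label == "trough"), None)
            fallback = (
                LevelSelection(mode="one_level", levels=(trough,))
                if selection.mode == "two_level" and trough is not None
                else None
            )
            if fallback is None:
                results[order.order_id] = OrderResult(
                    order_id=order.order_id, eligible=False, exclusion_reason="no_level"
                )
            else:
                results[order.order_id] = _estimate_order(order, fallback, config)
    return [results[o.order_id] for o in orders]


@dataclass(frozen=True)
class CohortSummary:
    """Aggregate cohort description: exclusions, demographics of the
    eligible orders, target attainment overall and per stratum, AUC
    distribution per category, and AKI counts."""

    n_total: int
    n_eligible: int
    n_excluded_by_reason: dict[str, int]
    category_counts: dict[str, int]
    category_counts_by_obesity: dict[str, dict[str, int]]
    category_counts_by_renal: dict[str, dict[str, int]]
    category_counts_by_indication: dict[str, dict[str, int]]
    n_obese: int
    demographics: dict[str, NumericSummary]
    female_count: int
    auc_by_category: dict[str, NumericSummary]
    aki_count: int
    aki_by_obesity: dict[str, int]

    def category_percent(self, category: str) -> float:
        if self.n_eligible == 0:
            return 0.0
        return 100.0 * self.category_counts.get(category, 0) / self.n_eligible


def summarize_cohort(
    results: Sequence[OrderResult],
    orders: Sequence[VancoOrder],
) -> CohortSummary:
    """Descriptive summary of a processed cohort.

    ``results`` must come from :func:`run_pipeline` on ``orders`` (matched
    by order_id). Category counts partition the eligible orders.
    """
    if len(results) == 0:
        raise InvalidInputError("cannot summarize an empty result set")
    order_by_id = {o.order_id: o for o in orders}
    eligible = [r for r in results if r.eligible]
    excluded = [r for r in results if not r.eligible]

    n_excluded: dict[str, int] = {}
    for r in excluded:
        n_excluded[r.exclusion_reason] = n_excluded.get(r.exclusion_reason, 0) + 1

    categories = ("below", "therapeutic", "above")
    category_counts = {c: sum(1 for r in eligible if r.category == c) for c in categories}

    def stratified(key) -> dict[str, dict[str, int]]:
        strata: dict[str, dict[str, int]] = {}
        for r in eligible:
            stratum = key(r)
            bucket = strata.setdefault(stratum, {c: 0 for c in categories})
            bucket[r.category] += 1
        return strata

    by_obesity = stratified(lambda r: "obese" if r.obese else "non_obese")
    by_renal = stratified(lambda r: r.renal_stratum)
    by_indication = stratified(lambda r: r.indication_class)

    demo_values: dict[str, list[float]] = {
        "age_y": [], "weight_kg": [], "scr_mg_dl": [], "crcl_ml_min": [],
        "dose_mg_per_kg": [],
    }
    female_count = 0
    for r in eligible:
        order = order_by_id[r.order_id]
        demo_values["age_y"].append(order.demo.age)
        demo_values["weight_kg"].append(order.demo.weight)
        demo_values["scr_mg_dl"].append(order.demo.baseline_scr)
        demo_values["crcl_ml_min"].append(r.crcl)
        demo_values["dose_mg_per_kg"].append(order.regimen.dose / order.demo.weight)
        if order.demo.sex == "female":
            female_count += 1
    demographics = {
        name: describe_numeric(vals) for name, vals in demo_values.items() if vals
    }

    auc_by_category = {
        c: describe_numeric([r.auc_mic for r in eligible if r.category == c])
        for c in categories
        if any(r.category == c for r in eligible)
    }

    aki_by_obesity = {
        "obese": sum(1 for r in eligible if r.aki and r.obese),
        "non_obese": sum(1 for r in eligible if r.aki and not r.obese),
    }

    return CohortSummary(
        n_total=len(results),
        n_eligible=len(eligible),
        n_excluded_by_reason=n_excluded,
        category_counts=category_counts,
        category_counts_by_obesity=by_obesity,
        category_counts_by_renal=by_renal,
        category_counts_by_indication=by_indication,
        n_obese=sum(1 for r in eligible if r.obese),
        demographics=demographics,
        female_count=female_count,
        auc_by_category=auc_by_category,
        aki_count=sum(1 for r in eligible if r.aki),
        aki_by_obesity=aki_by_obesity,
    )
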