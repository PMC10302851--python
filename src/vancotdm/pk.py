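"""First-order one-compartment vancomycin pharmacokinetics.

Implements the standard two-point ("peak/trough") AUC24 estimation used in
vancomycin therapeutic drug monitoring, plus the population fallbacks needed
when only a single trough is available:

* elimination rate constant Ke from two post-distribution levels,
  ``Ke = ln(C1/C2) / (t2 - t1)``;
* Matzke population regression ``Ke = 0.00083 * CrCl + 0.0044`` (CrCl in
  mL/min, Ke in 1/h) when only one level exists;
* Cockcroft-Gault creatinine clearance,
  ``CrCl = (140 - age) * weight / (72 * SCr)`` (x 0.85 for females);
* back-extrapolation of the true peak to the end of the infusion and
  projection of the true trough to the end of the dosing interval;
* per-interval AUC as linear trapezoid over the infusion phase plus the
  exact exponential area over the elimination phase, scaled to 24 h:
  ``AUC24 = (t_in*(Cmax+Cmin)/2 + (Cmax-Cmin)/Ke) * 24/tau``.

All functions are pure and unit-fixed: concentrations mg/L, times h,
Ke 1/h, AUC mg.h/L, CrCl mL/min, weight kg, height m, SCr mg/dL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

from .errors import InvalidInputError, NonPhysiologicLevelsError

__all__ = [
    "PKConstants",
    "DEFAULT_CONSTANTS",
    "PatientDemographics",
    "DosingRegimen",
    "SerumLevel",
    "RenalFunction",
    "PKEstimate",
    "compute_bmi",
    "ideal_body_weight",
    "cockcroft_gault",
    "matzke_ke",
    "ke_from_two_levels",
    "back_extrapolate_peak",
    "project_trough",
    "peak_from_trough",
    "compute_auc24",
    "estimate_pk_two_level",
    "estimate_pk_one_level",
]

Sex = Literal["male", "female"]
WeightBasis = Literal["actual", "ideal", "adjusted"]


@dataclass(frozen=True)
class PKConstants:
    """Population constants used by the estimation equations.

    Attributes
    ----------
    matzke_slope, matzke_intercept
        Coefficients of the Matzke regression of vancomycin Ke (1/h) on
        creatinine clearance (mL/min).
    cg_age_offset, cg_denominator, cg_female_factor
        Cockcroft-Gault constants: ``(140 - age) * weight / (72 * SCr)``,
        multiplied by 0.85 for females.
    """

    matzke_slope: float = 0.00083
    matzke_intercept: float = 0.0044
    cg_age_offset: float = 140.0
    cg_denominator: float = 72.0
    cg_female_factor: float = 0.85


DEFAULT_CONSTANTS = PKConstants()


@dataclass(frozen=True)
class PatientDemographics:
    """Demographics needed for renal-function and body-size calculations.

    ``weight`` in kg, ``height`` in m, ``baseline_scr`` in mg/dL.
    """

    sex: Sex
    age: int
    weight: float
    height: float
    baseline_scr: float

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise InvalidInputError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.age < 0:
            raise InvalidInputError(f"age must be >= 0, got {self.age}")
        for name in ("weight", "height", "baseline_scr"):
            if not getattr(self, name) > 0:
                raise InvalidInputError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class DosingRegimen:
    """An intermittent-infusion regimen: ``dose`` mg infused over ``t_in`` h
    every ``tau`` h, with the first dose starting at ``start_time`` h."""

    dose: float
    tau: float
    t_in: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if not self.dose > 0:
            raise InvalidInputError(f"dose must be > 0, got {self.dose}")
        if not self.tau > 0:
            raise InvalidInputError(f"tau must be > 0, got {self.tau}")
        if not 0 < self.t_in < self.tau:
            raise InvalidInputError(
                f"infusion duration must satisfy 0 < t_in < tau, got t_in={self.t_in}, tau={self.tau}"
            )

    def dose_start(self, dose_number: int) -> float:
        """Absolute start time (h) of the ``dose_number``-th dose (1-based)."""
        return self.start_time + (dose_number - 1) * self.tau


@dataclass(frozen=True)
class SerumLevel:
    """A measured serum vancomycin concentration.

    ``draw_time`` is hours since the start of the regimen; ``dose_number``
    is the (1-based) ordinal of the dose whose interval the draw falls in.
    """

    concentration: float
    draw_time: float
    dose_number: int
    label: Literal["peak", "trough", "random"] = "random"

    def __post_init__(self) -> None:
        if not self.concentration > 0:
            raise InvalidInputError(f"concentration must be > 0, got {self.concentration}")
        if self.draw_time < 0:
            raise InvalidInputError(f"draw_time must be >= 0, got {self.draw_time}")
        if self.dose_number < 1:
            raise InvalidInputError(f"dose_number must be >= 1, got {self.dose_number}")
        if self.label not in ("peak", "trough", "random"):
            raise InvalidInputError(f"unknown level label {self.label!r}")

    def time_in_interval(self, regimen: DosingRegimen) -> float:
        """Hours elapsed between the start of the dose this draw follows
        and the draw itself."""
        return self.draw_time - regimen.dose_start(self.dose_number)


@dataclass(frozen=True)
class RenalFunction:
    """Creatinine clearance in mL/min."""

    crcl: float

    def __post_init__(self) -> None:
        if self.crcl < 0:
            raise InvalidInputError(f"crcl must be >= 0, got {self.crcl}")


@dataclass(frozen=True)
class PKEstimate:
    """Result of an AUC24 estimation for one order.

    ``cmax``/``cmin`` are the *true* peak (end of infusion) and trough
    (end of interval); ``auc_inf``/``auc_elim`` are the per-interval areas
    over the infusion and elimination phases; ``auc24`` is the 24-h area.
    """

    ke: float
    cmax: float
    cmin: float
    auc_inf: float
    auc_elim: float
    auc24: float
    method: Literal["two_level", "one_level_matzke"]

    def __post_init__(self) -> None:
        if not (self.cmax > self.cmin > 0):
            raise InvalidInputError(
                f"require cmax > cmin > 0, got cmax={self.cmax}, cmin={self.cmin}"
            )
        if not self.ke > 0:
            raise InvalidInputError(f"ke must be > 0, got {self.ke}")

    @property
    def half_life(self) -> float:
        """Elimination half-life in hours, ln(2)/Ke."""
        return math.log(2.0) / self.ke


def compute_bmi(weight: float, height: float) -> float:
    """Body mass index, weight (kg) / height (m) squared."""
    if not weight > 0 or not height > 0:
        raise InvalidInputError(f"weight and height must be > 0, got {weight}, {height}")
    return weight / height**2


def ideal_body_weight(sex: Sex, height: float) -> float:
    """Devine ideal body weight (kg): 50 (male) or 45.5 (female) plus
    2.3 kg per inch of height above 60 inches."""
    if not height > 0:
        raise InvalidInputError(f"height must be > 0, got {height}")
    base = 50.0 if sex == "male" else 45.5
    height_in = height * 100.0 / 2.54
    return base + 2.3 * max(0.0, height_in - 60.0)


def cockcroft_gault(
    demo: PatientDemographics,
    weight_basis: WeightBasis = "actual",
    constants: PKConstants = DEFAULT_CONSTANTS,
) -> RenalFunction:
    """Cockcroft-Gault creatinine clearance (mL/min).

    ``weight_basis`` selects actual, Devine ideal, or adjusted body weight
    (ideal + 0.4 x excess over ideal; actual if below ideal).
    """
    if not demo.baseline_scr > 0:
        raise InvalidInputError(f"SCr must be > 0, got {demo.baseline_scr}")
    if weight_basis == "actual":
        weight = demo.weight
    elif weight_basis == "ideal":
        weight = ideal_body_weight(demo.sex, demo.height)
    elif weight_basis == "adjusted":
        ibw = ideal_body_weight(demo.sex, demo.height)
        weight = ibw + 0.4 * (demo.weight - ibw) if demo.weight > ibw else demo.weight
    else:
        raise InvalidInputError(f"unknown weight basis {weight_basis!r}")
    crcl = (constants.cg_age_offset - demo.age) * weight / (
        constants.cg_denominator * demo.baseline_scr
    )
    if demo.sex == "female":
        crcl *= constants.cg_female_factor
    return RenalFunction(crcl=max(0.0, crcl))


def matzke_ke(renal: RenalFunction | float, constants: PKConstants = DEFAULT_CONSTANTS) -> float:
    """Population vancomycin elimination rate constant (1/h) from
    creatinine clearance via the Matzke regression."""
    crcl = renal.crcl if isinstance(renal, RenalFunction) else float(renal)
    if crcl < 0:
        raise InvalidInputError(f"crcl must be >= 0, got {crcl}")
    return constants.matzke_slope * crcl + constants.matzke_intercept


def ke_from_two_levels(c1: float, t1: float, c2: float, t2: float) -> float:
    """Observed elimination rate constant from two elimination-phase levels:
    ``ln(c1/c2) / (t2 - t1)``.

    Raises :class:`NonPhysiologicLevelsError` unless ``t2 > t1`` and
    ``c1 > c2 > 0`` (a later level must be lower under first-order decay).
    """
    if not (c1 > 0 and c2 > 0):
        raise InvalidInputError(f"concentrations must be > 0, got {c1}, {c2}")
    if t2 <= t1 or c1 <= c2:
        raise NonPhysiologicLevelsError(
            f"levels ({c1} mg/L @ {t1} h, {c2} mg/L @ {t2} h) are not a decaying pair"
        )
    return math.log(c1 / c2) / (t2 - t1)


def back_extrapolate_peak(c_obs: float, ke: float, dt_after_infusion_end: float) -> float:
    """True peak at the end of the infusion from a level drawn
    ``dt_after_infusion_end`` hours later: ``c_obs * exp(ke * dt)``."""
    if not c_obs > 0:
        raise InvalidInputError(f"concentration must be > 0, got {c_obs}")
    if not ke > 0:
        raise InvalidInputError(f"ke must be > 0, got {ke}")
    if dt_after_infusion_end < 0:
        raise InvalidInputError(f"dt must be >= 0, got {dt_after_infusion_end}")
    return c_obs * math.exp(ke * dt_after_infusion_end)


def project_trough(cmax: float, ke: float, tau: float, t_in: float) -> float:
    """True trough at the end of the interval:
    ``cmax * exp(-ke * (tau - t_in))``."""
    if not cmax > 0:
        raise InvalidInputError(f"cmax must be > 0, got {cmax}")
    if not ke > 0:
        raise InvalidInputError(f"ke must be > 0, got {ke}")
    if tau <= t_in or t_in < 0:
        raise InvalidInputError(f"require 0 <= t_in < tau, got t_in={t_in}, tau={tau}")
    return cmax * math.exp(-ke * (tau - t_in))


def peak_from_trough(cmin_obs: float, ke: float, tau: float, t_in: float) -> float:
    """True peak from a measured trough, the algebraic inverse of
    :func:`project_trough`: ``cmin_obs * exp(ke * (tau - t_in))``."""
    if not cmin_obs > 0:
        raise InvalidInputError(f"trough must be > 0, got {cmin_obs}")
    if not ke > 0:
        raise InvalidInputError(f"ke must be > 0, got {ke}")
    if tau <= t_in or t_in < 0:
        raise InvalidInputError(f"require 0 <= t_in < tau, got t_in={t_in}, tau={tau}")
    return cmin_obs * math.exp(ke * (tau - t_in))


def compute_auc24(
    cmax: float, cmin: float, ke: float, t_in: float, tau: float
) -> tuple[float, float, float]:
    """Per-interval AUC components and the 24-h AUC.

    Returns ``(auc_inf, auc_elim, auc24)`` where the infusion phase is a
    linear trapezoid, the elimination phase is the exact exponential area
    ``(cmax - cmin)/ke``, and the sum is scaled by ``24/tau``.
    """
    if not ke > 0:
        raise InvalidInputError(f"ke must be > 0, got {ke}")
    if not 0 < t_in < tau:
        raise InvalidInputError(f"require 0 < t_in < tau, got t_in={t_in}, tau={tau}")
    if not cmin > 0 or cmax <= cmin:
        raise NonPhysiologicLevelsError(
            f"require cmax > cmin > 0, got cmax={cmax}, cmin={cmin}"
        )
    auc_inf = t_in * (cmax + cmin) / 2.0
    auc_elim = (cmax - cmin) / ke
    auc24 = (auc_inf + auc_elim) * (24.0 / tau)
    return auc_inf, auc_elim, auc24


def estimate_pk_two_level(levels: Sequence[SerumLevel], regimen: DosingRegimen) -> PKEstimate:
    """AUC24 from a steady-state peak/trough pair in one dosing interval.

    Chain: observed Ke from the two levels -> back-extrapolate the earlier
    level to the end of the infusion (true Cmax) -> project the true Cmin
    to the end of the interval -> trapezoid + exponential AUC24.

    Both draws must fall in the elimination phase of the same interval.
    """
    if len(levels) != 2:
        raise InvalidInputError(f"exactly two levels required, got {len(levels)}")
    lv1, lv2 = sorted(levels, key=lambda lv: lv.draw_time)
    if lv1.dose_number != lv2.dose_number:
        raise InvalidInputError(
            "two-level estimation requires both draws in the same dosing interval"
        )
    t1 = lv1.time_in_interval(regimen)
    t2 = lv2.time_in_interval(regimen)
    if t1 < regimen.t_in:
        raise InvalidInputError(
            f"first level drawn at {t1} h, during the infusion (t_in={regimen.t_in} h)"
        )
    ke = ke_from_two_levels(lv1.concentration, t1, lv2.concentration, t2)
    cmax = back_extrapolate_peak(lv1.concentration, ke, t1 - regimen.t_in)
    cmin = project_trough(cmax, ke, regimen.tau, regimen.t_in)
    auc_inf, auc_elim, auc24 = compute_auc24(cmax, cmin, ke, regimen.t_in, regimen.tau)
    return PKEstimate(
        ke=ke, cmax=cmax, cmin=cmin,
        auc_inf=auc_inf, auc_elim=auc_elim, auc24=auc24,
        method="two_level",
    )


def estimate_pk_one_level(
    trough: SerumLevel,
    renal: RenalFunction,
    regimen: DosingRegimen,
    constants: PKConstants = DEFAULT_CONSTANTS,
) -> PKEstimate:
    """AUC24 from a single steady-state trough.

    Ke comes from the Matzke regression on creatinine clearance; the
    measured trough is taken as the true trough and the true peak is the
    exponential extrapolation back across the elimination window.
    """
    if renal is None:
        raise InvalidInputError("creatinine clearance is required for one-level estimation")
    ke = matzke_ke(renal, constants)
    cmax = peak_from_trough(trough.concentration, ke, regimen.tau, regimen.t_in)
    cmin = project_trough(cmax, ke, regimen.tau, regimen.t_in)
    auc_inf, auc_elim, auc24 = compute_auc24(cmax, cmin, ke, regimen.t_in, regimen.tau)
    return PKEstimate(
        ke=ke, cmax=cmax, cmin=cmin,
        auc_inf=auc_inf, auc_elim=auc_elim, auc24=auc24,
        method="one_level_matzke",
    )
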