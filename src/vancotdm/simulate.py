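"""Synthetic vancomycin cohorts with known ground-truth pharmacokinetics.

Each simulated order is a steady-state one-compartment intermittent-infusion
patient. Demographics are drawn to match a real 305-order hospital cohort
(mean age ~54 y, weight ~75 kg, ~25% female, ~25% obese, mostly preserved
renal function); individual elimination follows the Matzke population
regression on Cockcroft-Gault clearance, perturbed by log-normal
inter-individual variability, with volume of distribution ~0.7 L/kg.
Serum levels are sampled from the closed-form steady-state concentration
profile with multiplicative log-normal assay noise.

Because the true Ke, clearance and steady-state AUC24 (= 24-h dose / CL)
of every simulated patient are recorded, the generator doubles as the
recovery oracle for the estimation chain: with zero assay noise the
two-level estimator must recover Ke exactly and AUC24 to within the small
trapezoid-vs-exponential discrepancy over the infusion phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import pk
from .errors import InvalidInputError

__all__ = [
    "SyntheticTruth",
    "GeneratorConfig",
    "steady_state_concentration",
    "add_assay_noise",
    "simulate_scr_trajectory",
    "generate_cohort",
]

from .cohort import VancoOrder


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth pharmacokinetics of one simulated order.

    ``auc24_true`` is the exact steady-state 24-h AUC, (dose x 24/tau) / CL.
    """

    order_id: str
    ke_true: float
    vd_true: float
    cl_true: float
    auc24_true: float
    aki_injected: bool

    def __post_init__(self) -> None:
        if not math.isclose(self.cl_true, self.ke_true * self.vd_true, rel_tol=1e-12):
            raise InvalidInputError("cl_true must equal ke_true * vd_true")
        if not self.auc24_true > 0:
            raise InvalidInputError("auc24_true must be > 0")


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-generator settings.

    Demographic defaults target the published cohort's structure (age
    53.8 +/- 18.4 y, weight 74.6 +/- 20.5 kg overall via obese /
    non-obese strata of 97.5 / 67.2 kg, SCr 0.93 +/- 0.69 mg/dL, 24.6%
    female, 24.6% obese, dose ~16.3 mg/kg). Heights are synthetic — the
    source cohort reported BMI class but no heights — drawn through a BMI
    model so the obese fraction is matched by construction.
    """

    n: int = 305
    seed: int = 0

    # demographics
    female_fraction: float = 0.246
    obese_fraction: float = 0.246
    age_mean: float = 53.8
    age_sd: float = 18.4
    age_min: int = 18
    age_max: int = 95
    weight_mean_nonobese: float = 67.2
    weight_sd_nonobese: float = 15.0
    weight_mean_obese: float = 97.5
    weight_sd_obese: float = 22.1
    weight_min: float = 40.0
    bmi_mean_nonobese: float = 25.0
    bmi_sd_nonobese: float = 3.0
    bmi_mean_obese: float = 34.0
    bmi_sd_obese: float = 3.5
    obesity_bmi_threshold: float = 30.0
    bmi_min: float = 16.0
    bmi_max: float = 55.0
    scr_mean_nonobese: float = 0.99
    scr_sd_nonobese: float = 0.77
    scr_mean_obese: float = 0.78
    scr_sd_obese: float = 0.30
    scr_min: float = 0.4
    scr_max: float = 4.0

    # dosing policy: mg/kg rounded to increments; interval from CrCl
    dose_mg_per_kg: float = 16.3
    dose_mg_per_kg_obese: float = 14.4
    dose_rounding_mg: float = 250.0
    dose_min_mg: float = 250.0
    dose_max_mg: float = 3000.0

    # pharmacokinetic truth model
    vd_per_kg: float = 0.7
    iiv_cv_ke: float = 0.2
    iiv_cv_vd: float = 0.2

    # level sampling
    assay_cv: float = 0.1
    pair_fraction: float = 0.7
    level_dose_number: int = 4
    peak_delay_h: float = 1.0
    trough_offset_h: float = 0.5

    # outcomes and exclusions
    aki_rate: float = 0.026
    scr_days: int = 7
    one_time_dose_rate: float = 0.0
    hemodialysis_rate: float = 0.0
    no_level_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InvalidInputError(f"n must be >= 1, got {self.n}")
        for name in ("female_fraction", "obese_fraction", "pair_fraction", "aki_rate",
                     "one_time_dose_rate", "hemodialysis_rate", "no_level_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidInputError(f"{name} must be in [0, 1], got {v}")
        for name in ("age_sd", "weight_sd_nonobese", "weight_sd_obese",
                     "bmi_sd_nonobese", "bmi_sd_obese", "scr_sd_nonobese",
                     "scr_sd_obese", "iiv_cv_ke", "iiv_cv_vd", "assay_cv"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


def steady_state_concentration(
    regimen: pk.DosingRegimen, truth: SyntheticTruth, t_in_interval: float
) -> float:
    """Exact steady-state serum concentration (mg/L) at ``t_in_interval``
    hours into a dosing interval, for a one-compartment model with
    zero-order infusion and first-order elimination.

    At the end of the infusion this equals
    ``Cmax_ss = (dose/(t_in*CL)) * (1 - e^{-ke*t_in}) / (1 - e^{-ke*tau})``
    and decays mono-exponentially until the next dose.
    """
    t = t_in_interval
    if not 0 <= t < regimen.tau:
        raise InvalidInputError(f"time {t} h outside the dosing interval [0, {regimen.tau})")
    ke, cl = truth.ke_true, truth.cl_true
    rate_over_cl = regimen.dose / (regimen.t_in * cl)
    accumulation = math.exp(-ke * regimen.tau) / (1.0 - math.exp(-ke * regimen.tau))
    if t <= regimen.t_in:
        # rising limb plus the decaying residue of all previous doses
        residue = (1.0 - math.exp(-ke * regimen.t_in)) * math.exp(-ke * (t - regimen.t_in))
        return rate_over_cl * ((1.0 - math.exp(-ke * t)) + residue * accumulation)
    cmax_ss = rate_over_cl * (1.0 - math.exp(-ke * regimen.t_in)) / (
        1.0 - math.exp(-ke * regimen.tau)
    )
    return cmax_ss * math.exp(-ke * (t - regimen.t_in))


def add_assay_noise(c_true: float, cv: float, rng: np.random.Generator) -> float:
    """Multiplicative log-normal assay noise with coefficient of variation
    ``cv`` and mean equal to ``c_true``; ``cv = 0`` returns ``c_true``
    without consuming randomness."""
    if cv < 0:
        raise InvalidInputError(f"cv must be >= 0, got {cv}")
    if not c_true > 0:
        raise InvalidInputError(f"concentration must be > 0, got {c_true}")
    if cv == 0:
        return c_true
    sigma2 = math.log1p(cv * cv)
    return c_true * math.exp(rng.normal(-0.5 * sigma2, math.sqrt(sigma2)))


def simulate_scr_trajectory(
    baseline: float, inject_aki: bool, rng: np.random.Generator, n_days: int = 7
) -> tuple[tuple[int, float], ...]:
    """Daily serum-creatinine series starting at the baseline (day 0).

    With ``inject_aki`` the series contains at least two consecutive days
    each exceeding baseline by >= 0.5 mg/dL and >= 50%; without it every
    value is clipped below both criteria, so the guideline AKI rule
    classifies the trajectory correctly by construction.
    """
    if not baseline > 0:
        raise InvalidInputError(f"baseline must be > 0, got {baseline}")
    if n_days < 3:
        raise InvalidInputError(f"n_days must be >= 3, got {n_days}")
    series = [(0, round(baseline, 2))]
    # stay strictly below both qualifying criteria on ordinary days
    safe_cap = min(baseline + 0.45, 1.45 * baseline)
    onset = int(rng.integers(2, n_days - 1)) if inject_aki else -1
    for day in range(1, n_days):
        if inject_aki and onset <= day <= onset + 1:
            scr = max(baseline + 0.6, 1.6 * baseline) * (1.0 + 0.15 * rng.random())
        else:
            scr = min(baseline * (0.88 + 0.24 * rng.random()), safe_cap)
        series.append((day, round(scr, 2)))
    return tuple(series)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    """Rejection-sampled truncated normal (falls back to clipping after
    100 draws, only reachable with extreme configs)."""
    if sd == 0:
        return min(max(mean, lo), hi)
    for _ in range(100):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    return min(max(mean, lo), hi)


def _choose_interval(crcl: float) -> float:
    """Dosing interval (h) from baseline CrCl, emulating renally adjusted
    trough-based practice: q8h for high clearance, q12h for preserved,
    q24h below 60 mL/min."""
    if crcl >= 120:
        return 8.0
    if crcl >= 60:
        return 12.0
    return 24.0


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    if cv == 0:
        return 1.0
    sigma2 = math.log1p(cv * cv)
    return math.exp(rng.normal(-0.5 * sigma2, math.sqrt(sigma2)))


def generate_cohort(
    config: GeneratorConfig = GeneratorConfig(),
) -> tuple[list[VancoOrder], list[SyntheticTruth]]:
    """Generate a reproducible synthetic cohort and its ground truths.

    Per order: demographics are drawn (obesity stratum first, then weight
    and BMI within stratum, height derived from BMI so the obese fraction
    is matched by construction); CrCl comes from Cockcroft-Gault; true Ke
    is the Matzke prediction perturbed by log-normal inter-individual
    variability; Vd ~ ``vd_per_kg`` x weight with its own variability; the
    dose is a mg/kg policy rounded to 250 mg with a CrCl-based interval;
    and levels are sampled from the steady-state profile with assay noise
    (a peak/trough pair with probability ``pair_fraction``, else a trough).
    """
    rng = np.random.default_rng(config.seed)
    orders: list[VancoOrder] = []
    truths: list[SyntheticTruth] = []
    for i in range(config.n):
        order_id = f"SIM{i:04d}"
        obese = rng.random() < config.obese_fraction
        sex = "female" if rng.random() < config.female_fraction else "male"
        age = int(round(_truncated_normal(
            rng, config.age_mean, config.age_sd, config.age_min, config.age_max)))
        if obese:
            weight = _truncated_normal(rng, config.weight_mean_obese,
                                       config.weight_sd_obese, config.weight_min, 250.0)
            bmi = _truncated_normal(rng, config.bmi_mean_obese, config.bmi_sd_obese,
                                    config.obesity_bmi_threshold, config.bmi_max)
            scr = _truncated_normal(rng, config.scr_mean_obese, config.scr_sd_obese,
                                    config.scr_min, config.scr_max)
        else:
            weight = _truncated_normal(rng, config.weight_mean_nonobese,
                                       config.weight_sd_nonobese, config.weight_min, 250.0)
            bmi = _truncated_normal(rng, config.bmi_mean_nonobese, config.bmi_sd_nonobese,
                                    config.bmi_min,
                                    config.obesity_bmi_threshold - 0.1)
            scr = _truncated_normal(rng, config.scr_mean_nonobese, config.scr_sd_nonobese,
                                    config.scr_min, config.scr_max)
        height = math.sqrt(weight / bmi)
        demo = pk.PatientDemographics(
            sex=sex, age=age, weight=round(weight, 1),
            height=round(height, 2), baseline_scr=round(scr, 2),
        )
        crcl = pk.cockcroft_gault(demo).crcl

        mg_per_kg = config.dose_mg_per_kg_obese if obese else config.dose_mg_per_kg
        raw_dose = mg_per_kg * demo.weight
        dose = config.dose_rounding_mg * round(raw_dose / config.dose_rounding_mg)
        dose = min(max(dose, config.dose_min_mg), config.dose_max_mg)
        tau = _choose_interval(crcl)
        t_in = min(max(1.0, dose / 1000.0), tau / 2.0)
        regimen = pk.DosingRegimen(dose=dose, tau=tau, t_in=t_in)

        ke_true = pk.matzke_ke(crcl) * _lognormal_factor(rng, config.iiv_cv_ke)
        vd_true = config.vd_per_kg * demo.weight * _lognormal_factor(rng, config.iiv_cv_vd)
        cl_true = ke_true * vd_true
        auc24_true = dose * (24.0 / tau) / cl_true
        aki = rng.random() < config.aki_rate
        truth = SyntheticTruth(
            order_id=order_id, ke_true=ke_true, vd_true=vd_true,
            cl_true=cl_true, auc24_true=auc24_true, aki_injected=aki,
        )

        no_level = rng.random() < config.no_level_rate
        want_pair = rng.random() < config.pair_fraction
        levels: list[pk.SerumLevel] = []
        if not no_level:
            dn = config.level_dose_number
            t_trough = regimen.tau - config.trough_offset_h
            c_trough = add_assay_noise(
                steady_state_concentration(regimen, truth, t_trough),
                config.assay_cv, rng,
            )
            if want_pair:
                t_peak = regimen.t_in + config.peak_delay_h
                c_peak = add_assay_noise(
                    steady_state_concentration(regimen, truth, t_peak),
                    config.assay_cv, rng,
                )
                levels.append(pk.SerumLevel(
                    concentration=c_peak,
                    draw_time=regimen.dose_start(dn) + t_peak,
                    dose_number=dn, label="peak",
                ))
            levels.append(pk.SerumLevel(
                concentration=c_trough,
                draw_time=regimen.dose_start(dn) + t_trough,
                dose_number=dn, label="trough",
            ))

        scr_series = simulate_scr_trajectory(demo.baseline_scr, aki, rng, config.scr_days)
        indication = rng.choice([
            "sepsis", "pneumonia", "bacteremia", "osteomyelitis", "meningitis",
            "cellulitis", "UTI", "skin and soft tissue infection", "",
        ], p=[0.20, 0.20, 0.15, 0.07, 0.03, 0.13, 0.08, 0.08, 0.06])
        orders.append(VancoOrder(
            order_id=order_id, demo=demo, regimen=regimen,
            levels=tuple(levels), scr_series=scr_series,
            indication_text=str(indication),
            one_time_dose=bool(rng.random() < config.one_time_dose_rate),
            hemodialysis=bool(rng.random() < config.hemodialysis_rate),
        ))
        truths.append(truth)
    return orders, truths
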