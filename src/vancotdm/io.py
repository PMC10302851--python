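"""Cohort file formats, report rendering, and run manifests.

Cohort CSV dialect
------------------
Comma-separated, UTF-8, mandatory header. One row per vancomycin order:

====================  =====================================================
column                meaning
====================  =====================================================
order_id              opaque identifier
sex                   ``male`` / ``female``
age_y                 age, years (integer)
weight_kg             actual body weight, kg
height_m              height, m
baseline_scr_mg_dl    baseline serum creatinine, mg/dL
dose_mg               dose per administration, mg
tau_h                 dosing interval, h
t_in_h                infusion duration, h
start_time_h          regimen start time, h (usually 0)
levels                ``label:conc_mg_l:draw_time_h:dose_number`` entries
                      joined by ``;`` (may be empty)
scr_series            ``day:scr_mg_dl`` entries joined by ``;`` (day 0 =
                      baseline)
indication            free text
one_time_dose         ``true`` / ``false`` (also ``1`` / ``0``)
hemodialysis          ``true`` / ``false``
====================  =====================================================

Malformed rows are collected as :class:`RowError` records, never silently
dropped; a missing column raises :class:`~vancotdm.errors.CohortSchemaError`.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from . import pk
from .cohort import CohortSummary, OrderResult, VancoOrder
from .errors import CohortSchemaError
from .simulate import SyntheticTruth
from .stats import NumericSummary, TestResult, format_p

__all__ = [
    "COHORT_COLUMNS",
    "RowError",
    "RunManifest",
    "read_cohort_csv",
    "write_cohort_csv",
    "write_results_csv",
    "write_truths_csv",
    "write_exclusion_log",
    "render_report",
    "round_half_up",
]

COHORT_COLUMNS = (
    "order_id", "sex", "age_y", "weight_kg", "height_m", "baseline_scr_mg_dl",
    "dose_mg", "tau_h", "t_in_h", "start_time_h",
    "levels", "scr_series", "indication", "one_time_dose", "hemodialysis",
)


@dataclass(frozen=True)
class RowError:
    """A row that could not be parsed into an order."""

    row_index: int
    order_id: str
    message: str


@dataclass(frozen=True)
class RunManifest:
    """Everything needed to reproduce a run: config echo, seed, input
    provenance, package version, timestamp."""

    seed: int | None
    config: dict
    input_source: str
    package_version: str = __version__
    timestamp: str = ""

    @classmethod
    def create(cls, seed: int | None, config: dict, input_source: str) -> "RunManifest":
        return cls(
            seed=seed, config=config, input_source=input_source,
            timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (0.05 -> 0.1), matching printed-report style."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _encode_levels(levels: Sequence[pk.SerumLevel]) -> str:
    return ";".join(
        f"{lv.label}:{lv.concentration!r}:{lv.draw_time!r}:{lv.dose_number}"
        for lv in levels
    )


def _decode_levels(text: str) -> tuple[pk.SerumLevel, ...]:
    text = (text or "").strip()
    if not text:
        return ()
    out = []
    for entry in text.split(";"):
        label, conc, t, dn = entry.split(":")
        out.append(pk.SerumLevel(
            concentration=float(conc), draw_time=float(t),
            dose_number=int(dn), label=label,
        ))
    return tuple(out)


def _encode_scr(series: Sequence[tuple[int, float]]) -> str:
    return ";".join(f"{day}:{scr!r}" for day, scr in series)


def _decode_scr(text: str) -> tuple[tuple[int, float], ...]:
    text = (text or "").strip()
    if not text:
        return ()
    return tuple((int(d), float(s)) for d, s in (e.split(":") for e in text.split(";")))


def _parse_bool(text: str) -> bool:
    t = (text or "").strip().lower()
    if t in ("true", "1", "yes"):
        return True
    if t in ("false", "0", "no", ""):
        return False
    raise ValueError(f"unparseable boolean {text!r}")


def write_cohort_csv(orders: Sequence[VancoOrder], path: str | Path) -> None:
    rows = []
    for o in orders:
        rows.append({
            "order_id": o.order_id,
            "sex": o.demo.sex,
            "age_y": o.demo.age,
            "weight_kg": o.demo.weight,
            "height_m": o.demo.height,
            "baseline_scr_mg_dl": o.demo.baseline_scr,
            "dose_mg": o.regimen.dose,
            "tau_h": o.regimen.tau,
            "t_in_h": o.regimen.t_in,
            "start_time_h": o.regimen.start_time,
            "levels": _encode_levels(o.levels),
            "scr_series": _encode_scr(o.scr_series),
            "indication": o.indication_text,
            "one_time_dose": str(o.one_time_dose).lower(),
            "hemodialysis": str(o.hemodialysis).lower(),
        })
    pd.DataFrame(rows, columns=list(COHORT_COLUMNS)).to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> tuple[list[VancoOrder], list[RowError]]:
    """Parse a cohort CSV into typed orders plus row-level error records."""
    path = Path(path)
    if not path.exists():
        raise CohortSchemaError(f"cohort file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"cohort file {path} is missing columns: {missing}")
    orders: list[VancoOrder] = []
    errors: list[RowError] = []
    for idx, row in df.iterrows():
        oid = str(row["order_id"])
        try:
            demo = pk.PatientDemographics(
                sex=row["sex"].strip().lower(),
                age=int(float(row["age_y"])),
                weight=float(row["weight_kg"]),
                height=float(row["height_m"]),
                baseline_scr=float(row["baseline_scr_mg_dl"]),
            )
            regimen = pk.DosingRegimen(
                dose=float(row["dose_mg"]),
                tau=float(row["tau_h"]),
                t_in=float(row["t_in_h"]),
                start_time=float(row["start_time_h"] or 0.0),
            )
            orders.append(VancoOrder(
                order_id=oid,
                demo=demo,
                regimen=regimen,
                levels=_decode_levels(row["levels"]),
                scr_series=_decode_scr(row["scr_series"]),
                indication_text=str(row["indication"]),
                one_time_dose=_parse_bool(row["one_time_dose"]),
                hemodialysis=_parse_bool(row["hemodialysis"]),
            ))
        except Exception as exc:  # row-level problems must not abort the file
            errors.append(RowError(row_index=int(idx), order_id=oid, message=str(exc)))
    return orders, errors


def write_results_csv(results: Sequence[OrderResult], path: str | Path) -> None:
    rows = []
    for r in results:
        est = r.pk_estimate
        rows.append({
            "order_id": r.order_id,
            "eligible": str(r.eligible).lower(),
            "exclusion_reason": r.exclusion_reason or "",
            "method": est.method if est else "",
            "ke_per_h": f"{est.ke:.6g}" if est else "",
            "cmax_mg_l": f"{est.cmax:.6g}" if est else "",
            "cmin_mg_l": f"{est.cmin:.6g}" if est else "",
            "auc24_mg_h_l": f"{est.auc24:.6g}" if est else "",
            "auc_mic": f"{r.auc_mic:.6g}" if r.auc_mic is not None else "",
            "category": r.category or "",
            "obese": "" if r.obese is None else str(r.obese).lower(),
            "renal_stratum": r.renal_stratum or "",
            "indication_class": r.indication_class or "",
            "aki": "" if r.aki is None else str(r.aki).lower(),
            "crcl_ml_min": f"{r.crcl:.6g}" if r.crcl is not None else "",
            "bmi_kg_m2": f"{r.bmi:.6g}" if r.bmi is not None else "",
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_truths_csv(truths: Sequence[SyntheticTruth], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(t) for t in truths]).to_csv(path, index=False)


def write_exclusion_log(results: Sequence[OrderResult], path: str | Path) -> None:
    """Line-oriented exclusion log: ``order_id<TAB>reason``."""
    lines = [
        f"{r.order_id}\t{r.exclusion_reason}"
        for r in results if not r.eligible
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def _pct(count: int, total: int) -> float:
    return round_half_up(100.0 * count / total, 1) if total else 0.0


def _summary_block(s: NumericSummary) -> dict:
    return {
        "mean": s.mean, "sd": s.sd, "median": s.median, "iqr": s.iqr,
        "q1": s.q1, "q3": s.q3, "min": s.minimum, "max": s.maximum, "n": s.n,
    }


def render_report(
    summary: CohortSummary,
    tests: Sequence[TestResult] | dict[str, TestResult] | None = None,
) -> tuple[str, dict]:
    """Render a cohort summary (and optional contingency-test results) as a
    human-readable text report plus an equivalent JSON-serializable dict.

    Every number printed in the text is taken from the returned dict, so
    the two views cannot diverge.
    """
    if isinstance(tests, dict):
        test_items = list(tests.items())
    elif tests:
        test_items = [(t.method, t) for t in tests]
    else:
        test_items = []

    n_el = summary.n_eligible
    categories = ("below", "therapeutic", "above")
    doc: dict = {
        "n_total": summary.n_total,
        "n_eligible": n_el,
        "excluded": dict(sorted(summary.n_excluded_by_reason.items())),
        "demographics": {k: _summary_block(v) for k, v in summary.demographics.items()},
        "female": {"count": summary.female_count, "percent": _pct(summary.female_count, n_el)},
        "obese": {"count": summary.n_obese, "percent": _pct(summary.n_obese, n_el)},
        "attainment": {
            c: {
                "count": summary.category_counts.get(c, 0),
                "percent": _pct(summary.category_counts.get(c, 0), n_el),
            }
            for c in categories
        },
        "attainment_by_obesity": {
            stratum: {
                c: {"count": counts.get(c, 0),
                    "percent": _pct(counts.get(c, 0), sum(counts.values()))}
                for c in categories
            }
            for stratum, counts in sorted(summary.category_counts_by_obesity.items())
        },
        "attainment_by_renal": {
            stratum: {
                c: {"count": counts.get(c, 0),
                    "percent": _pct(counts.get(c, 0), sum(counts.values()))}
                for c in categories
            }
            for stratum, counts in sorted(summary.category_counts_by_renal.items())
        },
        "auc_mic_by_category": {
            c: _summary_block(s) for c, s in summary.auc_by_category.items()
        },
        "aki": {
            "count": summary.aki_count,
            "percent": _pct(summary.aki_count, n_el),
            "by_obesity": dict(summary.aki_by_obesity),
        },
        "tests": {
            name: {
                "statistic": None if t.statistic is None else round(t.statistic, 2),
                "p_value": t.p_value,
                "p_display": format_p(t.p_value),
                "method": t.method,
            }
            for name, t in test_items
        },
    }

    lines: list[str] = []
    add = lines.append
    add("Vancomycin AUC/MIC target-attainment report")
    add("=" * 44)
    add(f"Orders screened: {doc['n_total']}; eligible: {doc['n_eligible']}")
    if doc["excluded"]:
        add("Excluded: " + ", ".join(f"{k}={v}" for k, v in doc["excluded"].items()))
    add("")
    add("Demographics (eligible orders, mean +/- SD)")
    labels = {
        "age_y": "Age (years)",
        "weight_kg": "Weight (kg)",
        "scr_mg_dl": "SCr (mg/dL)",
        "crcl_ml_min": "CrCl (mL/min)",
        "dose_mg_per_kg": "Dose (mg/kg)",
    }
    for key, label in labels.items():
        if key in doc["demographics"]:
            d = doc["demographics"][key]
            add(f"  {label}: {d['mean']:.1f} +/- {d['sd']:.1f}")
    add(f"  Female: {doc['female']['count']} ({doc['female']['percent']}%)")
    add(f"  Obese (BMI >= 30): {doc['obese']['count']} ({doc['obese']['percent']}%)")
    add("")
    add("AUC/MIC target attainment (400-600 mg.h/L)")
    cat_labels = {"below": "Below goal (<400)",
                  "therapeutic": "Therapeutic (400-600)",
                  "above": "Above goal (>600)"}
    for c in categories:
        att = doc["attainment"][c]
        line = f"  {cat_labels[c]}: {att['count']}/{doc['n_eligible']} ({att['percent']}%)"
        if c in doc["auc_mic_by_category"]:
            s = doc["auc_mic_by_category"][c]
            line += f"   median AUC/MIC {s['median']:.0f} (IQR {s['iqr']:.1f})"
        add(line)
    add("")
    add("Box-plot statistics of AUC/MIC per category (min / Q1 / median / Q3 / max)")
    for c in categories:
        if c in doc["auc_mic_by_category"]:
            s = doc["auc_mic_by_category"][c]
            add(f"  {c}: {s['min']:.0f} / {s['q1']:.0f} / {s['median']:.0f}"
                f" / {s['q3']:.0f} / {s['max']:.0f}")
    add("")
    add("Attainment by obesity stratum")
    for stratum, cats in doc["attainment_by_obesity"].items():
        parts = [f"{c} {cats[c]['count']} ({cats[c]['percent']}%)" for c in categories]
        add(f"  {stratum}: " + ", ".join(parts))
    add("")
    add(f"AKI: {doc['aki']['count']}/{doc['n_eligible']} ({doc['aki']['percent']}%)"
        f" [obese {doc['aki']['by_obesity'].get('obese', 0)},"
        f" non-obese {doc['aki']['by_obesity'].get('non_obese', 0)}]")
    if doc["tests"]:
        add("")
        add("Contingency tests")
        for name, t in doc["tests"].items():
            stat = "" if t["statistic"] is None else f"X2 {t['statistic']:.2f}, "
            add(f"  {name}: {stat}p {t['p_display']}")
    return "\n".join(lines) + "\n", doc
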