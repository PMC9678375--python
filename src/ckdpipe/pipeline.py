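"""Pipeline driver: from labs + patients tables to annual report tables.

One call to :func:`run_pipeline` produces, per calendar year:

* prevalence of biochemical CKD stage G3A/G3B among patients with a
  creatinine measurement who were alive throughout the year;
* the annual uACR testing rate in that prevalent cohort, plus a pooled
  stratified testing table with group comparisons;
* the NICE-2021 referral criterion flags, mutually exclusive categories and
  KFRE summaries (nephrology-followed patients' flags are computed and
  exported but discounted from the category counts);

together with incident CKD counts per eGFR equation and band, a KFRE-by-
ethnicity table, and the equation-switch reclassification summary.  All
counts are emitted with numerators and denominators, never bare
percentages, and a frozen copy of the configuration is written next to the
outputs for provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import monitoring
from .equations import EQUATIONS, KfreParameters, compute_egfr
from .impact import ReclassificationSummary, reclassification_summary
from .phenotyping import (
    EgfrSeries,
    GuidelineThresholds,
    incident_ckd_onset,
    prevalent_g3_in_year,
    year_end_day,
    year_start_day,
)
from .referral import criterion_flags, exclusive_category

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "write_report"]

DAYS_PER_YEAR = 365.25


class PipelineConfig(BaseModel):
    """Validated configuration for a full pipeline run."""

    model_config = ConfigDict(frozen=True)

    thresholds: GuidelineThresholds = GuidelineThresholds()
    equation: str = "mdrd"
    use_ethnicity: bool = False
    kfre_calibration: str = "non_north_american"
    variant: str = "main"
    start_year: int = 2013
    end_year: int = 2020
    pair_window_days: int = 182
    impact_from: str = "mdrd"
    impact_to: str = "ckdepi2021"
    impact_mode: str = "confirmed"

    @property
    def years(self) -> range:
        return range(self.start_year, self.end_year + 1)


@dataclass
class PipelineResult:
    prevalence: pd.DataFrame
    testing: pd.DataFrame
    testing_strata: pd.DataFrame
    testing_tests: dict
    assessments: pd.DataFrame
    category_counts: pd.DataFrame
    kfre_by_ethnicity: pd.DataFrame
    incident_by_equation: pd.DataFrame
    reclassification: dict[str, ReclassificationSummary] = field(default_factory=dict)


def _day_ints(dates: pd.Series) -> np.ndarray:
    return dates.to_numpy().astype("datetime64[D]").astype(np.int64)


def egfr_series_map(
    labs: pd.DataFrame,
    patients: pd.DataFrame,
    equation: str,
    *,
    use_ethnicity: bool = False,
) -> dict[str, EgfrSeries]:
    """Score every creatinine row under one equation, grouped per patient.

    Age is computed at each sample date from date of birth.  Rows from
    patients younger than 18 at sampling are outside the adult guideline
    scope and are dropped.
    """
    creat = labs.loc[labs["creatinine_umol_l"].notna(), ["patient_id", "date", "creatinine_umol_l"]]
    merged = creat.merge(
        patients[["patient_id", "dob", "sex", "ethnicity"]], on="patient_id", how="inner"
    )
    day = _day_ints(merged["date"])
    dob = _day_ints(merged["dob"])
    age = (day - dob) / DAYS_PER_YEAR
    adult = age >= 18.0
    merged, day, age = merged.loc[adult], day[adult], age[adult]
    egfr = compute_egfr(
        merged["creatinine_umol_l"].to_numpy(dtype=float),
        age,
        merged["sex"].to_numpy(),
        equation,
        black=(merged["ethnicity"] == "black").to_numpy(),
        use_ethnicity=use_ethnicity,
    )
    out: dict[str, EgfrSeries] = {}
    order = np.argsort(day, kind="stable")
    pid_arr = merged["patient_id"].to_numpy()[order]
    day_s, egfr_s = day[order], np.asarray(egfr)[order]
    frame = pd.DataFrame({"pid": pid_arr, "day": day_s, "egfr": egfr_s})
    for pid, grp in frame.groupby("pid", sort=True):
        out[str(pid)] = EgfrSeries(str(pid), equation, grp["day"].to_numpy(), grp["egfr"].to_numpy())
    return out


def _acr_map(labs: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    acr = labs.loc[labs["acr_mg_mmol"].notna(), ["patient_id", "date", "acr_mg_mmol"]]
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    day = _day_ints(acr["date"])
    frame = pd.DataFrame({"pid": acr["patient_id"].to_numpy(), "day": day,
                          "val": acr["acr_mg_mmol"].to_numpy(dtype=float)})
    frame = frame.sort_values(["pid", "day"], kind="mergesort")
    for pid, grp in frame.groupby("pid", sort=True):
        out[str(pid)] = (grp["day"].to_numpy(), grp["val"].to_numpy())
    return out


def run_pipeline(
    labs: pd.DataFrame, patients: pd.DataFrame, config: PipelineConfig | None = None
) -> PipelineResult:
    cfg = config or PipelineConfig()
    t = cfg.thresholds
    params = KfreParameters.from_calibration(cfg.kfre_calibration)
    series = egfr_series_map(labs, patients, cfg.equation, use_ethnicity=cfg.use_ethnicity)
    acrs = _acr_map(labs)
    pinfo = patients.set_index("patient_id")
    death_day = pd.Series(
        np.where(
            pinfo["death_date"].notna(),
            pinfo["death_date"].to_numpy().astype("datetime64[D]").astype("float64"),
            np.inf,
        ),
        index=pinfo.index,
    )
    dob_day = pd.Series(_day_ints(pinfo["dob"]), index=pinfo.index)
    empty_acr = (np.array([], dtype=np.int64), np.array([], dtype=float))

    prevalence_rows, testing_rows, assess_rows, records = [], [], [], []
    for year in cfg.years:
        ys, ye = year_start_day(year), year_end_day(year)
        denom_pids = []
        for pid, s in series.items():
            if death_day[pid] <= ye:  # must be alive throughout the year
                continue
            i0 = np.searchsorted(s.days, ys, side="left")
            if i0 >= len(s.days) or s.days[i0] > ye:
                continue  # no in-year creatinine: outside the year's denominator
            denom_pids.append(pid)
        prevalent = [p for p in denom_pids if prevalent_g3_in_year(series[p], year, t)]
        prevalence_rows.append(
            {
                "year": year,
                "n_prevalent_g3": len(prevalent),
                "denominator": len(denom_pids),
                "pct": 100.0 * len(prevalent) / len(denom_pids) if denom_pids else np.nan,
            }
        )
        tested_flags = []
        for pid in prevalent:
            a_days, a_vals = acrs.get(pid, empty_acr)
            tested = bool(np.any((a_days >= ys) & (a_days <= ye)))
            tested_flags.append(tested)
            age_end = (ye - dob_day[pid]) / DAYS_PER_YEAR
            s = series[pid]
            in_year = (s.days >= ys) & (s.days <= ye)
            mean_egfr = float(s.values[in_year].mean())
            row = pinfo.loc[pid]
            records.append(
                {
                    "patient_id": pid,
                    "year": year,
                    "tested": tested,
                    "age": float(age_end),
                    "age_band": monitoring.age_band(age_end)[0],
                    "sex": row["sex"],
                    "egfr_band": monitoring.egfr_band(mean_egfr)[0],
                    "diabetes": bool(row["diabetes"]),
                    "hypertension": bool(row["hypertension"]),
                    "ckd_coded": bool(row["ckd_coded"]),
                }
            )
            flags, max_kfre = criterion_flags(
                s,
                *acrs.get(pid, empty_acr),
                year=year,
                diabetes=bool(row["diabetes"]),
                sex=str(row["sex"]),
                age_at_day=lambda d, pid=pid: (d - dob_day[pid]) / DAYS_PER_YEAR,
                thresholds=t,
                params=params,
                variant=cfg.variant,
                pair_window_days=cfg.pair_window_days,
            )
            category, untestable = exclusive_category(flags)
            assess_rows.append(
                {
                    "patient_id": pid,
                    "year": year,
                    "accel_decline": flags.accel_decline,
                    "albuminuria": flags.albuminuria,
                    "egfr_lt30": flags.egfr_lt30,
                    "kfre_gt5": (
                        "not_computable" if flags.kfre_gt5 is None else str(flags.kfre_gt5).lower()
                    ),
                    "max_kfre": np.nan if max_kfre is None else max_kfre,
                    "category": category,
                    "kfre_untestable": untestable,
                    "excluded_nephrology": bool(row["nephrology_followup"]),
                    "ethnicity": row["ethnicity"],
                }
            )
        rate = monitoring.annual_testing_rate(tested_flags, year)
        testing_rows.append(
            {
                "year": year,
                "tested": rate.numerator,
                "denominator": rate.denominator,
                "rate_pct": 100.0 * rate.rate if rate.rate is not None else np.nan,
            }
        )

    assessments = pd.DataFrame(
        assess_rows,
        columns=[
            "patient_id", "year", "accel_decline", "albuminuria", "egfr_lt30",
            "kfre_gt5", "max_kfre", "category", "kfre_untestable",
            "excluded_nephrology", "ethnicity",
        ],
    )
    cat_rows = []
    for year in cfg.years:
        sub = assessments.loc[assessments["year"] == year]
        counted = sub.loc[~sub["excluded_nephrology"]]
        row = {"year": year, "n_prevalent_g3": int(len(sub)),
               "n_counted": int(len(counted))}
        for cat in ("decline_or_albuminuria", "egfr_lt30_only", "kfre_only", "none"):
            row[cat] = int((counted["category"] == cat).sum())
        row["kfre_untestable"] = int(counted["kfre_untestable"].sum())
        # KFRE>5% among all prevalent with a computable risk, nephrology included
        computable = sub.loc[sub["kfre_gt5"] != "not_computable"]
        row["kfre_gt5_any"] = int((computable["kfre_gt5"] == "true").sum())
        row["kfre_computable"] = int(len(computable))
        cat_rows.append(row)
    category_counts = pd.DataFrame(cat_rows)

    if len(records):
        records_df = pd.DataFrame(records)
        strata, extras = monitoring.stratified_testing_table(records_df)
        tests = extras["tests"]
    else:
        strata, tests = pd.DataFrame(), {}

    eth_rows = []
    if len(assessments):
        computable = assessments.loc[assessments["kfre_gt5"] != "not_computable"]
        for eth, grp in computable.groupby("ethnicity", sort=True):
            eth_rows.append(
                {
                    "ethnicity": eth,
                    "n_assessed": int(len(grp)),
                    "n_kfre_gt5": int((grp["kfre_gt5"] == "true").sum()),
                    "pct": 100.0 * (grp["kfre_gt5"] == "true").mean(),
                }
            )
    kfre_by_ethnicity = pd.DataFrame(eth_rows)

    inc_rows = []
    for eqn in EQUATIONS:
        s_map = series if eqn == cfg.equation and not cfg.use_ethnicity else egfr_series_map(
            labs, patients, eqn
        )
        for band in ("g3_5", "g4_5"):
            counts = dict.fromkeys(cfg.years, 0)
            for pid, s in s_map.items():
                onset = incident_ckd_onset(s, band, t)
                if onset is not None:
                    y = int(str(onset)[:4])
                    if y in counts:
                        counts[y] += 1
            for year in cfg.years:
                inc_rows.append(
                    {"equation": eqn, "band": band, "year": year, "incident": counts[year]}
                )
    incident_by_equation = pd.DataFrame(inc_rows)

    ref_day = year_end_day(cfg.end_year)
    impact_patients = patients[["patient_id", "sex", "ethnicity"]].copy()
    impact_patients["age"] = (ref_day - _day_ints(patients["dob"])) / DAYS_PER_YEAR
    s_from = egfr_series_map(labs, patients, cfg.impact_from, use_ethnicity=cfg.use_ethnicity)
    s_to = egfr_series_map(labs, patients, cfg.impact_to, use_ethnicity=cfg.use_ethnicity)
    reclass = {
        band: reclassification_summary(
            s_from, s_to, impact_patients,
            eq_from=cfg.impact_from, eq_to=cfg.impact_to,
            band=band, mode=cfg.impact_mode, thresholds=t,
        )
        for band in ("g3_5", "g4_5")
    }

    return PipelineResult(
        prevalence=pd.DataFrame(prevalence_rows),
        testing=pd.DataFrame(testing_rows),
        testing_strata=strata,
        testing_tests=tests,
        assessments=assessments,
        category_counts=category_counts,
        kfre_by_ethnicity=kfre_by_ethnicity,
        incident_by_equation=incident_by_equation,
        reclassification=reclass,
    )


def write_report(result: PipelineResult, outdir, config: PipelineConfig | None = None) -> None:
    """Write the report bundle as CSV/JSON plus a frozen config for provenance."""
    from .io import write_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_table(result.prevalence, outdir / "prevalence_by_year.csv")
    write_table(result.testing, outdir / "testing_by_year.csv")
    write_table(result.testing_strata, outdir / "testing_stratified.csv")
    write_table(result.assessments, outdir / "assessments.csv")
    write_table(result.category_counts, outdir / "referral_categories_by_year.csv")
    write_table(result.kfre_by_ethnicity, outdir / "kfre_by_ethnicity.csv")
    write_table(result.incident_by_equation, outdir / "incident_by_equation.csv")
    reclass = {band: s.as_dict() for band, s in result.reclassification.items()}
    (outdir / "reclassification.json").write_text(
        json.dumps({"summaries": reclass, "testing_tests": result.testing_tests},
                   indent=2, sort_keys=True, default=float)
        + "\n"
    )
    for band, s in result.reclassification.items():
        write_table(s.strata, outdir / f"reclassification_strata_{band}.csv")
    if config is not None:
        (outdir / "config_frozen.yaml").write_text(
            yaml.safe_dump(config.model_dump(), sort_keys=True)
        )
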