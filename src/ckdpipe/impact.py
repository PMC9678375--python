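"""Reclassification when laboratories switch eGFR equations.

For each patient the same dated creatinine values are scored independently
under two equations; band membership (G3–5: eGFR <60, G4–5: eGFR <30) is
established either from the single baseline measurement (``single_measure``,
the research-cohort style where only one value exists) or from the confirmed
two-value rule with onset recomputed per equation (``confirmed``).  The
summary reports counts under each equation, the fold change, who crossed the
boundary in each direction, the per-patient eGFR shift among from-band
members (median with interquartile interval), and strata by sex, age band
and ethnicity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .monitoring import age_band
from .phenotyping import EgfrSeries, GuidelineThresholds, incident_ckd_onset

__all__ = ["ReclassificationSummary", "band_members", "reclassification_summary"]

BANDS = ("g3_5", "g4_5")
MODES = ("single_measure", "confirmed")


@dataclass
class ReclassificationSummary:
    eq_from: str
    eq_to: str
    band: str
    mode: str
    n_from: int
    n_to: int
    gained: int
    lost: int
    persisting: int
    fold_change: float
    direction: str  # "reduction" | "increase" | "unchanged"
    delta_egfr_median: float | None
    delta_egfr_iqi: tuple[float, float] | None
    median_age_lost: float | None
    median_age_persisting: float | None
    strata: pd.DataFrame = field(repr=False, default=None)

    def as_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "strata"}
        return d


def _band_threshold(band: str, thresholds: GuidelineThresholds) -> float:
    if band == "g3_5":
        return thresholds.g3_high
    if band == "g4_5":
        return thresholds.g3_low
    raise ValueError(f"band must be one of {BANDS}, got {band!r}")


def band_members(
    series: EgfrSeries, band: str, mode: str, thresholds: GuidelineThresholds
) -> bool:
    """Whether one patient's series places them in the CKD band.

    ``single_measure`` classifies on the baseline (earliest) value alone;
    ``confirmed`` requires a sustained crossing confirmed ≥3 months later,
    recomputed from scratch under the series' own equation.
    """
    if len(series) == 0:
        return False
    if mode == "single_measure":
        return bool(series.values[0] < _band_threshold(band, thresholds))
    if mode == "confirmed":
        return incident_ckd_onset(series, band, thresholds) is not None
    raise ValueError(f"mode must be one of {MODES}, got {mode!r}")


def reclassification_summary(
    series_from: dict[str, EgfrSeries],
    series_to: dict[str, EgfrSeries],
    patients: pd.DataFrame,
    *,
    eq_from: str,
    eq_to: str,
    band: str = "g3_5",
    mode: str = "confirmed",
    thresholds: GuidelineThresholds | None = None,
) -> ReclassificationSummary:
    """Summarise band reclassification between two per-equation series sets.

    ``series_from``/``series_to`` map patient_id → :class:`EgfrSeries` built
    from the *same* creatinine values under each equation.  ``patients``
    carries ``patient_id``, ``sex``, ``ethnicity`` and ``age`` (years, at a
    common reference date) for stratification.  Conservation holds exactly:
    gained − lost = n_to − n_from.
    """
    t = thresholds or GuidelineThresholds()
    pids = sorted(set(series_from) & set(series_to))
    member_from = np.array([band_members(series_from[p], band, mode, t) for p in pids])
    member_to = np.array([band_members(series_to[p], band, mode, t) for p in pids])
    n_from = int(member_from.sum())
    n_to = int(member_to.sum())
    gained = int((member_to & ~member_from).sum())
    lost = int((member_from & ~member_to).sum())
    persisting = int((member_from & member_to).sum())

    if n_from == n_to:
        fold, direction = 1.0 if n_from else float("nan"), "unchanged"
    elif n_to < n_from:
        fold = n_from / n_to if n_to else float("inf")
        direction = "reduction"
    else:
        fold = n_to / n_from if n_from else float("inf")
        direction = "increase"

    deltas = []
    for p, is_from in zip(pids, member_from):
        if not is_from:
            continue
        deltas.append(float(np.median(series_to[p].values - series_from[p].values)))
    deltas = np.asarray(deltas)
    if len(deltas):
        delta_median = float(np.median(deltas))
        delta_iqi = tuple(np.percentile(deltas, [25, 75]).tolist())
    else:
        delta_median, delta_iqi = None, None

    info = patients.set_index("patient_id").loc[pids]
    status = np.where(
        member_from & member_to,
        "persisting",
        np.where(member_from, "lost", np.where(member_to, "gained", "outside")),
    )
    ages = info["age"].to_numpy(dtype=float)
    med_lost = float(np.median(ages[status == "lost"])) if lost else None
    med_persist = float(np.median(ages[status == "persisting"])) if persisting else None

    strat = pd.DataFrame(
        {
            "patient_id": pids,
            "status": status,
            "sex": info["sex"].to_numpy(),
            "ethnicity": info["ethnicity"].to_numpy(),
            "age_band": age_band(ages),
        }
    )
    rows = []
    for factor in ("sex", "age_band", "ethnicity"):
        for stratum, grp in strat.groupby(factor, sort=True):
            counts = grp["status"].value_counts()
            rows.append(
                {
                    "factor": factor,
                    "stratum": str(stratum),
                    "n_from": int(counts.get("persisting", 0) + counts.get("lost", 0)),
                    "n_to": int(counts.get("persisting", 0) + counts.get("gained", 0)),
                    "gained": int(counts.get("gained", 0)),
                    "lost": int(counts.get("lost", 0)),
                    "persisting": int(counts.get("persisting", 0)),
                }
            )
    return ReclassificationSummary(
        eq_from=eq_from,
        eq_to=eq_to,
        band=band,
        mode=mode,
        n_from=n_from,
        n_to=n_to,
        gained=gained,
        lost=lost,
        persisting=persisting,
        fold_change=fold,
        direction=direction,
        delta_egfr_median=delta_median,
        delta_egfr_iqi=delta_iqi,
        median_age_lost=med_lost,
        median_age_persisting=med_persist,
        strata=pd.DataFrame(rows),
    )
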