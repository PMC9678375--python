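"""Independent reference implementations used only as test oracles.

These are deliberately naive, scalar, literal transcriptions of the
published closed forms and of the temporal rules — written separately from
the package so that agreement is meaningful.  The brute-force temporal
rules check every pair/window combination literally instead of streaming.
"""

from __future__ import annotations

import math

# --- closed-form equations (scalar, creatinine in mg/dL) -------------------


def egfr_mdrd(scr_mgdl: float, age: float, female: bool, black: bool = False) -> float:
    out = 175.0 * scr_mgdl**-1.154 * age**-0.203
    if female:
        out *= 0.742
    if black:
        out *= 1.212
    return out


def egfr_ckdepi_2009(scr_mgdl: float, age: float, female: bool, black: bool = False) -> float:
    kappa = 0.7 if female else 0.9
    alpha = -0.329 if female else -0.411
    r = scr_mgdl / kappa
    out = 141.0 * min(r, 1.0) ** alpha * max(r, 1.0) ** -1.209 * 0.993**age
    if female:
        out *= 1.018
    if black:
        out *= 1.159
    return out


def egfr_ckdepi_2021(scr_mgdl: float, age: float, female: bool) -> float:
    kappa = 0.7 if female else 0.9
    alpha = -0.241 if female else -0.302
    r = scr_mgdl / kappa
    out = 142.0 * min(r, 1.0) ** alpha * max(r, 1.0) ** -1.2 * 0.9938**age
    if female:
        out *= 1.012
    return out


S0_5YR = {"north_american": 0.8996, "non_north_american": 0.9365}


def kfre_5yr(age: float, male: bool, egfr: float, acr_mg_g: float, calibration: str) -> float:
    lp = (
        -0.2201 * (age / 10.0 - 7.036)
        + 0.2467 * ((1.0 if male else 0.0) - 0.5642)
        - 0.5567 * (egfr / 5.0 - 7.222)
        + 0.4510 * (math.log(acr_mg_g) - 5.137)
    )
    return 1.0 - S0_5YR[calibration] ** math.exp(lp)


# --- brute-force temporal rules --------------------------------------------


def sustained_below_brute(days, vals, threshold: float, sustain: int = 91):
    """Earliest start index of a confirmed sustained crossing, literally."""
    n = len(days)
    hits = []
    for i in range(n):
        if not vals[i] < threshold:
            continue
        for j in range(i + 1, n):
            if (
                vals[j] < threshold
                and days[j] - days[i] >= sustain
                and all(vals[k] <= threshold for k in range(i + 1, j))
            ):
                hits.append(i)
                break
    return min(hits) if hits else None


def accel_decline_brute(days, vals, rel=0.25, abs_=15.0, window=365, sustain=91):
    """Every confirmed accelerated-decline index day, literally enumerated."""
    n = len(days)
    out = []
    for j in range(n):
        confirmed = False
        for i in range(n):
            dt = days[j] - days[i]
            if not 0 < dt <= window:
                continue
            level = max(vals[i] * (1.0 - rel), vals[i] - abs_)
            if vals[j] > level:
                continue
            for k in range(j + 1, n):
                if (
                    days[k] - days[j] >= sustain
                    and vals[k] <= level
                    and all(vals[m] <= level for m in range(j + 1, k))
                ):
                    confirmed = True
                    break
            if confirmed:
                break
        if confirmed:
            out.append(days[j])
    return out
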