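"""Creatinine-based eGFR equations, their inversion, and the 4-variable 5-year KFRE.

Three estimating equations for glomerular filtration rate are provided:

* ``mdrd`` — the 4-variable IDMS-traceable MDRD study equation,
  ``175 · Scr^-1.154 · age^-0.203 · 0.742[female] · 1.212[Black]``;
* ``ckdepi2009`` — the CKD-EPI 2009 two-branch equation with sex-specific
  knot ``κ`` and exponent ``α``, optional Black-ethnicity coefficient;
* ``ckdepi2021`` — the 2021 race-free refit, which by construction has no
  ethnicity term.

Serum creatinine is handled in µmol/L (UK laboratory reporting) and converted
to mg/dL only at the equation boundary; urine albumin-to-creatinine ratio
(uACR) is handled in mg/mmol and converted to mg/g only inside the KFRE.

The KFRE is the published 4-variable (age, sex, eGFR, uACR) Cox-type model
``risk = 1 − S0^exp(Σ βᵢ(xᵢ − x̄ᵢ))`` with ACR entered as ln(mg/g).  Two
baseline survivals are shipped: the North-American development calibration
and the non-North-American recalibration (the default, appropriate for UK
cohorts).  All numeric coefficients live in a checksummed JSON data file so
equation updates are auditable, never as code literals.
"""

from __future__ import annotations

import functools
import hashlib
import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = [
    "UMOL_PER_MGDL",
    "MG_G_PER_MG_MMOL",
    "EQUATIONS",
    "KfreParameters",
    "coefficients",
    "egfr_mdrd",
    "egfr_ckdepi_2009",
    "egfr_ckdepi_2021",
    "compute_egfr",
    "invert_egfr_to_creatinine",
    "kfre_5yr",
    "acr_mg_mmol_to_mg_g",
]

#: µmol/L of creatinine per mg/dL.
UMOL_PER_MGDL = 88.4
#: mg/g of ACR per mg/mmol.
MG_G_PER_MG_MMOL = 8.84

EQUATIONS = ("mdrd", "ckdepi2009", "ckdepi2021")
SEXES = ("female", "male")
ETHNICITIES = ("white", "black", "asian", "mixed", "other", "unknown")

_DATA_FILE = "equation_coefficients.json"


def _canonical(payload: dict) -> str:
    return json.dumps(payload, sort_keys=True, separators=(",", ":"))


@functools.lru_cache(maxsize=1)
def coefficients() -> dict:
    """Load the versioned coefficient file, verifying its SHA-256 checksum."""
    text = resources.files("ckdpipe").joinpath(f"data/{_DATA_FILE}").read_text()
    doc = json.loads(text)
    digest = hashlib.sha256(_canonical(doc["coefficients"]).encode()).hexdigest()
    if digest != doc["sha256"]:
        raise RuntimeError(
            f"equation coefficient file failed its checksum "
            f"(expected {doc['sha256']}, got {digest}); refusing to score"
        )
    return doc["coefficients"]


def _female_mask(sex) -> np.ndarray:
    sex_arr = np.asarray(sex)
    if sex_arr.ndim == 0:
        sex_arr = sex_arr[None]
    bad = ~np.isin(sex_arr, SEXES)
    if bad.any():
        raise ValueError(f"sex must be one of {SEXES}, got {sex_arr[bad][:5]!r}")
    return sex_arr == "female"


def _check_positive_creatinine(scr_umol_l) -> np.ndarray:
    scr = np.asarray(scr_umol_l, dtype=float)
    if not np.all(np.isfinite(scr)) or np.any(scr <= 0):
        raise ValueError(
            "serum creatinine must be positive and finite, in µmol/L "
            "(1 mg/dL = 88.4 µmol/L — values below ~20 usually mean mg/dL "
            "was supplied in a µmol/L column)"
        )
    return scr


def _check_adult_age(age_years) -> np.ndarray:
    age = np.asarray(age_years, dtype=float)
    if not np.all(np.isfinite(age)) or np.any(age < 18):
        raise ValueError("age must be finite and ≥ 18 years (adult guideline scope)")
    return age


def _maybe_scalar(x: np.ndarray, *inputs):
    if all(np.ndim(v) == 0 for v in inputs):
        return float(x.reshape(-1)[0])
    return x


def egfr_mdrd(creatinine_umol_l, age_years, sex, *, black=False):
    """4-variable IDMS-traceable MDRD eGFR in mL/min/1.73 m².

    ``black`` applies the 1.212 ethnicity coefficient; pass ``False`` (the
    default) when ethnicity is unknown or the coefficient is not in use.
    Accepts scalars or arrays and broadcasts.
    """
    c = coefficients()["mdrd"]
    scr = _check_positive_creatinine(creatinine_umol_l) / UMOL_PER_MGDL
    age = _check_adult_age(age_years)
    female = _female_mask(sex)
    out = (
        c["scale"]
        * scr**c["scr_exp"]
        * age**c["age_exp"]
        * np.where(female, c["female"], 1.0)
        * np.where(np.asarray(black), c["black"], 1.0)
    )
    return _maybe_scalar(np.asarray(out, dtype=float), creatinine_umol_l, age_years)


def _ckdepi(scr_umol_l, age_years, sex, table, *, black=False):
    scr = _check_positive_creatinine(scr_umol_l) / UMOL_PER_MGDL
    age = _check_adult_age(age_years)
    female = _female_mask(sex)
    kappa = np.where(female, table["kappa"]["female"], table["kappa"]["male"])
    alpha = np.where(female, table["alpha"]["female"], table["alpha"]["male"])
    ratio = scr / kappa
    out = (
        table["scale"]
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** table["scr_exp"]
        * table["age_base"] ** age
        * np.where(female, table["female"], 1.0)
    )
    if "black" in table:
        out = out * np.where(np.asarray(black), table["black"], 1.0)
    return np.asarray(out, dtype=float)


def egfr_ckdepi_2009(creatinine_umol_l, age_years, sex, *, black=False):
    """CKD-EPI 2009 creatinine eGFR in mL/min/1.73 m² (optional Black coefficient)."""
    out = _ckdepi(creatinine_umol_l, age_years, sex, coefficients()["ckdepi2009"], black=black)
    return _maybe_scalar(out, creatinine_umol_l, age_years)


def egfr_ckdepi_2021(creatinine_umol_l, age_years, sex):
    """CKD-EPI 2021 race-free creatinine eGFR in mL/min/1.73 m².

    The refit has no ethnicity term: output is identical for any two
    ethnicities at identical creatinine/age/sex.
    """
    out = _ckdepi(creatinine_umol_l, age_years, sex, coefficients()["ckdepi2021"])
    return _maybe_scalar(out, creatinine_umol_l, age_years)


def compute_egfr(creatinine_umol_l, age_years, sex, equation, *, black=False, use_ethnicity=False):
    """Dispatch to a named equation.

    The ethnicity coefficient is applied only when ``use_ethnicity`` is true
    AND the equation has one (mdrd, ckdepi2009); ckdepi2021 ignores it by
    construction.
    """
    eth = np.asarray(black) & bool(use_ethnicity)
    if equation == "mdrd":
        return egfr_mdrd(creatinine_umol_l, age_years, sex, black=eth)
    if equation == "ckdepi2009":
        return egfr_ckdepi_2009(creatinine_umol_l, age_years, sex, black=eth)
    if equation == "ckdepi2021":
        return egfr_ckdepi_2021(creatinine_umol_l, age_years, sex)
    raise ValueError(f"unknown eGFR equation {equation!r}; expected one of {EQUATIONS}")


def invert_egfr_to_creatinine(egfr, age_years, sex, equation="mdrd", *, black=False, use_ethnicity=False):
    """Creatinine (µmol/L) that reproduces ``egfr`` under the named equation.

    The forward maps are strict power laws in creatinine (two-branch for the
    CKD-EPI forms), so the inverse is closed-form and round-trips to machine
    precision.  Valid for target eGFR in (1, 200).
    """
    g = np.asarray(egfr, dtype=float)
    if not np.all(np.isfinite(g)) or np.any(g <= 1.0) or np.any(g >= 200.0):
        raise ValueError("target eGFR must lie strictly inside (1, 200) mL/min/1.73 m²")
    age = _check_adult_age(age_years)
    female = _female_mask(sex)
    eth = np.asarray(black) & bool(use_ethnicity) if equation != "ckdepi2021" else False
    co = coefficients()
    if equation == "mdrd":
        c = co["mdrd"]
        const = (
            c["scale"]
            * age ** c["age_exp"]
            * np.where(female, c["female"], 1.0)
            * np.where(np.asarray(eth), c["black"], 1.0)
        )
        scr_mgdl = (g / const) ** (1.0 / c["scr_exp"])
    elif equation in ("ckdepi2009", "ckdepi2021"):
        c = co[equation]
        const = c["scale"] * c["age_base"] ** age * np.where(female, c["female"], 1.0)
        if "black" in c:
            const = const * np.where(np.asarray(eth), c["black"], 1.0)
        kappa = np.where(female, c["kappa"]["female"], c["kappa"]["male"])
        alpha = np.where(female, c["alpha"]["female"], c["alpha"]["male"])
        ratio = g / const  # = (scr/κ)^exponent on the relevant branch
        # g ≤ const ⇔ scr ≥ κ (low branch, exponent scr_exp); else high branch (α).
        scr_mgdl = kappa * np.where(
            ratio <= 1.0, ratio ** (1.0 / c["scr_exp"]), ratio ** (1.0 / alpha)
        )
    else:
        raise ValueError(f"unknown eGFR equation {equation!r}; expected one of {EQUATIONS}")
    out = np.asarray(scr_mgdl * UMOL_PER_MGDL, dtype=float)
    return _maybe_scalar(out, egfr, age_years)


def acr_mg_mmol_to_mg_g(acr_mg_mmol):
    """Convert uACR from UK units (mg/mmol) to mg/g (factor 8.84)."""
    acr = np.asarray(acr_mg_mmol, dtype=float)
    if np.any(acr < 0):
        raise ValueError("uACR cannot be negative")
    return _maybe_scalar(acr * MG_G_PER_MG_MMOL, acr_mg_mmol)


@dataclass(frozen=True)
class KfreParameters:
    """Coefficients of the 4-variable 5-year KFRE.

    Covariates enter centred: age/10, male indicator, eGFR/5 and ln(ACR mg/g).
    ``baseline_survival_5yr`` is S0 at the centring point.
    """

    beta_age_per_10yr: float
    beta_male: float
    beta_egfr_per_5: float
    beta_log_acr: float
    center_age_per_10yr: float
    center_male: float
    center_egfr_per_5: float
    center_log_acr: float
    baseline_survival_5yr: float
    calibration: str = "non_north_american"

    def __post_init__(self):
        if not 0.0 < self.baseline_survival_5yr < 1.0:
            raise ValueError("baseline_survival_5yr must lie in (0, 1)")
        signs_ok = (
            self.beta_age_per_10yr < 0
            and self.beta_male > 0
            and self.beta_egfr_per_5 < 0
            and self.beta_log_acr > 0
        )
        if not signs_ok:
            raise ValueError(
                "KFRE coefficient signs violated (age −, male +, eGFR −, lnACR +)"
            )

    @classmethod
    def from_calibration(cls, calibration: str = "non_north_american") -> "KfreParameters":
        k = coefficients()["kfre4v"]
        if calibration not in k["baseline_survival_5yr"]:
            raise ValueError(
                f"unknown KFRE calibration {calibration!r}; "
                f"expected one of {tuple(k['baseline_survival_5yr'])}"
            )
        return cls(
            beta_age_per_10yr=k["beta"]["age_per_10yr"],
            beta_male=k["beta"]["male"],
            beta_egfr_per_5=k["beta"]["egfr_per_5"],
            beta_log_acr=k["beta"]["log_acr_mg_g"],
            center_age_per_10yr=k["center"]["age_per_10yr"],
            center_male=k["center"]["male"],
            center_egfr_per_5=k["center"]["egfr_per_5"],
            center_log_acr=k["center"]["log_acr_mg_g"],
            baseline_survival_5yr=k["baseline_survival_5yr"][calibration],
            calibration=calibration,
        )


def kfre_5yr(age_years, sex, egfr, acr_mg_mmol=None, *, acr_mg_g=None, params: KfreParameters | None = None):
    """5-year kidney-failure risk in (0, 1) from the 4-variable KFRE.

    Exactly one of ``acr_mg_mmol`` / ``acr_mg_g`` must be given and must be
    strictly positive: the model is undefined at ACR 0, and a patient with no
    ACR measurement has *no computable risk* — callers must represent that
    state explicitly (see :func:`ckdpipe.referral.max_kfre_in_year`) rather
    than pass a placeholder.
    """
    if (acr_mg_mmol is None) == (acr_mg_g is None):
        raise ValueError("give exactly one of acr_mg_mmol or acr_mg_g")
    if params is None:
        params = KfreParameters.from_calibration()
    acr = np.asarray(acr_mg_g if acr_mg_g is not None else acr_mg_mmol, dtype=float)
    if acr_mg_g is None:
        acr = acr * MG_G_PER_MG_MMOL
    if np.any(~np.isfinite(acr)) or np.any(acr <= 0):
        raise ValueError(
            "KFRE is undefined at ACR ≤ 0 or missing; treat such patients as "
            "'risk not computable' upstream"
        )
    age = _check_adult_age(age_years)
    g = np.asarray(egfr, dtype=float)
    if np.any(~np.isfinite(g)) or np.any(g <= 0):
        raise ValueError("eGFR must be positive and finite")
    male = ~_female_mask(sex)
    lp = (
        params.beta_age_per_10yr * (age / 10.0 - params.center_age_per_10yr)
        + params.beta_male * (male.astype(float) - params.center_male)
        + params.beta_egfr_per_5 * (g / 5.0 - params.center_egfr_per_5)
        + params.beta_log_acr * (np.log(acr) - params.center_log_acr)
    )
    risk = 1.0 - params.baseline_survival_5yr ** np.exp(lp)
    return _maybe_scalar(np.asarray(risk, dtype=float), age_years, egfr, acr)
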