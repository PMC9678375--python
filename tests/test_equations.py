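"""Equation-layer tests: frozen oracle points, monotonicities, inversion."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from ckdpipe import equations as eq
from _oracles import egfr_ckdepi_2009, egfr_ckdepi_2021, egfr_mdrd, kfre_5yr

# Frozen reference points, hand-evaluated from the published closed forms.
FROZEN = [
    # (equation, scr µmol/L, age, sex, black, expected)
    ("mdrd", 88.4, 60, "male", False, 76.2208),
    ("mdrd", 88.4, 60, "female", False, 56.5558),  # = 76.2208 × 0.742
    ("ckdepi2009", 176.8, 70, "male", False, 32.8398),
    ("ckdepi2009", 61.88, 50, "female", False, 101.0251),  # Scr = κ: 141·1.018·0.993^50
    ("ckdepi2021", 61.88, 50, "female", False, 105.2976),  # 142·1.012·0.9938^50
    ("ckdepi2021", 79.56, 40, "male", False, 110.7256),  # Scr = κ: 142·0.9938^40
]


@pytest.mark.parametrize("equation,scr,age,sex,black,expected", FROZEN)
def test_egfr_frozen_reference_points(equation, scr, age, sex, black, expected):
    got = eq.compute_egfr(scr, age, sex, equation, black=black, use_ethnicity=black)
    assert got == pytest.approx(expected, abs=5e-4)


def test_egfr_agrees_with_independent_oracle_grid():
    """4-significant-figure agreement with literal scalar transcriptions."""
    rng = np.random.default_rng(2024)
    for _ in range(200):
        scr = rng.uniform(40, 800)
        age = rng.uniform(18, 95)
        female = bool(rng.integers(2))
        black = bool(rng.integers(2))
        sex = "female" if female else "male"
        cases = [
            (eq.egfr_mdrd(scr, age, sex, black=black), egfr_mdrd(scr / 88.4, age, female, black)),
            (
                eq.egfr_ckdepi_2009(scr, age, sex, black=black),
                egfr_ckdepi_2009(scr / 88.4, age, female, black),
            ),
            (eq.egfr_ckdepi_2021(scr, age, sex), egfr_ckdepi_2021(scr / 88.4, age, female)),
        ]
        for got, want in cases:
            assert got == pytest.approx(want, rel=5e-4)


def test_mdrd_power_law_in_creatinine():
    a = eq.egfr_mdrd(100.0, 55, "male")
    b = eq.egfr_mdrd(200.0, 55, "male")
    assert b / a == pytest.approx(2.0**-1.154, rel=1e-12)


def test_ethnicity_coefficient_is_exactly_multiplicative():
    base = eq.egfr_ckdepi_2009(150.0, 60, "female", black=False)
    with_eth = eq.egfr_ckdepi_2009(150.0, 60, "female", black=True)
    assert with_eth / base == pytest.approx(1.159, rel=1e-12)
    # the 2021 refit has no ethnicity term at all
    assert eq.compute_egfr(150.0, 60, "female", "ckdepi2021", black=True, use_ethnicity=True) == (
        eq.compute_egfr(150.0, 60, "female", "ckdepi2021", black=False)
    )


@settings(deadline=None, max_examples=150)
@given(
    scr=st.floats(21, 1499),
    age=st.floats(18, 100),
    female=st.booleans(),
    equation=st.sampled_from(eq.EQUATIONS),
)
def test_egfr_positive_finite_and_decreasing_in_creatinine(scr, age, female, equation):
    sex = "female" if female else "male"
    lo = eq.compute_egfr(scr, age, sex, equation)
    hi = eq.compute_egfr(scr * 1.05, age, sex, equation)
    assert np.isfinite(lo) and lo > 0
    assert hi < lo


def test_female_below_male_for_mdrd_grid():
    scr = np.linspace(50, 1200, 40)
    for age in (18, 40, 75, 100):
        f = eq.egfr_mdrd(scr, age, "female")
        m = eq.egfr_mdrd(scr, age, "male")
        assert np.all(f < m)


def test_black_2009_with_coefficient_exceeds_2021_everywhere():
    """Direction behind the reported prevalence rise among Black patients."""
    scr = np.linspace(40, 1200, 60)
    for age in (20, 45, 70, 95):
        for sex in ("female", "male"):
            e2009 = eq.egfr_ckdepi_2009(scr, age, sex, black=True)
            e2021 = eq.egfr_ckdepi_2021(scr, age, sex)
            assert np.all(e2021 < e2009)


def test_unit_hinting_rejections():
    with pytest.raises(ValueError, match="mg/dL"):
        eq.egfr_mdrd(-1.0, 50, "male")
    with pytest.raises(ValueError, match="18"):
        eq.egfr_mdrd(90.0, 12, "male")
    with pytest.raises(ValueError, match="sex"):
        eq.egfr_mdrd(90.0, 50, "m")


# --- inversion -------------------------------------------------------------


def test_invert_frozen_example():
    assert eq.invert_egfr_to_creatinine(76.2208, 60, "male", "mdrd") == pytest.approx(
        88.4, abs=0.05
    )


def test_invert_round_trip_and_monotone():
    rng = np.random.default_rng(7)
    worst = 0.0
    for _ in range(1000):
        equation = eq.EQUATIONS[rng.integers(3)]
        age = rng.uniform(18, 95)
        sex = "female" if rng.integers(2) else "male"
        g = rng.uniform(2, 190)
        scr = eq.invert_egfr_to_creatinine(g, age, sex, equation)
        back = eq.compute_egfr(scr, age, sex, equation)
        worst = max(worst, abs(back - g) / g)
        higher = eq.invert_egfr_to_creatinine(min(g * 1.1, 195), age, sex, equation)
        assert higher < scr  # higher eGFR ⇒ strictly lower creatinine
    assert worst < 1e-9


def test_invert_matches_root_finding():
    """Cross-check the analytic inverse against a bracketing root-finder."""
    for equation in eq.EQUATIONS:
        for g in (20.0, 59.5, 95.0):
            scr = eq.invert_egfr_to_creatinine(g, 67, "female", equation)
            rooted = brentq(
                lambda s: eq.compute_egfr(s, 67, "female", equation) - g, 1.0, 5000.0
            )
            assert scr == pytest.approx(rooted, rel=1e-7)


def test_invert_rejects_out_of_range_targets():
    with pytest.raises(ValueError):
        eq.invert_egfr_to_creatinine(250.0, 50, "male", "mdrd")
    with pytest.raises(ValueError):
        eq.invert_egfr_to_creatinine(0.5, 50, "male", "mdrd")


# --- KFRE ------------------------------------------------------------------


def test_kfre_risk_at_centering_point_is_one_minus_baseline():
    """With every continuous covariate at its centring constant the linear
    predictor reduces to the male-indicator term (the indicator cannot sit at
    its fractional centring value), forcing risk = 1 − S0^exp(lp_male)."""
    for cal in ("north_american", "non_north_american"):
        p = eq.KfreParameters.from_calibration(cal)
        lp_male = p.beta_male * (1.0 - p.center_male)
        expected = 1.0 - p.baseline_survival_5yr ** np.exp(lp_male)
        got = eq.kfre_5yr(
            p.center_age_per_10yr * 10,
            "male",
            p.center_egfr_per_5 * 5,
            acr_mg_g=float(np.exp(p.center_log_acr)),
            params=p,
        )
        assert got == pytest.approx(expected, rel=1e-12)


def test_kfre_frozen_reference_point():
    """Age 60 male, eGFR 25, ACR 100 mg/g — hand-evaluated linear predictor."""
    p_na = eq.KfreParameters.from_calibration("north_american")
    assert eq.kfre_5yr(60, "male", 25, acr_mg_g=100, params=p_na) == pytest.approx(
        0.33043, abs=5e-5
    )
    assert eq.kfre_5yr(60, "male", 25, acr_mg_g=100) == pytest.approx(0.22020, abs=5e-5)


def test_kfre_agrees_with_independent_oracle():
    rng = np.random.default_rng(55)
    for _ in range(100):
        age = rng.uniform(18, 95)
        male = bool(rng.integers(2))
        g = rng.uniform(5, 90)
        acr = rng.uniform(1, 300) * 8.84
        cal = ("north_american", "non_north_american")[rng.integers(2)]
        got = eq.kfre_5yr(
            age, "male" if male else "female", g, acr_mg_g=acr,
            params=eq.KfreParameters.from_calibration(cal),
        )
        assert got == pytest.approx(kfre_5yr(age, male, g, acr, cal), rel=5e-4)


def test_kfre_log_linear_in_acr():
    p = eq.KfreParameters.from_calibration()
    r1 = eq.kfre_5yr(70, "female", 40, acr_mg_g=10, params=p)
    r2 = eq.kfre_5yr(70, "female", 40, acr_mg_g=100, params=p)
    lp1 = np.log(np.log(1 - r1) / np.log(p.baseline_survival_5yr))
    lp2 = np.log(np.log(1 - r2) / np.log(p.baseline_survival_5yr))
    assert lp2 - lp1 == pytest.approx(p.beta_log_acr * np.log(10), rel=1e-9)


@settings(deadline=None, max_examples=200)
@given(
    age=st.floats(18, 100),
    male=st.booleans(),
    g=st.floats(2, 120),
    acr=st.floats(0.2, 300),
)
def test_kfre_bounds_and_monotonicities(age, male, g, acr):
    sex = "male" if male else "female"
    r = eq.kfre_5yr(age, sex, g, acr_mg_mmol=acr)
    assert 0.0 < r < 1.0
    assert eq.kfre_5yr(age, sex, g, acr_mg_mmol=acr * 1.5) > r  # ↑ ACR ⇒ ↑ risk
    assert eq.kfre_5yr(age, sex, g * 1.2, acr_mg_mmol=acr) < r  # ↑ eGFR ⇒ ↓ risk
    if age <= 95:
        assert eq.kfre_5yr(age + 5, sex, g, acr_mg_mmol=acr) < r  # ↑ age ⇒ ↓ 5-yr risk
    assert eq.kfre_5yr(age, "male", g, acr_mg_mmol=acr) > eq.kfre_5yr(
        age, "female", g, acr_mg_mmol=acr
    )


def test_kfre_undefined_at_zero_acr():
    with pytest.raises(ValueError, match="not computable"):
        eq.kfre_5yr(60, "male", 30, acr_mg_mmol=0.0)


def test_acr_unit_conversion():
    assert eq.acr_mg_mmol_to_mg_g(70.0) == pytest.approx(618.8)
    assert eq.acr_mg_mmol_to_mg_g(0.0) == 0.0
    assert eq.acr_mg_mmol_to_mg_g(3.0) == pytest.approx(26.52)
    with pytest.raises(ValueError):
        eq.acr_mg_mmol_to_mg_g(-1.0)


def test_coefficient_file_checksum_guard():
    doc = eq.coefficients()
    assert set(doc) == {"mdrd", "ckdepi2009", "ckdepi2021", "kfre4v"}
    # KFRE coefficient sign contract is enforced at construction
    with pytest.raises(ValueError, match="sign"):
        eq.KfreParameters(
            beta_age_per_10yr=0.2, beta_male=0.2, beta_egfr_per_5=-0.5, beta_log_acr=0.45,
            center_age_per_10yr=7.0, center_male=0.56, center_egfr_per_5=7.2,
            center_log_acr=5.1, baseline_survival_5yr=0.9,
        )
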