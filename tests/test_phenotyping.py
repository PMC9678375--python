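"""Temporal-rule tests: worked examples, brute-force equivalence, censoring."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from ckdpipe.phenotyping import (
    EgfrSeries,
    GuidelineThresholds,
    accelerated_decline,
    accelerated_decline_index_days,
    first_sustained_below,
    incident_ckd_onset,
    prevalent_g3_in_year,
)
from conftest import day, series
from _oracles import accel_decline_brute, sustained_below_brute

VALUE_GRID = (25.0, 28.0, 31.0, 45.0, 59.0, 61.0)
GAP_GRID = (30, 91, 200)


def grid_series(length: int):
    """Every series of the given length over the value/gap grids."""
    for vals in itertools.product(VALUE_GRID, repeat=length):
        for gaps in itertools.product(GAP_GRID, repeat=length - 1):
            days = [0]
            for g in gaps:
                days.append(days[-1] + g)
            yield days, list(vals)


class TestFirstSustainedBelow:
    @pytest.mark.parametrize(
        "pairs,expect_day",
        [
            ([(0, 28), (100, 29)], 0),  # confirmed ≥91 days later, no rise above
            ([(0, 28), (50, 32), (120, 28)], None),  # rise above 30 breaks the run
            ([(0, 28)], None),  # confirmation duration unmet
            ([(0, 28), (50, 30), (120, 28)], 0),  # value == threshold is not "rising above"
            ([(0, 31), (100, 29), (200, 28)], 100),
        ],
    )
    def test_worked_examples(self, pairs, expect_day):
        days = [d for d, _ in pairs]
        vals = [v for _, v in pairs]
        idx = first_sustained_below(days, vals, 30.0, 91)
        got = None if idx is None else days[idx]
        assert got == expect_day

    def test_later_pair_can_still_qualify_after_a_break(self):
        days = [0, 50, 120, 250]
        vals = [28, 32, 28, 27]
        idx = first_sustained_below(days, vals, 30.0, 91)
        assert days[idx] == 120


class TestAcceleratedDecline:
    def test_thirty_percent_fall_confirmed(self, thresholds):
        flag, date = accelerated_decline(series([(0, 60), (200, 42), (300, 40)]), thresholds)
        assert flag and str(date) == str(np.datetime64(0, "D") + 200)

    def test_rebound_above_qualifying_level_blocks_confirmation(self, thresholds):
        flag, _ = accelerated_decline(series([(0, 60), (200, 42), (250, 55)]), thresholds)
        assert not flag

    def test_window_exceeded(self, thresholds):
        flag, _ = accelerated_decline(series([(0, 90), (400, 60)]), thresholds)
        assert not flag

    def test_absolute_fall_route(self, thresholds):
        # 90 → 74: 17.8% relative (fails ≥25%) but 16 absolute (meets ≥15)
        flag, _ = accelerated_decline(series([(0, 90), (180, 74), (300, 73)]), thresholds)
        assert flag


class TestBruteForceEquivalence:
    """Streaming rules agree with literal enumeration on the value/gap grids."""

    @pytest.mark.parametrize("length", [1, 2, 3])
    def test_exhaustive_short_series(self, length, thresholds):
        for days, vals in grid_series(length):
            assert first_sustained_below(days, vals, 30.0, 91) == sustained_below_brute(
                days, vals, 30.0, 91
            )
            assert (
                accelerated_decline_index_days(days, vals, thresholds)
                == accel_decline_brute(days, vals)
            )

    def test_random_longer_series(self, thresholds):
        rng = np.random.default_rng(321)
        for _ in range(1500):
            n = int(rng.integers(4, 9))
            vals = list(rng.choice(VALUE_GRID, size=n))
            days = np.concatenate([[0], np.cumsum(rng.choice(GAP_GRID, size=n - 1))]).tolist()
            assert first_sustained_below(days, vals, 30.0, 91) == sustained_below_brute(
                days, vals, 30.0, 91
            )
            assert (
                accelerated_decline_index_days(days, vals, thresholds)
                == accel_decline_brute(days, vals)
            )


class TestPrevalentG3:
    def test_qualifying_pair(self):
        assert prevalent_g3_in_year(series([("2015-03-01", 45), ("2015-08-01", 50)]), 2015)

    def test_gap_unmet(self):
        assert not prevalent_g3_in_year(series([("2015-03-01", 45), ("2015-04-01", 50)]), 2015)

    def test_resolution_by_later_normal_value(self):
        s = series([("2014-03-01", 45), ("2014-08-01", 50), ("2015-05-01", 65)])
        assert not prevalent_g3_in_year(s, 2015)
        assert prevalent_g3_in_year(s, 2014)  # only data through that year end count

    def test_requalification_with_new_pair_after_resolution(self):
        s = series(
            [("2014-03-01", 45), ("2014-08-01", 50), ("2015-02-01", 65),
             ("2015-04-01", 50), ("2015-09-01", 48)]
        )
        assert prevalent_g3_in_year(s, 2015)

    def test_prior_year_g4_crossing_excludes_from_g3(self):
        s = series(
            [("2014-02-01", 45), ("2014-06-01", 48), ("2014-09-01", 28),
             ("2015-01-15", 27), ("2015-07-01", 26)]
        )
        assert prevalent_g3_in_year(s, 2014)  # progressed in-year: still G3 that year
        assert not prevalent_g3_in_year(s, 2015)  # already G4–5 when the year began

    def test_in_year_progression_keeps_g3_membership(self):
        s = series(
            [("2014-03-01", 45), ("2014-08-01", 43), ("2015-05-01", 28), ("2015-09-01", 27)]
        )
        assert prevalent_g3_in_year(s, 2015)

    def test_boundary_value_60_neither_qualifies_nor_resolves(self):
        s = series([("2015-03-01", 45), ("2015-06-15", 60.0), ("2015-08-01", 50)])
        assert prevalent_g3_in_year(s, 2015)


class TestIncidentOnset:
    def test_two_value_rule(self):
        s = series([("2014-02-01", 55), ("2014-07-01", 52)])
        assert str(incident_ckd_onset(s, "g3_5")) == "2014-02-01"
        assert incident_ckd_onset(s, "g4_5") is None

    def test_all_normal_series(self):
        assert incident_ckd_onset(series([("2014-02-01", 70), ("2015-07-01", 65)]), "g3_5") is None

    def test_borderline_series_differs_by_equation(self):
        """A series confirmed under the lower-reporting equation only.

        Creatinine fixed so eGFR sits at 58–59 under MDRD but above 60 under
        the 2021 refit (constructed by inverting the MDRD form).
        """
        from ckdpipe.equations import egfr_ckdepi_2021, invert_egfr_to_creatinine

        scr = [invert_egfr_to_creatinine(g, 70, "female", "mdrd") for g in (58.0, 59.0)]
        e2021 = [egfr_ckdepi_2021(s, 70, "female") for s in scr]
        assert all(g > 60 for g in e2021)
        s_mdrd = series([("2016-01-10", 58.0), ("2016-06-10", 59.0)])
        s_2021 = series([("2016-01-10", e2021[0]), ("2016-06-10", e2021[1])])
        assert incident_ckd_onset(s_mdrd, "g3_5") is not None
        assert incident_ckd_onset(s_2021, "g3_5") is None


class TestSeriesContracts:
    def test_days_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            EgfrSeries("p", "mdrd", [5, 5], [50.0, 51.0])

    def test_truncation_never_creates_a_later_onset(self, thresholds):
        """Onsets can only be discovered, never un-discovered, by more data."""
        rng = np.random.default_rng(99)
        for _ in range(300):
            n = int(rng.integers(2, 10))
            days = np.cumsum(rng.integers(20, 200, size=n)).astype(int)
            vals = rng.uniform(20, 70, size=n)
            s = EgfrSeries("p", "mdrd", days, vals)
            full = incident_ckd_onset(s, "g3_5", thresholds)
            for cut in days:
                part = incident_ckd_onset(s.truncated(int(cut)), "g3_5", thresholds)
                if part is not None:
                    assert full is not None and full <= part

    def test_determinism_identical_inputs(self, thresholds):
        s = series([(0, 59), (100, 45), (300, 28), (400, 27)])
        a = accelerated_decline(s, thresholds)
        b = accelerated_decline(s, thresholds)
        assert a == b

    def test_thresholds_validation(self):
        with pytest.raises(ValueError):
            GuidelineThresholds(g3_low=70, g3_high=60)
        with pytest.raises(ValueError):
            GuidelineThresholds(decline_rel=1.5)
        with pytest.raises(ValueError):
            GuidelineThresholds(sustain_days=0)
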