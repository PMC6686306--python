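"""Immersion analysis: merging, bout mixture, classification, budgets, returns."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_immersion, random_alternating_series
from pelagis import activity as act
from pelagis.activity import (
    DegenerateFitError,
    StageCalendar,
    bec_from_params,
    classify_events,
    compute_daily_budgets,
    extract_return_date,
    fit_bout_model,
    merge_short_events,
    population_criterion,
)
from pelagis.geolocation import TwilightPair
from pelagis.simulate import BreedingRecord


class TestMergeShortEvents:
    def test_interior_absorption(self):
        s = make_immersion(["dry", "wet", "dry"], [30.0, 1.0, 30.0])
        m = merge_short_events(s)
        assert len(m) == 1
        assert m.states[0] == "dry"
        assert m.durations_s[0] == pytest.approx(61.0 * 60.0)

    def test_fixed_point_when_nothing_short(self):
        s = make_immersion(["wet", "dry", "wet"], [10.0, 20.0, 30.0])
        m = merge_short_events(s)
        assert np.array_equal(m.durations_s, s.durations_s)
        assert np.array_equal(m.states, s.states)

    def test_single_short_event_collapses_to_empty(self):
        s = make_immersion(["wet"], [0.5])
        assert len(merge_short_events(s)) == 0

    def test_edge_absorption_conserves_time(self):
        s = make_immersion(["wet", "dry", "wet", "dry"], [1.0, 30.0, 1.2, 40.0])
        m = merge_short_events(s)
        assert m.total_seconds == pytest.approx(s.total_seconds)
        assert (m.durations_s >= 90.0).all()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_conservation_and_alternation_property(self, seed):
        s = random_alternating_series(np.random.default_rng(seed), n_events=120)
        m = merge_short_events(s)
        assert m.total_seconds == pytest.approx(s.total_seconds, rel=1e-12)
        if len(m) > 1:
            assert (m.states[1:] != m.states[:-1]).all()
            assert (m.durations_s >= 90.0).all() or len(m) == 1


class TestBoutMixture:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(2)
        n, p, lf, ls = 10_000, 0.8, 1.0, 0.01
        d = np.where(rng.random(n) < p, rng.exponential(1 / lf, n), rng.exponential(1 / ls, n))
        res = fit_bout_model(d, seed=1)
        assert res.converged
        assert res.bec == pytest.approx(bec_from_params(p, lf, ls), rel=0.10)
        assert res.lambda_fast > res.lambda_slow

    def test_bec_closed_form(self):
        # ln(p lf / ((1-p) ls)) / (lf - ls) = ln(400)/0.99
        assert bec_from_params(0.8, 1.0, 0.01) == pytest.approx(np.log(400.0) / 0.99)
        with pytest.raises(ValueError):
            bec_from_params(0.5, 0.01, 1.0)

    def test_likelihood_matches_grid_oracle(self):
        # independent dense-grid evaluation of the mixture likelihood
        rng = np.random.default_rng(3)
        d = np.concatenate([rng.exponential(1.0, 400), rng.exponential(100.0, 100)])
        res = fit_bout_model(d, seed=2)
        best_oracle = -np.inf
        for p in np.linspace(0.05, 0.95, 19):
            for lf in np.logspace(-1, 1, 21):
                for ls in np.logspace(-3, -1, 21):
                    ll = np.sum(np.log(p * lf * np.exp(-lf * d) + (1 - p) * ls * np.exp(-ls * d)))
                    best_oracle = max(best_oracle, ll)
        assert res.loglike >= best_oracle - 1e-6  # MLE at least as good as grid search

    def test_single_process_is_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_bout_model(np.full(500, 7.0), seed=0)

    def test_minimum_event_floor(self):
        with pytest.raises(ValueError):
            fit_bout_model(np.random.default_rng(0).exponential(1, 50))

    def test_summary_mentions_criterion(self):
        rng = np.random.default_rng(4)
        d = np.where(rng.random(2000) < 0.8, rng.exponential(1, 2000), rng.exponential(100, 2000))
        res = fit_bout_model(d, seed=3)
        assert "bout criterion" in res.summary()


class TestPopulationCriterion:
    def _fake(self, bec):
        # back out a mixture with the requested bec: fix lf and ls, solve for p
        lf, ls = 1.0, 1e-12
        r = ls / lf * np.exp(bec * (lf - ls))
        p = r / (1.0 + r)
        res = act.BoutMixtureResults(None, p, lf, ls, 1000, 0.0, True)
        assert res.bec == pytest.approx(bec, rel=1e-4)
        return res

    def test_mean_of_two(self):
        models = [self._fake(40.0), self._fake(60.0)]
        assert population_criterion(models) == pytest.approx(50.0, abs=0.01)

    def test_single_model_identity(self):
        m = self._fake(47.0)
        assert population_criterion([m]) == pytest.approx(47.0, abs=0.01)

    def test_packaged_default(self):
        assert population_criterion(None) == 53.16

    def test_all_nonconverged_raises(self):
        m = self._fake(40.0)
        m.converged = False
        with pytest.raises(ValueError):
            population_criterion([m])


def brute_force_labels(states, durations_min, criterion, land_hr):
    """Independent event-by-event application of the three threshold rules."""
    out = []
    for s, d in zip(states, durations_min):
        if s == "dry":
            if d > land_hr * 60:
                out.append("land")
            elif d > criterion:
                out.append("flight")
            else:
                out.append("foraging")
        else:
            out.append("float" if d > criterion else "foraging")
    return out


class TestClassifyEvents:
    @pytest.mark.parametrize(
        "state,minutes,expected",
        [
            ("dry", 120.0, "flight"),
            ("dry", 17 * 60.0, "land"),
            ("wet", 30.0, "foraging"),
            ("wet", 54.0, "float"),
            ("dry", 53.16, "foraging"),  # boundary: strictly longer than criterion
            ("dry", 16 * 60.0, "flight"),  # boundary: land rule is strictly > 16 hr
        ],
    )
    def test_rules(self, state, minutes, expected):
        other = "wet" if state == "dry" else "dry"
        s = make_immersion([other, state, other], [10.0, minutes, 10.0])
        ev = classify_events(s)
        assert ev["label"].iloc[1] == expected

    def test_empty_series(self):
        s = make_immersion([], [])
        assert classify_events(s).empty

    def test_oracle_equivalence_and_conservation(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            s = random_alternating_series(rng, n_events=150)
            ev = classify_events(s, 53.16, 16.0)
            oracle = brute_force_labels(s.states, s.durations_s / 60.0, 53.16, 16.0)
            assert list(ev["label"]) == oracle
            assert ev["duration_min"].sum() * 60.0 == pytest.approx(s.total_seconds, rel=1e-12)


def _simple_twilights(dates, dawn_h=9, dusk_h=21):
    pairs = []
    for d in dates:
        d64 = np.datetime64(d, "D")
        pairs.append(
            TwilightPair(
                d64,
                d64.astype("datetime64[s]") + np.timedelta64(dawn_h * 3600, "s"),
                d64.astype("datetime64[s]") + np.timedelta64(dusk_h * 3600, "s"),
            )
        )
    return pairs


@pytest.fixture
def record():
    return BreedingRecord("t", "female", "successful", np.datetime64("2012-10-11"))


class TestDailyBudgets:
    def test_full_day_float(self, record):
        s = make_immersion(["wet"], [3 * 1440.0], start="2013-02-01T00:00:00")
        ev = classify_events(s)
        pairs = _simple_twilights(["2013-02-01", "2013-02-02", "2013-02-03"])
        budgets = compute_daily_budgets(ev, pairs, record)
        mid = budgets[(budgets["date"] == pd.Timestamp("2013-02-02"))]
        assert np.allclose(mid["prop_float"], 1.0)
        assert set(mid["period"]) == {"daylight", "darkness"}

    def test_event_split_at_dusk_conserves_time(self, record):
        # flight 20:00-22:00 splits into 60 min daylight + 60 min darkness
        s = make_immersion(
            ["wet", "dry", "wet"], [20 * 60.0, 120.0, 26 * 60.0], start="2013-02-01T00:00:00"
        )
        ev = classify_events(s)
        pairs = _simple_twilights(["2013-02-01", "2013-02-02"])
        budgets = compute_daily_budgets(ev, pairs, record)
        day1 = budgets[budgets["date"] == pd.Timestamp("2013-02-01")]
        flight_day = day1[day1["period"] == "daylight"]["prop_flight"].iloc[0] * day1[day1["period"] == "daylight"]["atsea_min"].iloc[0]
        flight_night = day1[day1["period"] == "darkness"]["prop_flight"].iloc[0] * day1[day1["period"] == "darkness"]["atsea_min"].iloc[0]
        assert flight_day == pytest.approx(60.0, abs=1e-6)
        assert flight_night == pytest.approx(60.0, abs=1e-6)

    def test_budget_closure_property(self, record):
        rng = np.random.default_rng(12)
        s = random_alternating_series(rng, n_events=400)
        ev = classify_events(s)
        dates = pd.date_range("2013-01-01", periods=40).strftime("%Y-%m-%d")
        budgets = compute_daily_budgets(ev, _simple_twilights(dates), record)
        atsea = budgets[budgets["atsea_min"] > 0]
        total = atsea[["prop_foraging", "prop_flight", "prop_float"]].sum(axis=1)
        assert np.allclose(total, 1.0, atol=1e-9)

    def test_stage_and_days_since_laying(self, record):
        cal = StageCalendar()
        assert cal.stage_of("2013-02-01") == "rearing"
        assert cal.stage_of("2012-11-15") == "incubation"
        assert cal.stage_of("2012-12-20") == "hatching"
        assert cal.stage_of("2013-01-10") == "brooding"
        assert cal.stage_of("2013-05-01") == "nonbreeding"
        s = make_immersion(["wet", "dry"], [720.0, 720.0], start="2012-10-11T00:00:00")
        budgets = compute_daily_budgets(classify_events(s), _simple_twilights(["2012-10-11"]), record)
        laying_day = budgets[budgets["date"] == pd.Timestamp("2012-10-11")]
        assert (laying_day["days_since_laying"] == 0).all()

    def test_moon_attached(self, record):
        from pelagis.moon import moon_fraction

        s = make_immersion(["wet", "dry"], [720.0, 720.0], start="2013-02-01T00:00:00")
        moon = moon_fraction(pd.date_range("2013-01-30", "2013-02-03"))
        budgets = compute_daily_budgets(classify_events(s), _simple_twilights(["2013-02-01"]), record, moon=moon)
        assert budgets["moon"].notna().all()


class TestReturnDate:
    def _events(self, land_starts):
        rows = []
        for t in land_starts:
            rows.append({"individual_id": "t", "label": "land", "start": np.datetime64(t, "s"), "duration_min": 17 * 60.0})
        rows.append({"individual_id": "t", "label": "float", "start": np.datetime64("2013-05-01T00:00:00", "s"), "duration_min": 60.0})
        return pd.DataFrame(rows).sort_values("start").reset_index(drop=True)

    def test_first_event_after_boundary(self):
        ev = self._events(["2013-09-10T06:00:00"])
        assert extract_return_date(ev) == pd.Timestamp("2013-09-10")

    def test_missing_when_no_land(self):
        ev = self._events([])
        assert extract_return_date(ev) is None

    def test_lookback_admits_early_returners(self):
        ev = self._events(["2013-08-27T12:00:00", "2013-09-12T12:00:00"])
        assert extract_return_date(ev, lookback_days=30) == pd.Timestamp("2013-08-27")

    def test_breeding_land_not_counted(self):
        ev = self._events(["2012-12-20T00:00:00"])  # incubation shift, long before boundary
        assert extract_return_date(ev) is None
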