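"""Penalized quasi-binomial trend models: bases, PIRLS/GCV, tests, windows."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from pelagis.moon import SYNODIC_MONTH_DAYS
from pelagis.simulate import BreedingRecord
from pelagis.trends import (
    ActivityTrendModel,
    build_dataset,
    bspline_basis,
    cyclic_basis,
    cyclic_penalty,
    difference_penalty,
    window_comparison,
)


def simulate_trend_data(
    rng,
    n_birds=12,
    n_days=120,
    trials=200,
    status_gap=0.6,
    moon_amp=0.3,
    bird_sd=0.25,
    overdisperse=0.0,
    flat=False,
):
    """Binomial (or beta-binomial) proportions from a known logit trend.

    The realized per-bird intercepts are stored in ``df.attrs["bird_intercepts"]``
    so recovery tests can compare against the group trend actually generated.
    """
    rows = []
    intercepts = {}
    for b in range(n_birds):
        status = "successful" if b < n_birds // 2 else "failed"
        b_int = rng.normal(0, bird_sd)
        intercepts[f"b{b}"] = (status, b_int)
        for d in range(n_days):
            age = d % SYNODIC_MONTH_DAYS
            if flat:
                eta = 0.0
            else:
                eta = (
                    -0.4
                    + (status_gap if status == "successful" else 0.0)
                    + 0.8 * np.sin(2 * np.pi * d / n_days)
                    + moon_amp * np.cos(2 * np.pi * (age - SYNODIC_MONTH_DAYS / 2) / SYNODIC_MONTH_DAYS)
                    + b_int
                )
            p = expit(eta)
            if overdisperse > 0:
                p = rng.beta(p / overdisperse, (1 - p) / overdisperse)
            y = rng.binomial(trials, p) / trials
            rows.append(
                dict(
                    individual_id=f"b{b}",
                    status=status,
                    sex="male",
                    days_since_laying=float(d),
                    moon=np.nan,
                    moon_age=age,
                    period="daylight",
                    activity="flight",
                    proportion=y,
                    weight=trials,
                )
            )
    df = pd.DataFrame(rows)
    df.attrs["bird_intercepts"] = intercepts
    return df


class TestBases:
    def test_cyclic_periodicity_and_unity(self):
        x = np.linspace(0, SYNODIC_MONTH_DAYS, 57)
        b = cyclic_basis(x)
        assert np.allclose(b.sum(axis=1), 1.0)
        assert np.allclose(b[0], b[-1])  # endpoints identical
        # derivative continuity at the seam
        eps = 1e-5
        left = (cyclic_basis(np.array([SYNODIC_MONTH_DAYS - eps])) - cyclic_basis(np.array([SYNODIC_MONTH_DAYS - 2 * eps]))) / eps
        right = (cyclic_basis(np.array([2 * eps])) - cyclic_basis(np.array([eps]))) / eps
        assert np.allclose(left, right, atol=1e-4)

    def test_penalties_positive_semidefinite(self):
        for s in (difference_penalty(12), cyclic_penalty(3)):
            evals = np.linalg.eigvalsh(s)
            assert evals.min() > -1e-10
            assert np.allclose(s, s.T)

    def test_bspline_partition_of_unity(self):
        x = np.linspace(0, 10, 40)
        b = bspline_basis(x, 12, 0.0, 10.0)
        assert b.shape == (40, 12)
        assert np.allclose(b.sum(axis=1), 1.0)


class TestBuildDataset:
    def _budgets(self, n_days=3):
        rows = []
        for d in pd.date_range("2013-02-01", periods=n_days):
            for period in ("daylight", "darkness"):
                rows.append(
                    dict(
                        individual_id="b0",
                        date=d,
                        period=period,
                        prop_foraging=0.2,
                        prop_flight=0.5,
                        prop_float=0.3,
                        atsea_min=600.0,
                        land_min=0.0,
                        days_since_laying=(d - pd.Timestamp("2012-10-11")).days,
                        stage="rearing",
                        moon=0.5,
                    )
                )
        return pd.DataFrame(rows)

    def _records(self):
        return [BreedingRecord("b0", "male", "successful", np.datetime64("2012-10-11"))]

    def test_row_counting(self):
        data = build_dataset(self._budgets(3), self._records())
        assert len(data) == 3 * 2 * 3  # days x periods x activities

    def test_proportion_validation(self):
        bad = self._budgets(2)
        bad.loc[0, "prop_flight"] = 1.7
        with pytest.raises(ValueError):
            build_dataset(bad, self._records())

    def test_moon_age_attached(self):
        data = build_dataset(self._budgets(2), self._records())
        assert ((data["moon_age"] >= 0) & (data["moon_age"] < SYNODIC_MONTH_DAYS)).all()


class TestModelFit:
    def test_null_recovery_flat_data(self):
        rng = np.random.default_rng(21)
        data = simulate_trend_data(rng, n_birds=8, n_days=80, flat=True, bird_sd=0.0)
        res = ActivityTrendModel(data, "flight", "daylight").fit()
        days = np.linspace(0, 79, 40)
        for status in ("failed", "successful"):
            curve = res.predict_group_curve(status, days, ci=False)["estimate"]
            assert np.abs(curve - 0.5).max() < 0.02
        edf = res.term_edf()
        assert edf["f(days):failed"] < 2.5
        assert edf["f(days):successful"] < 2.5

    def test_monotone_edf_in_lambda(self):
        rng = np.random.default_rng(22)
        data = simulate_trend_data(rng, n_birds=6, n_days=60)
        model = ActivityTrendModel(data, "flight", "daylight")
        lam_soft = {t.name: 1e-2 for t in model.terms if t.searchable}
        lam_hard = {t.name: 1e4 for t in model.terms if t.searchable}
        soft = model.fit(lambdas=lam_soft)
        hard = model.fit(lambdas=lam_hard)
        for name in lam_soft:
            assert hard.term_edf()[name] <= soft.term_edf()[name] + 1e-6

    def test_dispersion_binomial_vs_overdispersed(self):
        rng = np.random.default_rng(23)
        data = simulate_trend_data(rng, n_birds=8, n_days=80)
        res = ActivityTrendModel(data, "flight", "daylight").fit()
        assert res.dispersion == pytest.approx(1.0, abs=0.2)
        over = simulate_trend_data(np.random.default_rng(24), n_birds=8, n_days=80, overdisperse=0.02)
        res_over = ActivityTrendModel(over, "flight", "daylight").fit()
        assert res_over.dispersion > 1.3

    def test_cyclic_endpoint_equality_exact(self):
        rng = np.random.default_rng(25)
        data = simulate_trend_data(rng, n_birds=6, n_days=60)
        res = ActivityTrendModel(data, "flight", "daylight").fit()
        mc = res.predict_moon_curve(np.array([0.0, SYNODIC_MONTH_DAYS]), ci=False)
        assert mc["effect"].iloc[0] == pytest.approx(mc["effect"].iloc[1], abs=1e-12)

    def test_smooth_term_edf_bounded_by_basis(self):
        rng = np.random.default_rng(26)
        data = simulate_trend_data(rng, n_birds=6, n_days=60)
        res = ActivityTrendModel(data, "flight", "daylight").fit()
        table = res.test_smooth_terms()
        assert (table["edf"] <= table["ref_df"] + 1e-9).all()
        assert set(table["term"]) == {"f(days):failed", "f(days):successful", "f(moon)"}

    def test_group_divergence_detected(self):
        rng = np.random.default_rng(27)
        data = simulate_trend_data(rng, n_birds=10, n_days=100, status_gap=1.2)
        res = ActivityTrendModel(data, "flight", "daylight").fit()
        table = res.test_smooth_terms().set_index("term")
        assert table.loc["f(moon)", "p_value"] < 0.001  # strong moon signal built in

    def test_pirls_matches_statsmodels_glm_unpenalized(self):
        # dual route: with all penalties ~0 and no smooths beyond parametric
        # columns, PIRLS equals a statsmodels binomial GLM with Pearson scale
        import statsmodels.api as sm

        rng = np.random.default_rng(28)
        data = simulate_trend_data(rng, n_birds=4, n_days=40, bird_sd=0.0)
        model = ActivityTrendModel(data, "flight", "daylight", n_knots=4)
        lam = {t.name: 1e-8 for t in model.terms if t.searchable}
        lam["bird"] = 1e-6
        res = model.fit(lambdas=lam)
        glm = sm.GLM(
            model.y, model.X, family=sm.families.Binomial(), freq_weights=model.w
        ).fit(scale="X2")
        assert np.allclose(model.X @ res.params, model.X @ glm.params, atol=1e-3)

    def test_requires_two_individuals_per_status(self):
        rng = np.random.default_rng(29)
        data = simulate_trend_data(rng, n_birds=6, n_days=30)
        solo = data[data["individual_id"].isin(["b0", "b3", "b4", "b5"])]  # one successful
        with pytest.raises(ValueError):
            ActivityTrendModel(solo, "flight", "daylight")

    def test_summary_renders(self):
        rng = np.random.default_rng(30)
        data = simulate_trend_data(rng, n_birds=6, n_days=50)
        res = ActivityTrendModel(data, "flight", "daylight").fit()
        s = res.summary()
        assert "dispersion" in s and "f(moon)" in s


class TestWindowComparison:
    def _budgets_and_records(self, rng, n_birds=6, identical_windows=False):
        records = []
        rows = []
        for b in range(n_birds):
            status = "successful" if b % 2 == 0 else "failed"
            sex = "male" if b < n_birds // 2 else "female"
            records.append(BreedingRecord(f"b{b}", sex, status, np.datetime64("2012-10-11"),
                                          failure_date=np.datetime64("2012-12-26") if status == "failed" else None))
            for d in pd.date_range("2013-01-28", "2013-02-25").append(pd.date_range("2013-06-24", "2013-07-21")):
                for period in ("daylight", "darkness"):
                    base = 0.5 if (identical_windows or d.month in (1, 2)) else 0.3
                    f = np.clip(base + rng.normal(0, 0.05), 0.01, 0.97)
                    rest = 1.0 - f
                    rows.append(
                        dict(individual_id=f"b{b}", date=d, period=period,
                             prop_foraging=f, prop_flight=rest * 0.6, prop_float=rest * 0.4,
                             atsea_min=600.0, land_min=0.0,
                             days_since_laying=(d - pd.Timestamp("2012-10-11")).days,
                             stage="rearing", moon=0.5)
                    )
        return pd.DataFrame(rows), records

    def test_identical_windows_zero_difference(self):
        rng = np.random.default_rng(31)
        budgets, records = self._budgets_and_records(rng)
        win = (np.datetime64("2013-02-01"), np.datetime64("2013-02-20"))
        summary, tests = window_comparison(budgets, records, win, win, n_iter=50, seed=0)
        w = tests[tests["factor"] == "window"]
        assert np.allclose(w["difference"], 0.0, atol=1e-12)

    def test_window_means_match_hand_arithmetic(self):
        records = [BreedingRecord("b0", "male", "successful", np.datetime64("2012-10-11")),
                   BreedingRecord("b1", "male", "successful", np.datetime64("2012-10-11"))]
        rows = []
        for uid, props in (("b0", [0.2, 0.4, 0.6]), ("b1", [0.1, 0.1, 0.4])):
            for d, f in zip(pd.date_range("2013-02-01", periods=3), props):
                rows.append(dict(individual_id=uid, date=d, period="daylight",
                                 prop_foraging=f, prop_flight=(1 - f) / 2, prop_float=(1 - f) / 2,
                                 atsea_min=600.0, land_min=0.0, days_since_laying=1, stage="rearing", moon=0.5))
            for d, f in zip(pd.date_range("2013-06-25", periods=3), props):
                rows.append(dict(individual_id=uid, date=d, period="daylight",
                                 prop_foraging=f / 2, prop_flight=0.5, prop_float=0.5 - f / 2,
                                 atsea_min=600.0, land_min=0.0, days_since_laying=1, stage="nonbreeding", moon=0.5))
        budgets = pd.DataFrame(rows)
        summary, tests = window_comparison(
            budgets, records,
            (np.datetime64("2013-02-01"), np.datetime64("2013-02-03")),
            (np.datetime64("2013-06-25"), np.datetime64("2013-06-27")),
            n_iter=20, seed=0,
        )
        w = tests[(tests["factor"] == "window") & (tests["activity"] == "prop_foraging")]
        hand = np.mean([np.mean([0.2, 0.4, 0.6]), np.mean([0.1, 0.1, 0.4])])
        assert w["difference"].iloc[0] == pytest.approx(hand - hand / 2, abs=1e-12)

    def test_resampling_unit_is_individual(self):
        # permuting the order of a bird's days leaves the comparison unchanged
        rng = np.random.default_rng(32)
        budgets, records = self._budgets_and_records(rng)
        win_a = (np.datetime64("2013-01-28"), np.datetime64("2013-02-25"))
        win_b = (np.datetime64("2013-06-24"), np.datetime64("2013-07-21"))
        _, t1 = window_comparison(budgets, records, win_a, win_b, n_iter=100, seed=5)
        shuffled = budgets.copy()
        for uid, grp in shuffled.groupby("individual_id"):
            for (period, month), sub in grp.groupby([grp["period"], grp["date"].dt.month]):
                perm = rng.permutation(sub.index)
                cols = ["prop_foraging", "prop_flight", "prop_float"]
                shuffled.loc[sub.index, cols] = shuffled.loc[perm, cols].to_numpy()
        _, t2 = window_comparison(shuffled, records, win_a, win_b, n_iter=100, seed=5)
        # per-individual window means are order-invariant, so every observed
        # difference is unchanged (p-values can flip on float-level ties)
        assert np.allclose(t1["difference"], t2["difference"], atol=1e-12)
        assert list(t1["factor"]) == list(t2["factor"])

    def test_empty_window_errors(self):
        rng = np.random.default_rng(33)
        budgets, records = self._budgets_and_records(rng)
        with pytest.raises(ValueError):
            window_comparison(budgets, records,
                              (np.datetime64("2014-01-01"), np.datetime64("2014-01-10")),
                              (np.datetime64("2013-06-24"), np.datetime64("2013-07-21")))
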