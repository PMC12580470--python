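"""Beta-binomial nocturnality regression: likelihood, design, fit, prediction."""

from datetime import date, datetime, timedelta, timezone

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit
from scipy.stats import betabinom as scipy_betabinom
from scipy.stats import binom

from huntshift import nocturnality, sun
from huntshift.events import EffortCalendar


def _rows(n, rng, efforts=("high", "medium", "low")):
    return pd.DataFrame(
        {
            "effort": rng.choice(efforts, size=n),
            "placement": rng.choice(["trail", "forest"], size=n),
            "x": rng.normal(size=n),
            "n_night": 0,
            "n_day": 0,
        }
    )


class TestDesign:
    def test_full_factorial_column_count_two_levels(self):
        rng = np.random.default_rng(0)
        rows = _rows(50, rng, efforts=("high", "medium"))
        X, _, _, _ = nocturnality.build_design(
            rows, nocturnality.SpeciesFormula(covariates=("x",))
        )
        # intercept, effort, placement, effort:placement, x, effort:x,
        # placement:x, effort:placement:x
        assert X.shape[1] == 8

    def test_full_factorial_column_count_three_efforts_three_covariates(self):
        rng = np.random.default_rng(1)
        rows = _rows(100, rng)
        rows["y"] = rng.normal(size=100)
        rows["z"] = rng.normal(size=100)
        X, _, _, _ = nocturnality.build_design(
            rows, nocturnality.SpeciesFormula(covariates=("x", "y", "z"))
        )
        assert X.shape[1] == 1 + 2 + 1 + 2 + 3 * (1 + 2 + 1 + 2)

    def test_zscoring_and_stored_constants(self):
        rng = np.random.default_rng(2)
        rows = _rows(200, rng)
        rows["x"] = rng.normal(5.0, 3.0, size=200)
        X, _, _, scaling = nocturnality.build_design(
            rows, nocturnality.SpeciesFormula(covariates=("x",))
        )
        assert abs(X["x"].mean()) < 1e-10 and abs(X["x"].std(ddof=0) - 1) < 1e-10
        m, s = scaling["x"]
        np.testing.assert_allclose(X["x"] * s + m, rows["x"], rtol=1e-12)

    def test_constant_covariate_dropped(self):
        rng = np.random.default_rng(3)
        rows = _rows(30, rng)
        rows["x"] = 1.0
        X, _, _, _ = nocturnality.build_design(
            rows, nocturnality.SpeciesFormula(covariates=("x",))
        )
        assert "x" not in X.columns

    def test_transforms_log1p_and_quadratic(self):
        rng = np.random.default_rng(4)
        rows = _rows(40, rng)
        rows["x"] = rng.uniform(0, 100, size=40)
        X, _, _, scaling = nocturnality.build_design(
            rows,
            nocturnality.SpeciesFormula(
                covariates=("x",), transforms={"x": ["log1p", "quadratic"]}
            ),
        )
        assert "x^2" in X.columns
        m, s = scaling["x"]
        np.testing.assert_allclose(X["x"] * s + m, np.log1p(rows["x"]), rtol=1e-10)


class TestLoglik:
    def test_bernoulli_reduction(self):
        X = np.array([[1.0]])
        for phi in (0.5, 3.0, 100.0):
            ll = nocturnality.betabinom_loglik(
                np.array([0.0]), phi, X, np.array([1.0]), np.array([1.0])
            )
            assert ll == pytest.approx(np.log(0.5), abs=1e-10)

    def test_binomial_limit_at_large_phi(self):
        rng = np.random.default_rng(5)
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        beta = np.array([0.3, -0.7])
        n = rng.integers(1, 40, size=20).astype(float)
        k = rng.binomial(n.astype(int), expit(X @ beta)).astype(float)
        ll_bb = nocturnality.betabinom_loglik(beta, 1e6, X, k, n)
        ll_binom = binom.logpmf(k, n, expit(X @ beta)).sum()
        assert ll_bb == pytest.approx(ll_binom, abs=1e-4)

    def test_matches_scipy_betabinom_pmf(self):
        rng = np.random.default_rng(6)
        X = np.column_stack([np.ones(15), rng.normal(size=15)])
        beta = np.array([-0.2, 0.5])
        phi = 7.3
        n = rng.integers(1, 20, size=15)
        k = np.array([rng.integers(0, ni + 1) for ni in n])
        mu = expit(X @ beta)
        expected = scipy_betabinom.logpmf(k, n, mu * phi, (1 - mu) * phi).sum()
        got = nocturnality.betabinom_loglik(beta, phi, X, k.astype(float), n.astype(float))
        assert got == pytest.approx(expected, rel=1e-10)

    def test_nonpositive_phi_rejected(self):
        with pytest.raises(ValueError):
            nocturnality.betabinom_loglik(
                np.zeros(1), 0.0, np.ones((1, 1)), np.zeros(1), np.ones(1)
            )


def _simulate_bb(rng, X, beta, phi, n_per):
    mu = expit(X @ beta)
    p = rng.beta(mu * phi, (1 - mu) * phi)
    return rng.binomial(n_per, p).astype(float)


class TestFit:
    def test_null_intercept_within_3se(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame({"Intercept": np.ones(150)})
        k = _simulate_bb(rng, X.to_numpy(), np.array([0.0]), 12.0, 40)
        fit = nocturnality.fit_betabinom(X, k, np.full(150, 40.0))
        assert fit.converged
        assert abs(fit.coef["Intercept"]) < 3 * fit.se["Intercept"]

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame({"Intercept": np.ones(80), "x": rng.normal(size=80)})
        k = _simulate_bb(rng, X.to_numpy(), np.array([0.2, 0.6]), 10.0, 30)
        n = np.full(80, 30.0)
        fit1 = nocturnality.fit_betabinom(X, k, n)
        perm = rng.permutation(80)
        fit2 = nocturnality.fit_betabinom(X.iloc[perm].reset_index(drop=True), k[perm], n[perm])
        np.testing.assert_allclose(fit1.coef, fit2.coef, atol=1e-6)

    def test_map_shrinks_toward_zero(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame({"Intercept": np.ones(30), "x": rng.normal(size=30)})
        k = _simulate_bb(rng, X.to_numpy(), np.array([0.0, 1.5]), 8.0, 10)
        n = np.full(30, 10.0)
        ml = nocturnality.fit_betabinom(X, k, n, method="ml")
        map_ = nocturnality.fit_betabinom(X, k, n, method="map", penalty_sd=0.5)
        assert abs(map_.coef["x"]) < abs(ml.coef["x"])


class TestPredict:
    def _unit_fit(self, names, beta):
        p = len(names)
        return nocturnality.NocturnalityFit(
            coef=pd.Series(beta, index=names), se=pd.Series(np.ones(p), index=names),
            phi=10.0, phi_se=1.0, loglik=0.0, converged=True, gradient_norm=0.0,
            scaling={}, cov=np.eye(p + 1) * 1e-6,
        )

    def test_zero_covariates_give_half(self):
        fit = self._unit_fit(["Intercept", "x"], [0.0, -1.0])
        grid = pd.DataFrame({"Intercept": [1.0], "x": [0.0]})
        out = nocturnality.predict_nocturnality(fit, grid)
        assert out["night_share"].iloc[0] == pytest.approx(0.5)

    def test_matches_hand_computed_inverse_logit(self):
        fit = self._unit_fit(["Intercept", "x"], [0.4, -0.9])
        grid = pd.DataFrame({"Intercept": [1.0, 1.0, 1.0], "x": [-1.0, 0.0, 2.0]})
        out = nocturnality.predict_nocturnality(fit, grid)
        for i, x in enumerate([-1.0, 0.0, 2.0]):
            assert out["night_share"].iloc[i] == pytest.approx(expit(0.4 - 0.9 * x))

    def test_crosses_half_where_linear_predictor_crosses_zero(self):
        fit = self._unit_fit(["Intercept", "x"], [1.0, -2.0])
        grid = pd.DataFrame({"Intercept": np.ones(5), "x": np.linspace(0, 1, 5)})
        out = nocturnality.predict_nocturnality(fit, grid)
        assert np.all((out["night_share"] > 0.5) == (out["linpred"] > 0))

    def test_unknown_names_rejected(self):
        fit = self._unit_fit(["Intercept"], [0.0])
        with pytest.raises(ValueError, match="unknown"):
            nocturnality.predict_nocturnality(fit, pd.DataFrame({"bogus": [1.0]}))


class TestAggregateDayNight:
    def _deployments(self):
        return pd.DataFrame(
            [
                {
                    "camera_id": "c1", "location_id": "L1", "placement": "trail",
                    "dist_hunting_zone_m": 0.0, "vis50": 0.5, "vis70": 0.8, "vis140": 0.9,
                }
            ]
        )

    def _calendar(self):
        return EffortCalendar(months=[date(2021, 6, 1)], counts=[10.0], labels=["medium"])

    def test_noon_events_all_day_midnight_all_night(self):
        st = sun.twilight_times(sun.DEFAULT_LAT, sun.DEFAULT_LON, date(2021, 6, 10))
        noon = st.sunrise + (st.sunset - st.sunrise) / 2
        midnight = noon + timedelta(hours=12)
        ev = pd.DataFrame(
            {
                "camera_id": "c1",
                "event_time": [noon] * 3 + [midnight] * 2,
            }
        )
        out = nocturnality.aggregate_day_night(ev, self._deployments(), self._calendar())
        row = out.iloc[0]
        assert row["n_day"] == 3 and row["n_night"] == 2

    def test_counts_match_per_event_altitude_oracle(self, study, run_config):
        from huntshift import report as report_mod

        ev = report_mod.independent_events(run_config, study["detections"], study["calendar"])
        wild = ev["wildlife"]
        sp = wild[wild["class_label"] == "red_deer"]
        out = nocturnality.aggregate_day_night(sp, study["deployments"], study["calendar"])
        night_oracle = np.array(
            [sun.sun_altitude(sun.DEFAULT_LAT, sun.DEFAULT_LON, t) < -12 for t in sp["event_time"]]
        )
        assert out["n_night"].sum() == night_oracle.sum()
        assert (out["n_night"] + out["n_day"]).sum() == len(sp)


def test_posterior_sampler_tracks_ml_on_simple_model():
    rng = np.random.default_rng(10)
    X = pd.DataFrame({"Intercept": np.ones(60)})
    true_mu = 0.7
    k = _simulate_bb(rng, X.to_numpy(), np.array([logit(true_mu)]), 20.0, 40)
    n = np.full(60, 40.0)
    fit = nocturnality.fit_betabinom(X, k, n)
    draws = nocturnality.sample_posterior(X, k, n, n_samples=1500, burn=500, step_scale=0.08, seed=1)
    assert abs(draws["Intercept"].mean() - fit.coef["Intercept"]) < 3 * fit.se["Intercept"]
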