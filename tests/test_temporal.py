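"""Water-year MEI windows, the log-linear density model, and LMG."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from streamcits.temporal import (
    DEFAULT_WINDOWS,
    environmental_cv_component,
    event_covariates,
    fit_density_model,
    lmg_decomposition,
    partition_temporal_cv,
    water_year_mei,
)
from streamcits.types import EnsoSeries, ValidationError


def series_of(values_by_year_month):
    return EnsoSeries(records=[(y, m, v) for (y, m), v in values_by_year_month.items()])


class TestWaterYearMEI:
    def test_fall_window_is_sep_oct_mean(self):
        enso = series_of({(2007, 9): 1.0, (2007, 10): 2.0})
        assert water_year_mei(enso, 2007, "fall") == pytest.approx(1.5)

    def test_spring_window_of_equal_values_is_identity(self):
        months = {(2006, m): 0.7 for m in (9, 10, 11, 12)}
        months.update({(2007, m): 0.7 for m in (1, 2, 3, 4)})
        assert water_year_mei(series_of(months), 2007, "spring") == pytest.approx(0.7)

    def test_spring_window_spans_previous_september_through_april(self):
        assert DEFAULT_WINDOWS["spring"] == (
            (9, -1), (10, -1), (11, -1), (12, -1), (1, 0), (2, 0), (3, 0), (4, 0)
        )

    def test_constant_series_returns_constant(self):
        months = {(y, m): -0.4 for y in (2006, 2007) for m in range(1, 13)}
        for season in ("fall", "spring"):
            assert water_year_mei(series_of(months), 2007, season) == pytest.approx(-0.4)

    def test_missing_month_named(self):
        enso = series_of({(2007, 9): 1.0})
        with pytest.raises(ValidationError, match="2007-10"):
            water_year_mei(enso, 2007, "fall")

    def test_invariant_to_record_ordering(self):
        a = EnsoSeries(records=[(2007, 9, 1.0), (2007, 10, 2.0)])
        b = EnsoSeries(records=[(2007, 10, 2.0), (2007, 9, 1.0)])
        assert water_year_mei(a, 2007, "fall") == water_year_mei(b, 2007, "fall")


class TestFitDensityModel:
    def test_noiseless_coefficients_recovered_exactly(self):
        rng = np.random.default_rng(1)
        mei = rng.normal(size=20)
        year_index = np.repeat(np.arange(10), 2)
        b0, b1, b2 = 3.4, 0.14, -0.02
        density = np.exp(b0 + b1 * mei + b2 * year_index)
        fit = fit_density_model(
            pd.DataFrame({"density": density, "mei": mei, "year_index": year_index})
        )
        assert fit.b0 == pytest.approx(b0, abs=1e-8)
        assert fit.b1_enso == pytest.approx(b1, abs=1e-8)
        assert fit.b2_year == pytest.approx(b2, abs=1e-8)
        assert fit.r2 == pytest.approx(1.0)

    def test_intercept_matches_log_mean_density_with_centered_covariates(self):
        """A stream averaging 29 per 0.1 m^2 with centred covariates has an
        intercept near ln 29 ~ 3.37 — the natural-log convention."""
        rng = np.random.default_rng(2)
        mei = rng.normal(size=22)
        mei -= mei.mean()
        year_index = np.linspace(-5, 5, 22)
        density = 29.0 * np.exp(0.12 * mei + rng.normal(0, 0.05, 22))
        fit = fit_density_model(
            pd.DataFrame({"density": density, "mei": mei, "year_index": year_index})
        )
        assert fit.b0 == pytest.approx(math.log(29.0), abs=0.1)

    def test_single_predictor_model_supported(self):
        df = pd.DataFrame(
            {"density": [10.0, 12.0, 15.0, 11.0, 13.0], "mei": [0.1, 0.5, 1.0, 0.2, 0.7]}
        )
        fit = fit_density_model(df, predictors=("mei",))
        assert fit.b2_year is None
        assert fit.df == 3

    def test_nonpositive_density_rejected(self):
        df = pd.DataFrame(
            {"density": [10.0, 0.0, 15.0, 11.0], "mei": [0.1, 0.5, 1.0, 0.2],
             "year_index": [0, 1, 2, 3]}
        )
        with pytest.raises(ValidationError):
            fit_density_model(df)

    def test_collinear_covariates_flagged(self):
        df = pd.DataFrame(
            {"density": [10.0, 12.0, 15.0, 11.0, 9.0],
             "mei": [0.0, 1.0, 2.0, 3.0, 4.0],
             "year_index": [0.0, 2.0, 4.0, 6.0, 8.0]}
        )
        assert fit_density_model(df).collinear

    def test_slope_recovery_on_simulated_surveys(self):
        """b1 = 0.14 surveys: the OLS estimate's 95% CI covers the truth in
        >= 90% of replicates and the mean estimate is within 3 SE."""
        from streamcits.synthetic import (
            ReachSpec,
            TemporalSpec,
            default_community,
            simulate_survey,
            synthetic_enso,
        )

        years = list(range(2005, 2016))
        community = default_community()
        reach = ReachSpec()
        covered, estimates = 0, []
        n_rep = 60
        rng = np.random.default_rng(3)
        for _ in range(n_rep):
            enso = synthetic_enso(years, seed=rng)
            ds = simulate_survey(
                community, reach, TemporalSpec(b1_enso=0.14), enso, years, seed=rng
            )
            cov = event_covariates(ds, enso, "SimCreek")
            y = np.log(cov["density"])
            X = sm.add_constant(cov[["mei", "year_index"]])
            fit = sm.OLS(y, X).fit()
            lo, hi = fit.conf_int().loc["mei"]
            covered += lo <= 0.14 <= hi
            estimates.append(fit.params["mei"])
        assert covered / n_rep >= 0.90
        se = np.std(estimates, ddof=1) / math.sqrt(n_rep)
        assert abs(np.mean(estimates) - 0.14) < 3 * se


class TestLMG:
    def _brute_force(self, y, X):
        """Average sequential R^2 increments over every predictor ordering."""
        p = X.shape[1]

        def r2(cols):
            if not cols:
                return 0.0
            return sm.OLS(y, sm.add_constant(X[:, list(cols)])).fit().rsquared

        contrib = np.zeros(p)
        orders = list(itertools.permutations(range(p)))
        for order in orders:
            seen = []
            for i in order:
                before = r2(tuple(seen))
                seen.append(i)
                contrib[i] += r2(tuple(seen)) - before
        return contrib / len(orders)

    def test_matches_brute_force_at_p3(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 3))
        y = X @ np.array([1.0, 0.5, -0.3]) + rng.normal(size=40)
        res = lmg_decomposition(y, X, names=["a", "b", "c"])
        expected = self._brute_force(y, X)
        for name, exp in zip(["a", "b", "c"], expected):
            assert res.contributions[name] == pytest.approx(exp, abs=1e-10)

    def test_contributions_sum_to_model_r2(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        res = lmg_decomposition(y, X)
        assert sum(res.contributions.values()) == pytest.approx(res.model_r2, abs=1e-12)
        assert sum(res.percents.values()) + res.unexplained_percent == pytest.approx(100.0)

    def test_orthogonal_predictors_get_their_marginal_r2(self):
        rng = np.random.default_rng(6)
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        y = 2 * x1 + 1 * x2 + rng.normal(0, 0.5, n)
        res = lmg_decomposition(y, np.column_stack([x1, x2]), names=["x1", "x2"])
        for name, x in (("x1", x1), ("x2", x2)):
            marginal = sm.OLS(y, sm.add_constant(x)).fit().rsquared
            assert res.contributions[name] == pytest.approx(marginal, abs=1e-10)

    def test_identical_predictors_split_r2_evenly(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=50)
        y = x + rng.normal(0, 0.3, 50)
        res = lmg_decomposition(y, np.column_stack([x, x]), names=["u", "v"])
        assert res.contributions["u"] == pytest.approx(res.contributions["v"], abs=1e-10)
        assert res.contributions["u"] == pytest.approx(res.model_r2 / 2, abs=1e-10)

    def test_single_predictor_equals_its_r2(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        res = lmg_decomposition(y, x[:, None], names=["x"])
        full = sm.OLS(y, sm.add_constant(x)).fit().rsquared
        assert res.contributions["x"] == pytest.approx(full, abs=1e-12)

    def test_nonnegative_for_orthonormal_designs(self):
        rng = np.random.default_rng(9)
        Q, _ = np.linalg.qr(rng.normal(size=(40, 3)))
        y = Q @ np.array([1.0, -2.0, 0.5]) + rng.normal(0, 0.5, 40)
        res = lmg_decomposition(y, Q)
        assert all(v >= 0 for v in res.contributions.values())

    def test_too_many_predictors_rejected(self):
        rng = np.random.default_rng(10)
        with pytest.raises(ValidationError):
            lmg_decomposition(rng.normal(size=20), rng.normal(size=(20, 11)))


class TestTemporalPartition:
    @pytest.mark.parametrize(
        "cv,percent,expected", [(0.36, 30.0, 0.11), (0.31, 27.0, 0.08)]
    )
    def test_environmental_component_arithmetic(self, cv, percent, expected):
        from streamcits.temporal import LMGResult

        lmg = LMGResult(
            contributions={"mei": percent / 100 * 0.8, "year_index": percent / 100 * 0.2},
            model_r2=percent / 100,
            percents={"mei": percent * 0.8, "year_index": percent * 0.2},
            unexplained_percent=100 - percent,
        )
        assert round(environmental_cv_component(cv, lmg), 2) == expected

    def test_zero_explained_variance_all_unexplained(self):
        from streamcits.temporal import LMGResult

        lmg = LMGResult(contributions={}, model_r2=0.0, percents={},
                        unexplained_percent=100.0)
        part = partition_temporal_cv(0.4, lmg)
        assert part.unexplained == (1.0, pytest.approx(0.4))

    def test_environmental_fraction_increases_with_generating_slope(self):
        """Stronger climate forcing in the generator raises the estimated
        environmental share of the temporal CV (3-point grid)."""
        from streamcits.synthetic import (
            ReachSpec,
            TemporalSpec,
            default_community,
            simulate_survey,
            synthetic_enso,
        )
        from streamcits.variability import temporal_cv

        years = list(range(2005, 2016))
        community = default_community()
        shares = []
        for b1 in (0.0, 0.2, 0.6):
            vals = []
            for seed in (11, 12, 13, 14):
                enso = synthetic_enso(years, seed=seed)
                ds = simulate_survey(
                    community, ReachSpec(), TemporalSpec(b1_enso=b1, noise_sd=0.15),
                    enso, years, seed=seed + 100,
                )
                cov = event_covariates(ds, enso, "SimCreek")
                lmg = lmg_decomposition(
                    np.log(cov["density"]), cov[["mei", "year_index"]]
                )
                vals.append(lmg.model_r2)
            shares.append(np.mean(vals))
        assert shares[0] < shares[1] < shares[2]


class TestEventCovariates:
    def test_year_index_zero_based(self, simulated_survey):
        dataset, enso = simulated_survey
        cov = event_covariates(dataset, enso, "SimCreek")
        assert cov["year_index"].min() == 0
        assert cov["year_index"].max() == 10
        assert len(cov) == 22
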