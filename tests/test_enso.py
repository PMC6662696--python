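"""ENSO phase rules, annual stress, and the GLM/GLS trend models."""

import numpy as np
import pandas as pd
import pytest

from reefheat.enso import (
    aicc_from_loglik,
    annual_stress,
    classify_enso,
    compare_models,
    fit_glm,
    fit_gls,
)


def _oni_from_monthly(values, start="1985-01"):
    values = np.asarray(values, float)
    idx = pd.period_range(start, periods=len(values), freq="M")
    return pd.Series(values, index=idx, name="oni")


def brute_force_phase(months, threshold=0.05, min_months=5):
    """Literal month-counting oracle for one year of ONI values."""
    v = np.asarray(months, float)
    warm = (v > threshold).sum()
    cold = (v < -threshold).sum()
    if warm < min_months and cold < min_months:
        return "Neutral"
    if warm >= min_months and cold < min_months:
        return "El Nino"
    if cold >= min_months and warm < min_months:
        return "La Nina"
    if warm != cold:
        return "El Nino" if warm > cold else "La Nina"
    mw = np.abs(v[v > threshold]).mean()
    mc = np.abs(v[v < -threshold]).mean()
    if mw > mc:
        return "El Nino"
    if mc > mw:
        return "La Nina"
    return "Neutral"


class TestClassifyEnso:
    def test_seven_warm_months_is_el_nino(self):
        oni = _oni_from_monthly(np.r_[np.repeat(0.8, 7), np.zeros(5)])
        assert classify_enso(oni).loc[1985, "phase"] == "El Nino"

    def test_all_zero_year_is_neutral(self):
        oni = _oni_from_monthly(np.zeros(12))
        assert classify_enso(oni).loc[1985, "phase"] == "Neutral"

    def test_full_tie_falls_back_to_neutral(self):
        oni = _oni_from_monthly(np.r_[np.repeat(0.2, 6), np.repeat(-0.2, 6)])
        assert classify_enso(oni).loc[1985, "phase"] == "Neutral"

    def test_partial_year_rejected_with_months(self):
        oni = _oni_from_monthly(np.zeros(10))
        with pytest.raises(ValueError, match=r"\[11, 12\]"):
            classify_enso(oni)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            vals = rng.uniform(-1.5, 1.5, 12).round(2)
            oni = _oni_from_monthly(vals)
            got = classify_enso(oni).loc[1985, "phase"]
            assert got == brute_force_phase(vals)

    def test_exactly_one_phase_per_year(self, rng):
        vals = rng.uniform(-2, 2, 12 * 10)
        df = classify_enso(_oni_from_monthly(vals))
        assert len(df) == 10
        assert df["phase"].isin(["Neutral", "El Nino", "La Nina"]).all()
        non_neutral = df[df["phase"] != "Neutral"]
        qualifying = non_neutral.apply(
            lambda r: r["months_warm"] if r["phase"] == "El Nino" else r["months_cold"], axis=1
        )
        assert (qualifying >= 5).all()


class TestAnnualStress:
    def test_single_hot_month_sets_year_value(self):
        vals = np.zeros(12)
        vals[8] = 6.2
        monthly = _oni_from_monthly(vals)  # reuse the index helper
        y = annual_stress(monthly)
        assert y.loc[1985] == 6.2

    def test_constant_series(self):
        y = annual_stress(_oni_from_monthly(np.full(24, 2.0)))
        assert (y == 2.0).all()

    def test_33_year_series_has_33_values(self):
        y = annual_stress(_oni_from_monthly(np.random.default_rng(0).gamma(2, 1, 396)))
        assert len(y) == 33


def _make_inputs(rng, n=33, year_coef=0.03, shape=8.0, phase_effects=None):
    years = np.arange(1985, 1985 + n)
    idx = pd.Index(years, name="year")
    phase = rng.choice(["Neutral", "El Nino", "La Nina"], size=n, p=[0.5, 0.3, 0.2])
    phases = pd.DataFrame({"phase": phase}, index=idx)
    eta = 0.5 + year_coef * (years - years.min())
    if phase_effects:
        eta = eta + np.array([phase_effects.get(p, 0.0) for p in phase])
    mu = np.exp(eta)
    y = pd.Series(rng.gamma(shape, mu / shape), index=idx)
    return y, phases


class TestGammaGLM:
    def test_deviance_table_df_pattern_for_33_years(self, rng):
        y, phases = _make_inputs(rng)
        res = fit_glm(y, phases)
        tab = res.deviance_table.set_index("term")
        assert tab.loc["Years", "df"] == 1
        assert tab.loc["Years", "dfr"] == 30
        assert tab.loc["ENSO", "df"] == 2
        assert tab.loc["ENSO", "dfr"] == 28

    def test_residual_deviance_non_increasing(self, rng):
        for _ in range(10):
            y, phases = _make_inputs(rng, phase_effects={"El Nino": 0.3})
            res = fit_glm(y, phases)
            dev = res.deviance_table["resid_deviance"].values
            assert (np.diff(dev) <= 1e-12).all()

    def test_year_coefficient_recovery(self, rng):
        coefs = [
            fit_glm(*_make_inputs(rng)).coefficients["year"] for _ in range(100)
        ]
        assert abs(np.mean(coefs) - 0.03) < 0.005

    def test_constant_response_gives_zero_effects(self, rng):
        _, phases = _make_inputs(rng)
        y = pd.Series(np.full(33, 2.0), index=phases.index)
        res = fit_glm(y, phases)
        tab = res.deviance_table.set_index("term")
        assert tab.loc["Years", "F"] == 0.0
        assert res.coefficients["year"] == 0.0

    def test_zero_response_is_shifted_not_dropped(self, rng):
        y, phases = _make_inputs(rng)
        y.iloc[3] = 0.0
        res = fit_glm(y, phases)
        assert res.extras["zero_shifted"]
        assert np.isfinite(res.aicc)

    def test_phase_type_one_error_near_nominal(self, rng):
        rejections = 0
        n_reps = 200
        for _ in range(n_reps):
            y, phases = _make_inputs(rng)  # no phase effect in truth
            res = fit_glm(y, phases)
            tab = res.deviance_table.set_index("term")
            rejections += tab.loc["ENSO", "p"] <= 0.05
        assert 0.01 <= rejections / n_reps <= 0.11


class TestGlsAr1:
    def test_trend_recovered_under_ar1_noise(self, rng):
        slopes = []
        for _ in range(60):
            years = np.arange(1985, 2018)
            idx = pd.Index(years, name="year")
            phases = pd.DataFrame({"phase": ["Neutral"] * 33}, index=idx)
            e = np.empty(33)
            e[0] = rng.standard_normal()
            innov = rng.standard_normal(33) * np.sqrt(1 - 0.25)
            for i in range(1, 33):
                e[i] = 0.5 * e[i - 1] + innov[i]
            y = pd.Series(5.0 + 0.1 * (years - 1985) + e, index=idx)
            slopes.append(fit_gls(y, phases).coefficients["year"])
        assert abs(np.mean(slopes) - 0.1) < 0.02

    def test_independent_errors_estimate_rho_near_zero(self, rng):
        rhos = []
        for _ in range(40):
            years = np.arange(1985, 2018)
            idx = pd.Index(years, name="year")
            phases = pd.DataFrame({"phase": ["Neutral"] * 33}, index=idx)
            y = pd.Series(5.0 + rng.standard_normal(33), index=idx)
            rhos.append(fit_gls(y, phases).extras["rho"])
        assert abs(np.mean(rhos)) < 0.25

    def test_constant_y_gives_zero_slope(self, rng):
        _, phases = _make_inputs(rng)
        y = pd.Series(np.full(33, 4.0), index=phases.index)
        assert fit_gls(y, phases).coefficients["year"] == 0.0

    def test_singular_design_rejected(self, rng):
        years = np.arange(1985, 1997)
        idx = pd.Index(years, name="year")
        # phase perfectly collinear with the year split
        phases = pd.DataFrame({"phase": ["El Nino"] * 12}, index=idx)
        y = pd.Series(np.linspace(1, 3, 12), index=idx)
        res = fit_gls(y, phases)  # single level folds into intercept: fine
        assert "phase[El Nino]" in res.coefficients.index or len(res.coefficients) == 2


class TestModelComparison:
    def test_aicc_closed_form(self):
        assert aicc_from_loglik(-50.0, 4, 33) == pytest.approx(
            100.0 + 2 * 4 + 2 * 4 * 5 / (33 - 5)
        )

    def test_lower_aicc_selected(self, rng):
        y, phases = _make_inputs(rng)
        glm = fit_glm(y, phases)
        gls = fit_gls(y, phases)
        rep = compare_models(glm, gls)
        expected = glm.kind if glm.aicc < gls.aicc else gls.kind
        assert rep["selected"] == expected
        assert rep["delta_aicc"] == pytest.approx(abs(glm.aicc - gls.aicc))

    def test_gamma_generated_data_prefers_glm(self, rng):
        wins = 0
        for _ in range(40):
            y, phases = _make_inputs(rng, shape=4.0)
            rep = compare_models(fit_glm(y, phases), fit_gls(y, phases))
            wins += rep["selected"] == "GLM-Gamma-log"
        assert wins > 20
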