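"""Frequentist GLM fitting and the coefficient-additivity predictor."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from stoppedsums.distributions import (
    MagnitudeModelSpec,
    negbin_from_prob_scale,
    sample_frequencies,
    sample_magnitudes,
)
from stoppedsums.glm import (
    ContractError,
    FitResult,
    FrequencyGLM,
    MagnitudeGLM,
    SumsGLM,
    fit_frequency_glm,
    fit_magnitude_model,
    fit_sums_glm,
    predict_sums_coefficients,
)


def _two_group_counts(J, a1, seed):
    rng = np.random.default_rng(seed)
    cond = (np.arange(J) >= J // 2).astype(float)
    mean = 10.0 * np.exp(a1 * cond)
    counts = rng.negative_binomial(10.0, 10.0 / (10.0 + mean))
    return counts, pd.DataFrame({"condition": cond})


class TestFrequencyGLM:
    def test_poisson_null_intercept_is_log_mean(self, rng):
        counts = rng.poisson(7.0, size=200)
        res = fit_frequency_glm(counts, family="poisson")
        assert res.coefficients["const"] == pytest.approx(
            math.log(counts.mean()), abs=1e-8)

    def test_negbin_recovers_effect(self):
        counts, X = _two_group_counts(4000, a1=0.3, seed=1)
        res = fit_frequency_glm(counts, X, family="negbin")
        est, se = res.coefficients["condition"], res.standard_errors["condition"]
        assert abs(est - 0.3) < 3 * se
        assert 0 <= res.wald_p["condition"] <= 1

    def test_poisson_fit_to_overdispersed_counts(self):
        # variance/mean = 1/(1-pi) = 2, visible as Pearson chi2/df ~ 2
        spec = negbin_from_prob_scale(0.5, 10.0)
        counts = sample_frequencies(spec, 4000, seed=2)
        model = FrequencyGLM(family="poisson").fit(None, counts)
        assert model.result_.extra["dispersion_stat"] == pytest.approx(2.0,
                                                                       abs=0.25)

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_frequency_glm(np.array([1.5, 2.0, 3.0]))

    def test_sklearn_protocol(self):
        model = FrequencyGLM(family="poisson")
        assert clone(model).get_params()["family"] == "poisson"
        model.set_params(family="negbin")
        assert model.family == "negbin"


class TestMagnitudeGLM:
    def test_null_single_obs_intercept(self, rng):
        z = rng.lognormal(6.0, 0.4, size=300)
        res = fit_magnitude_model(z, family="lognormal")
        # one observation per subject: the subject mean is the observation
        assert res.coefficients["const"] == pytest.approx(
            np.log(z).mean(), abs=0.02)

    def test_lognormal_recovers_effect(self):
        rng = np.random.default_rng(3)
        J, nobs = 1000, 8
        cond = np.repeat((np.arange(J) >= J // 2).astype(float), nobs)
        groups = np.repeat(np.arange(J), nobs)
        z = rng.lognormal(6.5 + 0.25 * cond, 0.447)
        res = fit_magnitude_model(z, pd.DataFrame({"condition": cond}),
                                  groups=groups, family="lognormal")
        est, se = res.coefficients["condition"], res.standard_errors["condition"]
        assert abs(est - 0.25) < 3 * se

    def test_lognormal_beats_exponential_on_lognormal_data(self, rng):
        z = rng.lognormal(6.81, 0.447, size=10_000)
        ln = fit_magnitude_model(z, family="lognormal")
        ex = fit_magnitude_model(z, family="exponential")
        assert ln.log_likelihood > ex.log_likelihood

    def test_mixed_mode_matches_fixed_effects(self):
        rng = np.random.default_rng(4)
        J, nobs = 150, 6
        cond = np.repeat((np.arange(J) >= J // 2).astype(float), nobs)
        groups = np.repeat(np.arange(J), nobs)
        z = rng.lognormal(6.5 + 0.3 * cond + rng.normal(0, 0.2, J)[groups],
                          0.4)
        X = pd.DataFrame({"condition": cond})
        agg = fit_magnitude_model(z, X, groups=groups, family="lognormal")
        mix = fit_magnitude_model(z, X, groups=groups, family="lognormal",
                                  method="mixed")
        assert abs(agg.coefficients["condition"]
                   - mix.coefficients["condition"]) < 0.1

    def test_non_positive_magnitudes_rejected(self):
        with pytest.raises(ValueError):
            fit_magnitude_model(np.array([10.0, 0.0, 5.0]))


class TestSumsGLM:
    def test_null_ln_intercept_is_mean_log(self, rng):
        s = rng.lognormal(9.0, 0.5, size=500)
        res = fit_sums_glm(s, family="LN")
        assert res.coefficients["const"] == pytest.approx(np.log(s).mean(),
                                                          abs=1e-8)

    def test_additivity_on_simulated_data(self):
        # alpha1 = 0.2 on counts, beta1 = 0.3 on magnitudes -> omega1 ~ 0.5
        rng = np.random.default_rng(5)
        J = 3000
        cond = (np.arange(J) >= J // 2).astype(float)
        mean = 10.0 * np.exp(0.2 * cond)
        counts = rng.negative_binomial(10.0, 10.0 / (10.0 + mean))
        sums = np.array([
            rng.lognormal(6.5 + 0.3 * c, 0.447, size=n).sum() if n else 0.0
            for n, c in zip(counts, cond)
        ])
        keep = counts > 0
        X = pd.DataFrame({"condition": cond[keep]})
        res = fit_sums_glm(sums[keep], X, family="LN")
        est, se = res.coefficients["condition"], res.standard_errors["condition"]
        assert abs(est - 0.5) < 3 * se

    def test_gg_and_ln_agree(self):
        rng = np.random.default_rng(6)
        J = 2000
        cond = (np.arange(J) >= J // 2).astype(float)
        counts = rng.negative_binomial(10.0, 0.5, size=J)
        sums = np.array([
            rng.gamma(4.0, 250.0 * math.exp(0.2 * c), size=n).sum() if n else 0.0
            for n, c in zip(counts, cond)
        ])
        keep = counts > 0
        X = pd.DataFrame({"condition": cond[keep]})
        ln = fit_sums_glm(sums[keep], X, family="LN")
        gg = fit_sums_glm(sums[keep], X, family="GG")
        width = 2 * (ln.standard_errors["condition"]
                     + gg.standard_errors["condition"])
        assert abs(ln.coefficients["condition"]
                   - gg.coefficients["condition"]) < width

    def test_zero_sums_rejected(self):
        with pytest.raises(ValueError):
            fit_sums_glm(np.array([100.0, 0.0]))


class TestAdditivityPredictor:
    def test_printed_worked_examples(self):
        # eye-tracker study: 0.135 + 0.111; decision study: 0.306 - 0.069
        assert predict_sums_coefficients(
            {"left": 0.135}, {"left": 0.111})["left"] == pytest.approx(0.246)
        assert predict_sums_coefficients(
            {"similarity": -0.069},
            {"similarity": 0.306})["similarity"] == pytest.approx(0.237)

    def test_zero_effects(self):
        assert predict_sums_coefficients({"x": 0.0}, {"x": 0.0})["x"] == 0.0

    def test_unshared_predictors_pass_through(self):
        out = predict_sums_coefficients({"x": 0.2}, {"y": 0.3})
        assert out == {"x": 0.2, "y": 0.3}

    def test_link_mismatch_rejected(self):
        bad = FitResult(coefficients={"x": 1.0}, standard_errors={"x": 0.1},
                        wald_p={"x": 0.5}, log_likelihood=0.0,
                        family="lognormal", link="identity", n_units=10)
        with pytest.raises(ContractError):
            predict_sums_coefficients(bad, {"x": 0.1})

    def test_wald_calibration_under_null(self):
        # ~5% two-sided rejections of a null condition effect
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 300
        for _ in range(reps):
            s = rng.lognormal(9.0, 0.5, size=60)
            X = pd.DataFrame({"condition": (np.arange(60) >= 30).astype(float)})
            res = fit_sums_glm(s, X, family="LN")
            rejections += res.wald_p["condition"] < 0.05
        assert 0.01 <= rejections / reps <= 0.12
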