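"""Bayesian hierarchical estimation: structure, sampler, DIC, prediction."""

import copy
import math
import warnings

import numpy as np
import pytest

from stoppedsums.bayes import (
    _split_rhat,
    build_model,
    compute_dic,
    extend_with_observation_predictors,
    posterior_predict,
    run_mcmc,
    HierarchicalStoppedSums,
)
from stoppedsums.data import FixtureConfig, RSSDataset, generate_fixture

warnings.filterwarnings("ignore", message="split R-hat")


@pytest.fixture(scope="module")
def gg_fit(gamma_dataset):
    model = build_model(gamma_dataset, ["condition"], family="GG", levels=2)
    result = run_mcmc(model, chains=2, burn_in=500, draws=500, seed=99)
    return model, result


@pytest.fixture(scope="module")
def gamma_dataset():
    cfg = FixtureConfig(
        J=120,
        alpha={"const": np.log(8.0), "condition": 0.15},
        beta={"const": 6.8, "condition": 0.10},
        mag_family="gamma", mag_params={"shape": 4.0},
        sigma_upsilon=0.15, seed=7,
    )
    return generate_fixture(cfg)


class TestBuildModel:
    def test_two_level_parameter_set(self, gamma_dataset):
        model = build_model(gamma_dataset, ["condition"], family="GG")
        names = model.parameter_names
        U = len(model.n_u)
        expected = {"alpha[const]", "alpha[condition]", "q", "beta[const]",
                    "beta[condition]", "sigma2_upsilon", "q_m"}
        assert expected <= set(names)
        assert sum(n.startswith("lambda[") for n in names) == U
        assert sum(n.startswith("mu[") for n in names) == U

    def test_three_level_round_intercepts(self):
        cfg = FixtureConfig(levels=3, J=20, rounds=4, seed=3,
                            alpha={"const": 2.0, "condition": 0.1},
                            beta={"const": 6.0, "condition": 0.1},
                            round_intercepts=[6.1, 6.0, 5.9, 5.8])
        ds = generate_fixture(cfg)
        model = build_model(ds, ["condition"], family="LN", levels=3)
        rounds = [n for n in model.m_names if n.startswith("round:")]
        assert len(rounds) == 4
        assert "condition" in model.m_names
        # frequency layer keeps a single coefficient vector, no round terms
        assert all(not n.startswith("round:") for n in model.f_names)

    def test_missing_column_rejected(self, gamma_dataset):
        with pytest.raises(ValueError, match="nope"):
            build_model(gamma_dataset, ["nope"], family="GG")

    def test_log_density_support(self, gamma_dataset):
        model = build_model(gamma_dataset, ["condition"], family="GG")
        U = len(model.n_u)
        point = {
            "alpha": [2.0, 0.1], "q": 5.0, "lam": np.full(U, 8.0),
            "beta": [6.8, 0.1], "sigma2_u": 0.05, "mu": np.full(U, 6.8),
            "q_m": 4.0,
        }
        finite = model.log_density(point)
        assert np.isfinite(finite)
        bad = dict(point)
        bad["lam"] = np.r_[-1.0, np.full(U - 1, 8.0)]
        assert model.log_density(bad) == -np.inf


class TestSampler:
    def test_gg_sums_location_identity(self, gg_fit):
        # per draw, mu_S = mu + log(lambda) holds exactly
        _, result = gg_fit
        err = np.abs(result.draws["mu_S"] - result.draws["mu"]
                     - np.log(result.draws["lam"]))
        assert err.max() < 1e-12

    def test_recovers_generating_coefficients(self, gg_fit):
        _, result = gg_fit
        s = result.summaries
        for par, truth in (("alpha[condition]", 0.15),
                           ("beta[condition]", 0.10)):
            est, sd = s.loc[par, "mean"], s.loc[par, "sd"]
            assert abs(est - truth) < 4 * sd

    def test_derived_omega_is_alpha_plus_beta(self, gg_fit):
        _, result = gg_fit
        k_o = result.model.s_names.index("condition")
        k_a = result.model.f_names.index("condition")
        k_b = result.model.m_names.index("condition")
        np.testing.assert_allclose(
            result.draws["omega"][..., k_o],
            result.draws["alpha"][..., k_a] + result.draws["beta"][..., k_b])

    def test_rhat_reported_and_reasonable(self, gg_fit):
        _, result = gg_fit
        assert "alpha[condition]" in result.rhat
        assert all(r > 0.8 for r in result.rhat.values() if np.isfinite(r))

    def test_chain_validation(self, gg_fit):
        model, _ = gg_fit
        with pytest.raises(ValueError):
            run_mcmc(model, chains=1, burn_in=10, draws=10, seed=0)

    def test_split_rhat_detects_divergent_chains(self):
        rng = np.random.default_rng(0)
        same = rng.normal(size=(2, 400))
        apart = np.stack([rng.normal(0, 1, 400), rng.normal(5, 1, 400)])
        assert _split_rhat(same) < 1.05
        assert _split_rhat(apart) > 2.0

    def test_estimator_facade(self, gamma_dataset):
        est = HierarchicalStoppedSums(design=["condition"], family="GG",
                                      chains=2, burn_in=150, draws=150, seed=5)
        est.set_params(draws=120)
        assert est.get_params()["draws"] == 120
        est.fit(gamma_dataset)
        assert "alpha[condition]" in est.summary_.index
        assert len(est.predict()) == len(est.model_.n_u)


class TestDIC:
    def test_deterministic_given_draws(self, gg_fit):
        _, result = gg_fit
        assert compute_dic(result, "sums") == compute_dic(result, "sums")

    def test_degenerate_posterior_has_zero_pd(self, gg_fit):
        _, result = gg_fit
        frozen = copy.copy(result)
        frozen.draws = {
            k: np.broadcast_to(v[:1, :1], v.shape).copy()
            for k, v in result.draws.items()}
        frozen.deviance_draws = {
            k: np.broadcast_to(v[:1, :1], v.shape).copy()
            for k, v in result.deviance_draws.items()}
        for sub in ("frequency", "magnitude", "sums"):
            Dbar, pD, dic = compute_dic(frozen, sub)
            assert pD == pytest.approx(0.0, abs=1e-6)
            assert dic == pytest.approx(Dbar, abs=1e-6)

    def test_true_effect_improves_dic(self, gamma_dataset):
        # DIC should prefer the model that carries the real magnitude effect
        effect = build_model(gamma_dataset, ["condition"], family="GG")
        null = build_model(gamma_dataset, [], family="GG")
        wins = 0
        for seed in (11, 12, 13):
            dic_e = compute_dic(run_mcmc(effect, 2, 300, 300, seed=seed),
                                "magnitude")[2]
            dic_n = compute_dic(run_mcmc(null, 2, 300, 300, seed=seed),
                                "magnitude")[2]
            wins += dic_e < dic_n
        assert wins >= 2


class TestPosteriorPrediction:
    def test_gg_predictions_track_observed_sums(self, gg_fit, gamma_dataset):
        _, result = gg_fit
        pred = posterior_predict(result, gamma_dataset)
        r2 = np.corrcoef(pred["S_observed"], pred["sums_pred"])[0, 1] ** 2
        assert r2 > 0.99

    def test_relabeling_invariance(self, gamma_dataset):
        perm = {f"s{j:05d}": f"s{(j * 7) % 120:05d}" for j in range(120)}
        frame = gamma_dataset.frame.copy()
        frame["subject"] = frame["subject"].map(perm)
        ds2 = RSSDataset(frame, subject_predictors=["condition"])
        m1 = build_model(gamma_dataset, ["condition"], family="GG")
        m2 = build_model(ds2, ["condition"], family="GG")
        r1 = run_mcmc(m1, 2, 200, 200, seed=31)
        r2 = run_mcmc(m2, 2, 200, 200, seed=31)
        p1 = posterior_predict(r1).sort_index()
        p2 = posterior_predict(r2).sort_index()
        # same subjects (new labels), same data: predictions agree in
        # distribution; per-unit observed columns align exactly
        assert set(p1["n_observed"]) == set(p2["n_observed"])
        assert p1["sums_pred"].mean() == pytest.approx(
            p2["sums_pred"].mean(), rel=0.02)

    def test_mismatched_dataset_rejected(self, gg_fit):
        _, result = gg_fit
        tiny = RSSDataset(
            {"subject": ["a"], "magnitude": [10.0]})
        with pytest.raises(ValueError):
            posterior_predict(result, tiny)


class TestObservationLevelExtension:
    def test_zero_w_matches_unextended_density(self, gamma_dataset):
        model = build_model(gamma_dataset, ["condition"], family="GG")
        ext = extend_with_observation_predictors(
            model, np.zeros((len(model.z), 1)), names=["w"])
        U = len(model.n_u)
        point = {
            "alpha": [2.0, 0.1], "q": 5.0, "lam": np.full(U, 8.0),
            "beta": [6.8, 0.1], "sigma2_u": 0.05, "mu": np.full(U, 6.8),
            "q_m": 4.0,
        }
        ext_point = dict(point, delta=np.zeros((U, 1)), eta_p=[0.0],
                         sigma_p=[0.5])
        base = model.log_density(point)
        # the extension's own priors are extra terms; the data likelihood
        # part must be identical when w == 0 and delta == 0
        pr = model.priors
        prior_extra = (
            -(pr.prec_a + 1) * math.log(0.25) - pr.prec_b / 0.25
            + U * (-0.5 * math.log(2 * math.pi * 0.25))
        )
        assert ext.log_density(ext_point) == pytest.approx(base + prior_extra)

    def test_misaligned_rows_rejected(self, gamma_dataset):
        model = build_model(gamma_dataset, ["condition"], family="GG")
        with pytest.raises(ValueError):
            extend_with_observation_predictors(model,
                                               np.zeros((7, 1)))

    def test_recovers_observation_effect(self):
        # obs-level predictor centered within subject, eta_p = 0.2
        cfg = FixtureConfig(J=150, alpha={"const": np.log(8.0)},
                            beta={"const": 6.8},
                            mag_family="lognormal",
                            mag_params={"sigma_log": 0.4}, seed=23)
        ds = generate_fixture(cfg)
        rng = np.random.default_rng(24)
        w = rng.normal(0.0, 1.0, size=(len(ds.frame), 1))
        # center within subject so the sums-layer totals stay near zero
        frame = ds.frame.copy()
        frame["_w"] = w[:, 0]
        frame["_w"] -= frame.groupby("subject")["_w"].transform("mean")
        w = frame["_w"].to_numpy()[:, None]
        frame["magnitude"] = frame["magnitude"] * np.exp(0.2 * w[:, 0])
        ds2 = RSSDataset(frame.drop(columns="_w"))
        model = build_model(ds2, [], family="LN")
        model = extend_with_observation_predictors(model, w, names=["diff"])
        result = run_mcmc(model, chains=2, burn_in=400, draws=400, seed=25)
        s = result.summaries
        est = s.loc["eta_p[diff]", "mean"]
        sd = s.loc["eta_p[diff]", "sd"]
        assert abs(est - 0.2) < 3 * sd
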