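"""Frequentist GLMs for the frequency, magnitude and sums models.

Estimators follow the scikit-learn protocol (``fit``, ``predict``,
``get_params``/``set_params``, trailing-underscore fitted attributes) and
delegate the actual maximum-likelihood machinery to statsmodels. All
three models use the log link, which is what makes the coefficient
bookkeeping work: if the frequency and magnitude models share a
predictor x_k with coefficients alpha_k and beta_k, the sums model's
coefficient for x_k is omega_k = alpha_k + beta_k
(``predict_sums_coefficients``).

The magnitude model honors the two-level structure (magnitudes nested in
subjects) by default through subject-level aggregation: the analysis
unit is the subject and the response is its mean magnitude, modeled on
the log scale (log-normal family) or through a log-link gamma GLM
(gamma/exponential families). A full random-intercept mixed fit on the
log magnitudes (``method="mixed"``, log-normal only) is an opt-in mode.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
import statsmodels.api as sm
from sklearn.base import BaseEstimator

__all__ = [
    "FitResult",
    "FrequencyGLM",
    "MagnitudeGLM",
    "SumsGLM",
    "fit_frequency_glm",
    "fit_magnitude_model",
    "fit_sums_glm",
    "predict_sums_coefficients",
]


class FitError(RuntimeError):
    """Maximum-likelihood fit failed (separation, non-convergence, ...)."""


class ContractError(ValueError):
    """Models do not satisfy the contract an operation requires."""


@dataclass
class FitResult:
    coefficients: dict
    standard_errors: dict
    wald_p: dict
    log_likelihood: float
    family: str
    link: str
    n_units: int
    extra: dict = None

    def __post_init__(self):
        if set(self.coefficients) != set(self.standard_errors):
            raise ValueError("coefficient and SE name sets must match")

    def to_frame(self) -> pd.DataFrame:
        names = list(self.coefficients)
        return pd.DataFrame(
            {
                "coefficient": names,
                "estimate": [self.coefficients[k] for k in names],
                "se": [self.standard_errors[k] for k in names],
                "wald_p": [self.wald_p[k] for k in names],
            }
        )


def _as_design(X, add_intercept=True):
    """DataFrame design matrix with a leading intercept column."""
    if X is None:
        X = pd.DataFrame(index=range(0))
    X = pd.DataFrame(X).copy()
    X.columns = [str(c) for c in X.columns]
    if add_intercept and "const" not in X.columns:
        X.insert(0, "const", 1.0)
    return X


def _wald_p(est, se):
    return 2.0 * stats.norm.sf(np.abs(est) / se)


def _result_from_params(params, bse, llf, family, link, n_units, extra=None):
    coefficients = {k: float(v) for k, v in params.items()}
    ses = {k: float(v) for k, v in bse.items()}
    pvals = {k: float(_wald_p(coefficients[k], ses[k])) for k in coefficients}
    return FitResult(
        coefficients=coefficients,
        standard_errors=ses,
        wald_p=pvals,
        log_likelihood=float(llf),
        family=family,
        link=link,
        n_units=int(n_units),
        extra=extra or {},
    )


class FrequencyGLM(BaseEstimator):
    """Log-link count GLM for the per-subject frequencies n_j.

    Parameters
    ----------
    family : {"negbin", "poisson"}
        "negbin" fits a negative binomial (NB2) with the dispersion
        estimated by ML jointly with the coefficients, the standard way
        to absorb over-dispersion; "poisson" constrains variance = mean.
    add_intercept : bool
        Prepend a constant column to the design.
    """

    def __init__(self, family: str = "negbin", add_intercept: bool = True):
        self.family = family
        self.add_intercept = add_intercept

    def fit(self, X, y):
        if self.family not in ("negbin", "poisson"):
            raise ValueError("family must be 'negbin' or 'poisson'")
        y = np.asarray(y, dtype=float)
        if np.any(y < 0) or not np.allclose(y, np.round(y)):
            raise ValueError("counts must be non-negative integers")
        Xd = _as_design(X if X is not None else np.empty((len(y), 0)),
                        self.add_intercept)
        if len(Xd) != len(y):
            raise ValueError("X and y lengths differ")
        if np.linalg.matrix_rank(Xd.to_numpy(dtype=float)) < Xd.shape[1]:
            raise FitError("design matrix is rank-deficient")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if self.family == "poisson":
                res = sm.GLM(y, Xd, family=sm.families.Poisson()).fit()
                params, bse, llf = res.params, res.bse, res.llf
                mu = np.asarray(res.fittedvalues)
                pearson = float(np.sum((y - mu) ** 2 / mu))
                extra = {
                    "dispersion_stat": pearson / max(len(y) - Xd.shape[1], 1),
                    "statsmodels": res,
                }
            else:
                model = sm.NegativeBinomial(y, Xd)
                res = model.fit(disp=0, maxiter=200)
                if not res.mle_retvals.get("converged", True):
                    raise FitError(
                        "negative binomial ML did not converge: "
                        f"{res.mle_retvals}"
                    )
                params, bse, llf = res.params, res.bse, res.llf
                extra = {"alpha": float(res.params.get("alpha", np.nan)),
                         "statsmodels": res}
        self.result_ = _result_from_params(
            params.drop(labels=["alpha"], errors="ignore"),
            bse.drop(labels=["alpha"], errors="ignore"),
            llf, self.family, "log", len(y), extra,
        )
        self.coefficients_ = self.result_.coefficients
        self.feature_names_ = [c for c in Xd.columns]
        return self

    def predict(self, X):
        Xd = _as_design(X, self.add_intercept)[self.feature_names_]
        b = np.array([self.coefficients_[k] for k in self.feature_names_])
        return np.exp(Xd.to_numpy(dtype=float) @ b)


class MagnitudeGLM(BaseEstimator):
    """Two-level log-link model for the positive magnitudes Z_ij.

    y holds observation-level magnitudes, ``groups`` the subject id per
    observation, and X one row of subject-level predictors per
    observation (constant within subject). With ``method="subject_means"``
    (default) subjects are the analysis unit; ``method="mixed"``
    (log-normal only) fits a random-intercept mixed model on log Z.
    """

    def __init__(self, family: str = "lognormal", method: str = "subject_means",
                 add_intercept: bool = True):
        self.family = family
        self.method = method
        self.add_intercept = add_intercept

    def fit(self, X, y, groups=None):
        if self.family not in ("lognormal", "gamma", "exponential"):
            raise ValueError("family must be lognormal, gamma or exponential")
        y = np.asarray(y, dtype=float)
        if np.any(y <= 0):
            raise ValueError("magnitudes must be strictly positive")
        if groups is None:
            groups = np.arange(len(y))
        groups = np.asarray(groups)
        Xd = _as_design(X, self.add_intercept)
        if len(Xd) != len(y) or len(groups) != len(y):
            raise ValueError("X, y and groups lengths differ")

        if self.method == "mixed":
            if self.family != "lognormal":
                raise ValueError("mixed fitting is available for lognormal only")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.MixedLM(np.log(y), Xd, groups=groups).fit(reml=False)
            params = res.fe_params
            bse = res.bse[params.index]
            self.result_ = _result_from_params(
                params, bse, res.llf, self.family, "log",
                len(np.unique(groups)), {"statsmodels": res},
            )
        else:
            df = Xd.copy()
            df["_y"] = y
            df["_g"] = groups
            agg = df.groupby("_g", sort=False).mean()
            # the subject-level response is the mean magnitude; the LN
            # model places the linear predictor on its log
            ys = (np.log(agg["_y"].to_numpy()) if self.family == "lognormal"
                  else agg["_y"].to_numpy())
            Xs = agg.drop(columns="_y")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if self.family == "lognormal":
                    res = sm.OLS(ys, Xs).fit()
                else:
                    res = sm.GLM(
                        ys, Xs,
                        family=sm.families.Gamma(link=sm.families.links.Log()),
                    ).fit()
            self.result_ = _result_from_params(
                res.params, res.bse, np.nan, self.family, "log", len(ys),
                {"statsmodels": res},
            )
        self.coefficients_ = self.result_.coefficients
        self.feature_names_ = [c for c in Xd.columns]
        # observation-level log-likelihood at the fitted obs-level locations,
        # so that families are comparable on the same data
        eta = Xd.to_numpy(dtype=float) @ np.array(
            [self.coefficients_[k] for k in Xd.columns]
        )
        self.result_.log_likelihood = self._obs_loglik(y, eta)
        return self

    def _obs_loglik(self, y, eta):
        if self.family == "lognormal":
            r = np.log(y) - eta
            s2 = float(np.mean(r**2))
            self.sigma_log_ = math.sqrt(s2)
            return float(np.sum(stats.norm.logpdf(np.log(y), eta, self.sigma_log_)
                                - np.log(y)))
        mu = np.exp(eta)
        if self.family == "exponential":
            return float(np.sum(-np.log(mu) - y / mu))

        # gamma: profile the shape k at the fitted means (rate k/mu)
        def nll(log_k):
            k = math.exp(log_k)
            return -float(
                np.sum(
                    k * np.log(k / mu)
                    - special.gammaln(k)
                    + (k - 1) * np.log(y)
                    - k * y / mu
                )
            )

        opt = optimize.minimize_scalar(nll, bounds=(-6, 12), method="bounded")
        self.shape_ = math.exp(opt.x)
        return -float(opt.fun)

    def predict(self, X):
        """Natural-scale mean E[Z] per row of subject-level predictors."""
        Xd = _as_design(X, self.add_intercept)[self.feature_names_]
        eta = Xd.to_numpy(dtype=float) @ np.array(
            [self.coefficients_[k] for k in self.feature_names_]
        )
        if self.family == "lognormal":
            return np.exp(eta + getattr(self, "sigma_log_", 0.0) ** 2 / 2.0)
        return np.exp(eta)


class SumsGLM(BaseEstimator):
    """Log-link GLM for the per-subject sums S_j.

    family "LN" models log S_j as Gaussian (linear model on the logs);
    family "GG" fits a gamma GLM with log link. Subjects with n_j = 0
    must already be excluded (their sum is 0 and log 0 is undefined).
    """

    def __init__(self, family: str = "LN", add_intercept: bool = True):
        self.family = family
        self.add_intercept = add_intercept

    def fit(self, X, y):
        if self.family not in ("LN", "GG"):
            raise ValueError("family must be 'LN' or 'GG'")
        y = np.asarray(y, dtype=float)
        if np.any(y <= 0):
            raise ValueError("sums must be strictly positive "
                             "(drop zero-count subjects first)")
        Xd = _as_design(X, self.add_intercept)
        if np.linalg.matrix_rank(Xd.to_numpy(dtype=float)) < Xd.shape[1]:
            raise FitError("design matrix is rank-deficient")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if self.family == "LN":
                res = sm.OLS(np.log(y), Xd).fit()
                r = np.log(y) - np.asarray(res.fittedvalues)
                self.sigma_log_ = float(np.sqrt(np.mean(r**2)))
                llf = float(
                    np.sum(
                        stats.norm.logpdf(np.log(y), np.asarray(res.fittedvalues),
                                          self.sigma_log_)
                        - np.log(y)
                    )
                )
            else:
                res = sm.GLM(
                    y, Xd, family=sm.families.Gamma(link=sm.families.links.Log())
                ).fit()
                llf = float(res.llf)
        self.result_ = _result_from_params(
            res.params, res.bse, llf, self.family, "log", len(y),
            {"statsmodels": res},
        )
        self.coefficients_ = self.result_.coefficients
        self.feature_names_ = [c for c in Xd.columns]
        return self

    def predict(self, X):
        Xd = _as_design(X, self.add_intercept)[self.feature_names_]
        eta = Xd.to_numpy(dtype=float) @ np.array(
            [self.coefficients_[k] for k in self.feature_names_]
        )
        if self.family == "LN":
            return np.exp(eta + getattr(self, "sigma_log_", 0.0) ** 2 / 2.0)
        return np.exp(eta)


# ---------------------------------------------------------------------------
# thin functional wrappers


def fit_frequency_glm(counts, X=None, family: str = "negbin") -> FitResult:
    return FrequencyGLM(family=family).fit(
        X if X is not None else np.empty((len(counts), 0)), counts
    ).result_


def fit_magnitude_model(magnitudes, X=None, groups=None,
                        family: str = "lognormal",
                        method: str = "subject_means") -> FitResult:
    if X is None:
        X = np.empty((len(magnitudes), 0))
    return MagnitudeGLM(family=family, method=method).fit(
        X, magnitudes, groups=groups
    ).result_


def fit_sums_glm(sums, X=None, family: str = "LN") -> FitResult:
    if X is None:
        X = np.empty((len(sums), 0))
    return SumsGLM(family=family).fit(X, sums).result_


def _coef_map(model) -> dict:
    if isinstance(model, FitResult):
        if model.link != "log":
            raise ContractError(
                "coefficient additivity requires log links in every model"
            )
        return dict(model.coefficients)
    return dict(model)


def predict_sums_coefficients(alpha, beta) -> dict:
    """Predicted sums-model coefficients omega_k = alpha_k + beta_k.

    With log links on the frequency, magnitude and sums models, a
    predictor shared by the frequency model (coefficient alpha_k) and
    the magnitude model (beta_k) acts on the sums with coefficient
    alpha_k + beta_k; a predictor present in only one model passes
    through unchanged. Inputs are name->coefficient mappings or
    :class:`FitResult` objects (which must use the log link).
    """
    a, b = _coef_map(alpha), _coef_map(beta)
    return {k: a.get(k, 0.0) + b.get(k, 0.0) for k in {*a, *b}}
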