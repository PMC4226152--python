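"""Bayesian hierarchical estimation of the integrated stopped-sums model.

The joint model ties the frequency, magnitude and sums layers together
and estimates them simultaneously:

frequency   n_u ~ Poisson(lambda_u),  lambda_u ~ Gamma(q, q/eta_u),
            log eta_u = X_f alpha                  (gamma-mixed Poisson,
            marginally negative binomial with over-dispersion 1/q)
magnitude   GG:  Z_i ~ Gamma(q_m, q_m e^{-mu_u}),  LN: log Z_i ~ N(mu_u, sigma2)
            mu_u ~ N(X_m beta, sigma2_u)
sums        GG:  S_u ~ Gamma(lambda_u q_m, lambda_u q_m e^{-mu_Su}),
                 mu_Su = mu_u + log lambda_u  (deterministic identity)
            LN:  log S_u ~ N(X_s omega, sigma2_s)  (free coefficients,
                 since the sum of log-normals is only approximately
                 log-normal)

"Units" are subjects for two-level data and subject-round cells for
three-level data; in the three-level case the frequency layer keeps one
coefficient vector while the magnitude and sums layers get per-round
intercepts. Priors are deliberately diffuse, BUGS-style: N(0, 100^2) on
coefficients, Gamma(0.01, 0.01) on the shapes q and q_m and on the
precisions of every variance component.

Sampling is blocked Gibbs with adaptive random-walk Metropolis for the
non-conjugate blocks (adaptation runs during burn-in only, so the kept
draws target the exact posterior). Convergence is monitored by split
R-hat with a warning above 1.05.

An observation-level predictor extension is available: the magnitude
location becomes mu_u + tau_i with tau_i = sum_p delta_{pu} w_{pi},
delta_{pu} ~ N(eta_p, sigma_p^2), and the sums location gains the
per-unit predictor totals sum_i tau_i.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "PriorConfig",
    "HierarchicalModelSpec",
    "PosteriorResult",
    "HierarchicalStoppedSums",
    "build_model",
    "run_mcmc",
    "compute_dic",
    "posterior_predict",
    "extend_with_observation_predictors",
]

class ConvergenceWarning(UserWarning):
    pass


class SamplerError(RuntimeError):
    pass


@dataclass
class PriorConfig:
    """Diffuse BUGS-style priors for every block of the joint model."""

    coef_sd: float = 100.0
    shape_a: float = 0.01
    shape_b: float = 0.01
    prec_a: float = 0.01
    prec_b: float = 0.01


@dataclass
class HierarchicalModelSpec:
    """A fully specified joint model over one dataset.

    Data enter as per-unit aggregates (counts, sums, log-sums) plus the
    observation-level magnitudes; designs are dense unit-level matrices.
    """

    family: str
    levels: int
    priors: PriorConfig
    # unit-level data
    unit_ids: np.ndarray
    n_u: np.ndarray
    S_u: np.ndarray
    # observation-level data
    z: np.ndarray
    unit_idx: np.ndarray
    # designs
    X_f: np.ndarray
    X_m: np.ndarray
    X_s: np.ndarray
    f_names: list
    m_names: list
    s_names: list
    # observation-level extension (optional)
    w: np.ndarray | None = None
    w_names: list | None = None
    # caches
    _agg: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.family not in ("LN", "GG"):
            raise ValueError("family must be 'LN' or 'GG'")
        U = len(self.n_u)
        logz = np.log(self.z) if len(self.z) else np.empty(0)
        self._agg = {
            "U": U,
            "Nobs": len(self.z),
            "logz": logz,
            "sumz": np.bincount(self.unit_idx, weights=self.z, minlength=U),
            "sumlogz": np.bincount(self.unit_idx, weights=logz, minlength=U),
            "sumlogz2": np.bincount(self.unit_idx, weights=logz**2, minlength=U),
            "pos": self.n_u > 0,
            "logS": np.where(self.S_u > 0, np.log(np.maximum(self.S_u, 1e-300)), 0.0),
        }
        if self.w is not None:
            P = self.w.shape[1]
            self._agg["wsum"] = np.vstack(
                [np.bincount(self.unit_idx, weights=self.w[:, p], minlength=U)
                 for p in range(P)]
            ).T  # (U, P)

    # -- parameter bookkeeping -------------------------------------------
    @property
    def parameter_names(self) -> list:
        U = self._agg["U"]
        names = [f"alpha[{c}]" for c in self.f_names] + ["q"]
        names += [f"lambda[{i}]" for i in range(U)]
        names += [f"beta[{c}]" for c in self.m_names] + ["sigma2_upsilon"]
        names += [f"mu[{i}]" for i in range(U)]
        if self.family == "LN":
            names += ["sigma2"]
            names += [f"omega[{c}]" for c in self.s_names] + ["sigma2_s"]
        else:
            names += ["q_m"]
        if self.w is not None:
            names += [f"eta[{c}]" for c in self.w_names]
            names += [f"sigma_p[{c}]" for c in self.w_names]
        return names

    def _tau_obs(self, delta):
        """Per-observation tau_i = sum_p delta[u(i), p] w_ip (0 if no extension)."""
        if self.w is None:
            return 0.0
        return np.einsum("ip,ip->i", self.w, delta[self.unit_idx])

    def _tau_unit(self, delta):
        """Per-unit sum_i tau_ij, the Eq.-style sums-layer term."""
        if self.w is None:
            return 0.0
        return np.einsum("up,up->u", self._agg["wsum"], delta)

    # -- joint log density -----------------------------------------------
    def log_density(self, params: dict) -> float:
        """Joint log posterior density (up to a constant) at a parameter point.

        Returns -inf outside the support (non-positive lambda, shapes or
        variances).
        """
        pr = self.priors
        a = self._agg
        alpha = np.asarray(params["alpha"], dtype=float)
        q = float(params["q"])
        lam = np.asarray(params["lam"], dtype=float)
        beta = np.asarray(params["beta"], dtype=float)
        s2u = float(params["sigma2_u"])
        mu = np.asarray(params["mu"], dtype=float)
        if q <= 0 or s2u <= 0 or np.any(lam <= 0):
            return -np.inf
        eta = np.exp(self.X_f @ alpha)
        lp = 0.0
        # priors
        lp += -0.5 * float(alpha @ alpha) / pr.coef_sd**2
        lp += -0.5 * float(beta @ beta) / pr.coef_sd**2
        lp += (pr.shape_a - 1) * math.log(q) - pr.shape_b * q
        lp += -(pr.prec_a + 1) * math.log(s2u) - pr.prec_b / s2u  # IG on s2u
        # frequency layer
        rate = q / eta
        lp += float(np.sum(q * np.log(rate) - gammaln(q)
                           + (q - 1) * np.log(lam) - rate * lam))
        lp += float(np.sum(self.n_u * np.log(lam) - lam - gammaln(self.n_u + 1)))
        # magnitude location layer
        ups = self.X_m @ beta
        lp += float(np.sum(-0.5 * np.log(2 * np.pi * s2u)
                           - 0.5 * (mu - ups) ** 2 / s2u))
        delta = params.get("delta")
        tau_i = self._tau_obs(delta) if delta is not None else 0.0
        T_u = self._tau_unit(delta) if delta is not None else 0.0
        pos = a["pos"]
        if self.family == "LN":
            s2 = float(params["sigma2"])
            omega = np.asarray(params["omega"], dtype=float)
            s2s = float(params["sigma2_s"])
            if s2 <= 0 or s2s <= 0:
                return -np.inf
            lp += -0.5 * float(omega @ omega) / pr.coef_sd**2
            lp += -(pr.prec_a + 1) * math.log(s2) - pr.prec_b / s2
            lp += -(pr.prec_a + 1) * math.log(s2s) - pr.prec_b / s2s
            loc = mu[self.unit_idx] + tau_i
            lp += float(np.sum(-0.5 * np.log(2 * np.pi * s2)
                               - 0.5 * (a["logz"] - loc) ** 2 / s2 - a["logz"]))
            muS = np.asarray(self.X_s @ omega + T_u)
            lp += float(np.sum(-0.5 * np.log(2 * np.pi * s2s)
                               - 0.5 * (a["logS"][pos] - muS[pos]) ** 2
                               / s2s - a["logS"][pos]))
        else:
            qm = float(params["q_m"])
            if qm <= 0:
                return -np.inf
            lp += (pr.shape_a - 1) * math.log(qm) - pr.shape_b * qm
            loc = mu[self.unit_idx] + tau_i
            b = qm * np.exp(-loc)
            lp += float(np.sum(qm * np.log(b) - gammaln(qm)
                               + (qm - 1) * a["logz"] - b * self.z))
            muS = mu + np.log(lam) + T_u
            shp = lam[pos] * qm
            rte = shp * np.exp(-muS[pos])
            lp += float(np.sum(shp * np.log(rte) - gammaln(shp)
                               + (shp - 1) * a["logS"][pos] - rte * self.S_u[pos]))
        if delta is not None:
            etap = np.asarray(params["eta_p"], dtype=float)
            sp = np.asarray(params["sigma_p"], dtype=float)
            if np.any(sp <= 0):
                return -np.inf
            lp += -0.5 * float(etap @ etap) / pr.coef_sd**2
            lp += float(np.sum(-(pr.prec_a + 1) * np.log(sp**2) - pr.prec_b / sp**2))
            lp += float(np.sum(-0.5 * np.log(2 * np.pi * sp**2)
                               - 0.5 * (delta - etap) ** 2 / sp**2))
        return lp

    # -- submodel deviances ----------------------------------------------
    def deviance_frequency(self, lam):
        return -2.0 * float(
            np.sum(self.n_u * np.log(lam) - lam - gammaln(self.n_u + 1))
        )

    def deviance_magnitude(self, mu, sigma2=None, q_m=None, delta=None):
        a = self._agg
        tau = self._tau_obs(delta) if (delta is not None and self.w is not None) else 0.0
        loc = mu[self.unit_idx] + tau
        if self.family == "LN":
            ll = np.sum(-0.5 * np.log(2 * np.pi * sigma2)
                        - 0.5 * (a["logz"] - loc) ** 2 / sigma2 - a["logz"])
        else:
            b = q_m * np.exp(-loc)
            ll = np.sum(q_m * np.log(b) - gammaln(q_m)
                        + (q_m - 1) * a["logz"] - b * self.z)
        return -2.0 * float(ll)

    def deviance_sums(self, lam, mu, omega=None, sigma2_s=None, q_m=None,
                      delta=None):
        a = self._agg
        pos = a["pos"]
        T = self._tau_unit(delta) if (delta is not None and self.w is not None) else 0.0
        if self.family == "LN":
            muS = self.X_s @ omega + T
            muS = np.asarray(muS)
            ll = np.sum(-0.5 * np.log(2 * np.pi * sigma2_s)
                        - 0.5 * (a["logS"][pos] - muS[pos]) ** 2 / sigma2_s
                        - a["logS"][pos])
        else:
            muS = mu + np.log(lam) + T
            shp = lam[pos] * q_m
            rte = shp * np.exp(-np.asarray(muS)[pos])
            ll = np.sum(shp * np.log(rte) - gammaln(shp)
                        + (shp - 1) * a["logS"][pos] - rte * self.S_u[pos])
        return -2.0 * float(ll)


# ---------------------------------------------------------------------------
# model construction


def _unit_frame(dataset, levels):
    """Unit-level table: one row per subject (2-level) or subject-round."""
    from .data import RSSDataset  # local import to avoid a cycle

    if not isinstance(dataset, RSSDataset):
        raise TypeError("dataset must be an RSSDataset")
    return dataset.unit_frame(levels=levels)


def build_model(dataset, design, family: str = "GG", levels: int = 2,
                priors: PriorConfig | None = None) -> HierarchicalModelSpec:
    """Assemble the joint hierarchical model for a dataset.

    ``design`` assigns unit-level predictor columns to layers: either a
    list (shared by the frequency and magnitude layers) or a dict with
    keys "frequency", "magnitude" and optionally "sums" (defaults to the
    union; used by the LN sums layer only). Three-level data (a round
    column) gives the magnitude and sums layers per-round intercepts
    while the frequency layer keeps a single coefficient vector.
    """
    priors = priors or PriorConfig()
    if levels not in (2, 3):
        raise ValueError("levels must be 2 or 3")
    if isinstance(design, (list, tuple)):
        design = {"frequency": list(design), "magnitude": list(design)}
    f_cols = list(design.get("frequency", []))
    m_cols = list(design.get("magnitude", []))
    s_cols = design.get("sums")

    units = _unit_frame(dataset, levels)
    missing = [c for c in {*f_cols, *m_cols, *(s_cols or [])}
               if c not in units.columns]
    if missing:
        raise ValueError(f"predictor columns not in dataset: {missing}")

    U = len(units)
    n_u = units["n"].to_numpy(dtype=np.int64)
    S_u = units["S"].to_numpy(dtype=float)

    X_f = np.column_stack([np.ones(U)] + [units[c].to_numpy(float) for c in f_cols])
    f_names = ["const"] + f_cols

    if levels == 3:
        rounds = units["_round"].to_numpy()
        r_levels = list(pd.unique(rounds))
        R = np.column_stack([(rounds == r).astype(float) for r in r_levels])
        r_names = [f"round:{r}" for r in r_levels]
        X_m = np.column_stack([R] + [units[c].to_numpy(float) for c in m_cols])
        m_names = r_names + m_cols
        s_cols = list(dict.fromkeys(f_cols + m_cols)) if s_cols is None else list(s_cols)
        X_s = np.column_stack([R] + [units[c].to_numpy(float) for c in s_cols])
        s_names = r_names + s_cols
    else:
        X_m = np.column_stack([np.ones(U)] + [units[c].to_numpy(float) for c in m_cols])
        m_names = ["const"] + m_cols
        s_cols = list(dict.fromkeys(f_cols + m_cols)) if s_cols is None else list(s_cols)
        X_s = np.column_stack([np.ones(U)] + [units[c].to_numpy(float) for c in s_cols])
        s_names = ["const"] + s_cols

    z, unit_idx = dataset.observations(levels=levels)
    return HierarchicalModelSpec(
        family=family, levels=levels, priors=priors,
        unit_ids=units.index.to_numpy(), n_u=n_u, S_u=S_u,
        z=z, unit_idx=unit_idx,
        X_f=X_f, X_m=X_m, X_s=X_s,
        f_names=f_names, m_names=m_names, s_names=s_names,
    )


def extend_with_observation_predictors(model: HierarchicalModelSpec, w,
                                       names=None) -> HierarchicalModelSpec:
    """Augment the magnitude layer with observation-level predictors.

    ``w`` is an (observations x P) matrix aligned row-for-row with the
    dataset's magnitude observations. Each unit gets random coefficients
    delta_{pu} ~ N(eta_p, sigma_p^2); the magnitude location becomes
    mu_u + sum_p delta_{pu} w_{pi}, and the sums location gains the
    per-unit totals sum_i tau_i.
    """
    w = np.atleast_2d(np.asarray(w, dtype=float))
    if w.shape[0] == 1 and len(model.z) != 1:
        w = w.T
    if w.shape[0] != len(model.z):
        raise ValueError(
            f"w has {w.shape[0]} rows but the dataset has {len(model.z)} "
            "magnitude observations"
        )
    names = list(names) if names is not None else [f"w{p}" for p in range(w.shape[1])]
    return HierarchicalModelSpec(
        family=model.family, levels=model.levels, priors=model.priors,
        unit_ids=model.unit_ids, n_u=model.n_u, S_u=model.S_u,
        z=model.z, unit_idx=model.unit_idx,
        X_f=model.X_f, X_m=model.X_m, X_s=model.X_s,
        f_names=model.f_names, m_names=model.m_names, s_names=model.s_names,
        w=w, w_names=names,
    )


# ---------------------------------------------------------------------------
# the sampler


class _ChainState:
    """Mutable state of one chain, with adaptive Metropolis step sizes."""

    def __init__(self, model: HierarchicalModelSpec, rng: np.random.Generator):
        self.rng = rng
        m, a = model, model._agg
        U = a["U"]
        self.lam = np.maximum(m.n_u.astype(float), 0.5)
        X = m.X_f
        self.alpha = np.linalg.lstsq(X, np.log(self.lam), rcond=None)[0]
        self.q = 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            mlz = np.where(a["pos"], a["sumlogz"] / np.maximum(m.n_u, 1), 0.0)
        self.mu = mlz.copy()
        self.beta = np.linalg.lstsq(m.X_m, self.mu, rcond=None)[0]
        self.mu[~a["pos"]] = (m.X_m @ self.beta)[~a["pos"]]
        resid = self.mu - m.X_m @ self.beta
        self.sigma2_u = max(float(np.var(resid)), 1e-3)
        if m.family == "LN":
            r2 = (a["sumlogz2"] - 2 * self.mu * a["sumlogz"]
                  + m.n_u * self.mu**2)
            self.sigma2 = max(float(r2.sum() / max(a["Nobs"], 1)), 1e-3)
            pos = a["pos"]
            self.omega = np.linalg.lstsq(m.X_s[pos], a["logS"][pos], rcond=None)[0]
            rs = a["logS"][pos] - m.X_s[pos] @ self.omega
            self.sigma2_s = max(float(np.var(rs)), 1e-3)
        else:
            mz = a["sumz"].sum() / max(a["Nobs"], 1)
            vz = max(float(np.var(m.z)), 1e-12) if len(m.z) > 1 else mz**2
            self.q_m = max(mz**2 / vz, 0.1)
        if m.w is not None:
            P = m.w.shape[1]
            self.delta = np.zeros((U, P))
            self.eta_p = np.zeros(P)
            self.sigma_p = np.full(P, 0.5)
        # chain over-dispersion: jitter the initial point
        self.alpha = self.alpha + rng.normal(0, 0.05, size=self.alpha.shape)
        self.beta = self.beta + rng.normal(0, 0.05, size=self.beta.shape)
        self.q *= math.exp(rng.normal(0, 0.2))
        # adaptive RW step sizes
        self.s_lam = np.full(U, 0.3)
        self.s_mu = np.full(U, 0.3)
        self.s_alpha = np.full(len(self.alpha), 0.1)
        self.s_q = 0.3
        self.s_qm = 0.2
        if m.w is not None:
            self.s_delta = np.full((U, m.w.shape[1]), 0.3)
        self.acc = {}

    # adaptation helper (Robbins-Monro toward 0.44 acceptance)
    @staticmethod
    def _adapt(scale, accepted, it):
        gain = min(0.25, 2.0 / math.sqrt(it + 10.0))
        return scale * np.exp(gain * (accepted - 0.44))


class _Sampler:
    def __init__(self, model: HierarchicalModelSpec):
        self.m = model
        self.a = model._agg

    # ---- conditional pieces (vectorized over units) ----
    def _lp_lam(self, t, st):
        """Conditional log density of log lambda per unit (vector)."""
        m, a = self.m, self.a
        eta = np.exp(m.X_f @ st.alpha)
        lam = np.exp(t)
        lp = st.q * t - (st.q / eta) * lam  # prior (with jacobian)
        lp += m.n_u * t - lam  # Poisson
        if m.family == "GG":
            pos = a["pos"]
            shp = lam * st.q_m
            muS = st.mu + t + self._T_unit(st)
            with np.errstate(invalid="ignore", divide="ignore"):
                ls = (shp * (np.log(shp) - muS) - gammaln(shp)
                      + (shp - 1) * a["logS"] - shp * np.exp(-muS) * m.S_u)
            lp = lp + np.where(pos, np.nan_to_num(ls, nan=-np.inf,
                                                  neginf=-np.inf), 0.0)
        return lp

    def _lp_mu(self, mu, st):
        """Conditional log density of mu per unit (GG only; LN is conjugate)."""
        m, a = self.m, self.a
        ups = m.X_m @ st.beta
        lp = -0.5 * (mu - ups) ** 2 / st.sigma2_u
        qm = st.q_m
        if m.w is None:
            sum_ze = a["sumz"] * np.exp(-mu)
            lp += -m.n_u * qm * mu - qm * sum_ze
        else:
            tau = m._tau_obs(st.delta)
            ze = np.bincount(m.unit_idx, weights=m.z * np.exp(-tau),
                             minlength=a["U"])
            lp += -m.n_u * qm * mu - qm * ze * np.exp(-mu)
        pos = a["pos"]
        shp = st.lam * qm
        muS = mu + np.log(st.lam) + self._T_unit(st)
        ls = -shp * muS - shp * np.exp(-muS) * m.S_u
        lp = lp + np.where(pos, ls, 0.0)
        return lp

    def _T_unit(self, st):
        return self.m._tau_unit(st.delta) if self.m.w is not None else 0.0

    def _lp_alpha_marginal(self, alpha, q, st):
        """log p(alpha | n, q) with lambda integrated out (negative binomial).

        Valid for the LN variant, where lambda's only children are the
        counts; used in a partially collapsed Gibbs step.
        """
        pr = self.m.priors
        n = self.m.n_u
        eta = np.exp(self.m.X_f @ alpha)
        ll = float(np.sum(gammaln(n + q) - gammaln(q) - gammaln(n + 1)
                          + q * (np.log(q) - np.log(q + eta))
                          + n * (np.log(eta) - np.log(q + eta))))
        return ll - 0.5 * float(alpha @ alpha) / pr.coef_sd**2

    def _lp_q_marginal(self, logq, st):
        pr = self.m.priors
        q = math.exp(logq)
        lp = self._lp_alpha_marginal(st.alpha, q, st)
        lp += 0.5 * float(st.alpha @ st.alpha) / pr.coef_sd**2  # drop alpha prior
        return lp + pr.shape_a * logq - pr.shape_b * q

    def _lp_alpha(self, alpha, st):
        pr = self.m.priors
        le = self.m.X_f @ alpha
        return (-st.q * float(le.sum())
                - st.q * float(np.sum(st.lam * np.exp(-le)))
                - 0.5 * float(alpha @ alpha) / pr.coef_sd**2)

    def _lp_q(self, logq, st):
        pr = self.m.priors
        q = math.exp(logq)
        eta = np.exp(self.m.X_f @ st.alpha)
        ll = float(np.sum(q * (np.log(q) - np.log(eta)) - gammaln(q)
                          + (q - 1) * np.log(st.lam) - (q / eta) * st.lam))
        return ll + pr.shape_a * logq - pr.shape_b * q

    def _lp_qm(self, logqm, st):
        m, a, pr = self.m, self.a, self.m.priors
        qm = math.exp(logqm)
        tau = m._tau_obs(st.delta) if m.w is not None else 0.0
        loc_sum = float(np.sum(m.n_u * st.mu)) + (float(np.sum(tau))
                                                  if m.w is not None else 0.0)
        if m.w is None:
            ze = float(np.sum(a["sumz"] * np.exp(-st.mu)))
        else:
            loc = st.mu[m.unit_idx] + tau
            ze = float(np.sum(m.z * np.exp(-loc)))
        ll = (a["Nobs"] * qm * math.log(qm) - qm * loc_sum
              - a["Nobs"] * gammaln(qm) + qm * float(np.sum(a["sumlogz"]))
              - qm * ze)
        pos = a["pos"]
        shp = st.lam[pos] * qm
        muS = (st.mu + np.log(st.lam) + self._T_unit(st))[pos]
        ll += float(np.sum(shp * (np.log(shp) - muS) - gammaln(shp)
                           + shp * a["logS"][pos]
                           - shp * np.exp(-muS) * m.S_u[pos]))
        return ll + pr.shape_a * logqm - pr.shape_b * qm

    # ---- one full iteration ----
    def step(self, st: _ChainState, it: int, adapt: bool):
        m, a, pr = self.m, self.a, self.m.priors
        rng = st.rng
        U = a["U"]

        if m.family == "LN":
            # partially collapsed frequency block: update alpha and q
            # against the lambda-marginalized (negative binomial)
            # likelihood, then redraw lambda conjugately
            for k in range(len(st.alpha)):
                cur = self._lp_alpha_marginal(st.alpha, st.q, st)
                prop_a = st.alpha.copy()
                prop_a[k] += st.s_alpha[k] * rng.normal()
                ok = (math.log(rng.random())
                      < self._lp_alpha_marginal(prop_a, st.q, st) - cur)
                if ok:
                    st.alpha = prop_a
                if adapt:
                    st.s_alpha[k] = st._adapt(st.s_alpha[k], float(ok), it)
            lq = math.log(st.q)
            prop = lq + st.s_q * rng.normal()
            ok = (math.log(rng.random())
                  < self._lp_q_marginal(prop, st) - self._lp_q_marginal(lq, st))
            if ok:
                st.q = math.exp(prop)
            if adapt:
                st.s_q = float(st._adapt(np.array(st.s_q), float(ok), it))
            eta = np.exp(m.X_f @ st.alpha)
            st.lam = rng.gamma(st.q + m.n_u, 1.0 / (st.q / eta + 1.0))
        else:
            # lambda (Metropolis; the sums layer blocks exact collapse)
            t = np.log(st.lam)
            cur = self._lp_lam(t, st)
            prop = t + st.s_lam * rng.standard_normal(U)
            new = self._lp_lam(prop, st)
            acc = np.log(rng.random(U)) < (new - cur)
            t = np.where(acc, prop, t)
            st.lam = np.exp(t)
            if adapt:
                st.s_lam = st._adapt(st.s_lam, acc.astype(float), it)

            # q (Metropolis on log q)
            lq = math.log(st.q)
            prop = lq + st.s_q * rng.normal()
            if math.log(rng.random()) < self._lp_q(prop, st) - self._lp_q(lq, st):
                st.q = math.exp(prop)
                if adapt:
                    st.s_q = float(st._adapt(np.array(st.s_q), 1.0, it))
            elif adapt:
                st.s_q = float(st._adapt(np.array(st.s_q), 0.0, it))

            # alpha (componentwise Metropolis)
            for k in range(len(st.alpha)):
                cur = self._lp_alpha(st.alpha, st)
                prop_a = st.alpha.copy()
                prop_a[k] += st.s_alpha[k] * rng.normal()
                ok = math.log(rng.random()) < self._lp_alpha(prop_a, st) - cur
                if ok:
                    st.alpha = prop_a
                if adapt:
                    st.s_alpha[k] = st._adapt(st.s_alpha[k], float(ok), it)

        # mu
        if m.family == "LN":
            ups = m.X_m @ st.beta
            if m.w is None:
                obs_sum = a["sumlogz"]
            else:
                tau = m._tau_obs(st.delta)
                obs_sum = np.bincount(m.unit_idx, weights=a["logz"] - tau,
                                      minlength=U)
            prec = 1.0 / st.sigma2_u + m.n_u / st.sigma2
            mean = (ups / st.sigma2_u + obs_sum / st.sigma2) / prec
            st.mu = mean + rng.standard_normal(U) / np.sqrt(prec)
        else:
            cur = self._lp_mu(st.mu, st)
            prop = st.mu + st.s_mu * rng.standard_normal(U)
            new = self._lp_mu(prop, st)
            acc = np.log(rng.random(U)) < (new - cur)
            st.mu = np.where(acc, prop, st.mu)
            if adapt:
                st.s_mu = st._adapt(st.s_mu, acc.astype(float), it)

        # beta | mu (conjugate Gaussian regression)
        st.beta = self._draw_coefs(m.X_m, st.mu, st.sigma2_u, rng)

        # sigma2_upsilon
        ssr = float(np.sum((st.mu - m.X_m @ st.beta) ** 2))
        st.sigma2_u = 1.0 / rng.gamma(pr.prec_a + U / 2.0,
                                      1.0 / (pr.prec_b + ssr / 2.0))

        if m.family == "LN":
            # sigma2 (magnitude log-scale variance)
            if m.w is None:
                ssr = float(np.sum(a["sumlogz2"] - 2 * st.mu * a["sumlogz"]
                                   + m.n_u * st.mu**2))
            else:
                loc = st.mu[m.unit_idx] + m._tau_obs(st.delta)
                ssr = float(np.sum((a["logz"] - loc) ** 2))
            st.sigma2 = 1.0 / rng.gamma(pr.prec_a + a["Nobs"] / 2.0,
                                        1.0 / (pr.prec_b + ssr / 2.0))
            # omega, sigma2_s (sums layer)
            pos = a["pos"]
            ylog = a["logS"][pos] - (self._T_unit(st)[pos] if m.w is not None
                                     else 0.0)
            st.omega = self._draw_coefs(m.X_s[pos], ylog, st.sigma2_s, rng)
            rs = ylog - m.X_s[pos] @ st.omega
            st.sigma2_s = 1.0 / rng.gamma(pr.prec_a + pos.sum() / 2.0,
                                          1.0 / (pr.prec_b
                                                 + float(np.sum(rs**2)) / 2.0))
        else:
            # q_m
            lqm = math.log(st.q_m)
            prop = lqm + st.s_qm * rng.normal()
            ok = math.log(rng.random()) < self._lp_qm(prop, st) - self._lp_qm(lqm, st)
            if ok:
                st.q_m = math.exp(prop)
            if adapt:
                st.s_qm = float(st._adapt(np.array(st.s_qm), float(ok), it))

        # observation-level extension
        if m.w is not None:
            self._step_extension(st, it, adapt)

    def _draw_coefs(self, X, y, s2, rng):
        pr = self.m.priors
        K = X.shape[1]
        A = X.T @ X / s2 + np.eye(K) / pr.coef_sd**2
        b = X.T @ y / s2
        L = np.linalg.cholesky(A)
        mean = np.linalg.solve(A, b)
        return mean + np.linalg.solve(L.T, rng.standard_normal(K))

    def _step_extension(self, st, it, adapt):
        m, a, pr = self.m, self.a, self.m.priors
        rng = st.rng
        U, P = st.delta.shape
        if m.family == "LN":
            # per-unit conjugate MVN update for delta_u
            resid = a["logz"] - st.mu[m.unit_idx]
            pos = a["pos"]
            ylogS = a["logS"] - m.X_s @ st.omega
            for u in range(U):
                sel = m.unit_idx == u
                Wu = m.w[sel]
                A = np.diag(1.0 / st.sigma_p**2) + Wu.T @ Wu / st.sigma2
                b = st.eta_p / st.sigma_p**2 + Wu.T @ resid[sel] / st.sigma2
                if pos[u]:
                    ws = a["wsum"][u]
                    A += np.outer(ws, ws) / st.sigma2_s
                    b += ws * ylogS[u] / st.sigma2_s
                L = np.linalg.cholesky(A)
                mean = np.linalg.solve(A, b)
                st.delta[u] = mean + np.linalg.solve(L.T, rng.standard_normal(P))
        else:
            # componentwise Metropolis per predictor column
            for p in range(P):
                cur_tau = m._tau_obs(st.delta)
                prop_col = st.delta[:, p] + st.s_delta[:, p] * rng.standard_normal(U)
                dcol = prop_col - st.delta[:, p]
                prop_tau = cur_tau + dcol[m.unit_idx] * m.w[:, p]
                lp_cur = self._lp_delta_col(st.delta[:, p], cur_tau, st, p)
                lp_new = self._lp_delta_col(prop_col, prop_tau, st, p)
                acc = np.log(rng.random(U)) < (lp_new - lp_cur)
                st.delta[acc, p] = prop_col[acc]
                if adapt:
                    st.s_delta[:, p] = st._adapt(st.s_delta[:, p],
                                                 acc.astype(float), it)
        # eta_p, sigma_p
        for p in range(P):
            prec = U / st.sigma_p[p] ** 2 + 1.0 / pr.coef_sd**2
            mean = st.delta[:, p].sum() / st.sigma_p[p] ** 2 / prec
            st.eta_p[p] = mean + rng.normal() / math.sqrt(prec)
            ssr = float(np.sum((st.delta[:, p] - st.eta_p[p]) ** 2))
            st.sigma_p[p] = math.sqrt(
                1.0 / rng.gamma(pr.prec_a + U / 2.0, 1.0 / (pr.prec_b + ssr / 2.0))
            )

    def _lp_delta_col(self, col, tau, st, p):
        """Per-unit conditional for one delta column (GG), vectorized."""
        m, a = self.m, self.a
        U = a["U"]
        qm = st.q_m
        loc = st.mu[m.unit_idx] + tau
        per_obs = -qm * tau - qm * m.z * np.exp(-loc)
        lp = np.bincount(m.unit_idx, weights=per_obs, minlength=U)
        delta_full = st.delta.copy()
        delta_full[:, p] = col
        T = m._tau_unit(delta_full)
        pos = a["pos"]
        shp = st.lam * qm
        muS = st.mu + np.log(st.lam) + T
        lp = lp + np.where(pos, -shp * muS - shp * np.exp(-muS) * m.S_u, 0.0)
        lp += -0.5 * (col - st.eta_p[p]) ** 2 / st.sigma_p[p] ** 2
        return lp


# ---------------------------------------------------------------------------
# results


@dataclass
class PosteriorResult:
    model: HierarchicalModelSpec
    draws: dict          # name -> (chains, draws) or (chains, draws, dim)
    summaries: pd.DataFrame
    rhat: dict
    deviance_draws: dict  # submodel -> (chains, draws)
    chains: int
    burn_in: int
    n_draws: int
    seed: object

    def coefficient_summary(self) -> pd.DataFrame:
        keep = self.summaries.index.str.match(r"(alpha|beta|omega|eta)\[")
        return self.summaries[keep]


def _split_rhat(x: np.ndarray) -> float:
    """Split R-hat over a (chains, draws) array."""
    c, n = x.shape
    half = n // 2
    if half < 2:
        return float("nan")
    parts = np.vstack([x[:, :half], x[:, half: 2 * half]])
    W = parts.var(axis=1, ddof=1).mean()
    B = half * parts.mean(axis=1).var(ddof=1)
    if W <= 0:
        return 1.0
    var_plus = (half - 1) / half * W + B / half
    return float(np.sqrt(var_plus / W))


def _derived_omega_gg(model, draws):
    """GG sums coefficients per draw: omega_k = alpha_k + beta_k."""
    out = {}
    for i, name in enumerate(model.s_names):
        a_part = b_part = 0.0
        if name in model.f_names:
            a_part = draws["alpha"][..., model.f_names.index(name)]
        elif name.startswith("round:") and "const" in model.f_names:
            a_part = draws["alpha"][..., model.f_names.index("const")]
        if name in model.m_names:
            b_part = draws["beta"][..., model.m_names.index(name)]
        out[name] = a_part + b_part
    return np.stack([out[n] for n in model.s_names], axis=-1)


def run_mcmc(model: HierarchicalModelSpec, chains: int = 2,
             burn_in: int = 5000, draws: int = 10_000,
             seed=None, thin: int = 1) -> PosteriorResult:
    """Sample the joint posterior by blocked Gibbs/adaptive Metropolis.

    Defaults (2 chains, 5000 burn-in) follow standard practice for this
    model class; reduce ``draws`` for quick exploration. A warning is
    raised if any monitored parameter has split R-hat above 1.05.
    """
    if chains < 2:
        raise ValueError("chains must be >= 2 (needed for R-hat)")
    if burn_in < 0 or draws < 1:
        raise ValueError("burn_in must be >= 0 and draws >= 1")
    ss = np.random.SeedSequence(seed if not isinstance(seed, np.random.SeedSequence)
                                else seed.entropy)
    sampler = _Sampler(model)
    U = model._agg["U"]
    kept = {
        "alpha": np.empty((chains, draws, len(model.f_names))),
        "q": np.empty((chains, draws)),
        "lam": np.empty((chains, draws, U)),
        "beta": np.empty((chains, draws, len(model.m_names))),
        "sigma2_upsilon": np.empty((chains, draws)),
        "mu": np.empty((chains, draws, U)),
    }
    if model.family == "LN":
        kept["sigma2"] = np.empty((chains, draws))
        kept["omega"] = np.empty((chains, draws, len(model.s_names)))
        kept["sigma2_s"] = np.empty((chains, draws))
    else:
        kept["q_m"] = np.empty((chains, draws))
    if model.w is not None:
        P = model.w.shape[1]
        kept["eta_p"] = np.empty((chains, draws, P))
        kept["sigma_p"] = np.empty((chains, draws, P))
        kept["delta"] = np.empty((chains, draws, U, P))
    dev = {k: np.empty((chains, draws)) for k in ("frequency", "magnitude", "sums")}

    for c, child in enumerate(ss.spawn(chains)):
        rng = np.random.default_rng(child)
        st = _ChainState(model, rng)
        try:
            for it in range(burn_in):
                sampler.step(st, it, adapt=True)
            for d in range(draws):
                for _ in range(thin):
                    sampler.step(st, burn_in + d, adapt=False)
                kept["alpha"][c, d] = st.alpha
                kept["q"][c, d] = st.q
                kept["lam"][c, d] = st.lam
                kept["beta"][c, d] = st.beta
                kept["sigma2_upsilon"][c, d] = st.sigma2_u
                kept["mu"][c, d] = st.mu
                if model.family == "LN":
                    kept["sigma2"][c, d] = st.sigma2
                    kept["omega"][c, d] = st.omega
                    kept["sigma2_s"][c, d] = st.sigma2_s
                    dev["magnitude"][c, d] = model.deviance_magnitude(
                        st.mu, sigma2=st.sigma2,
                        delta=getattr(st, "delta", None))
                    dev["sums"][c, d] = model.deviance_sums(
                        st.lam, st.mu, omega=st.omega, sigma2_s=st.sigma2_s,
                        delta=getattr(st, "delta", None))
                else:
                    kept["q_m"][c, d] = st.q_m
                    dev["magnitude"][c, d] = model.deviance_magnitude(
                        st.mu, q_m=st.q_m, delta=getattr(st, "delta", None))
                    dev["sums"][c, d] = model.deviance_sums(
                        st.lam, st.mu, q_m=st.q_m,
                        delta=getattr(st, "delta", None))
                dev["frequency"][c, d] = model.deviance_frequency(st.lam)
                if model.w is not None:
                    kept["eta_p"][c, d] = st.eta_p
                    kept["sigma_p"][c, d] = st.sigma_p
                    kept["delta"][c, d] = st.delta
        except FloatingPointError as exc:  # pragma: no cover
            raise SamplerError(f"numerical failure in chain {c}: {exc}") from exc

    if model.family == "GG":
        kept["omega"] = _derived_omega_gg(model, kept)
        kept["mu_S"] = kept["mu"] + np.log(kept["lam"])

    rows, rhat = [], {}
    named = {
        "alpha": model.f_names, "beta": model.m_names, "omega": model.s_names,
        "eta_p": model.w_names, "sigma_p": model.w_names,
    }
    monitored = [k for k in ("alpha", "q", "beta", "sigma2_upsilon", "sigma2",
                             "omega", "sigma2_s", "q_m", "eta_p", "sigma_p")
                 if k in kept]
    for key in monitored:
        arr = kept[key]
        labels = ([key] if arr.ndim == 2
                  else [f"{key}[{n}]" for n in named.get(key, range(arr.shape[-1]))])
        cols = arr[..., None] if arr.ndim == 2 else arr
        for j, lab in enumerate(labels):
            x = cols[:, :, j]
            r = _split_rhat(x)
            rhat[lab] = r
            flat = x.ravel()
            rows.append({
                "parameter": lab, "mean": flat.mean(), "sd": flat.std(ddof=1),
                "ci_lower": np.quantile(flat, 0.025),
                "ci_upper": np.quantile(flat, 0.975), "rhat": r,
            })
    summaries = pd.DataFrame(rows).set_index("parameter")
    bad = {k: v for k, v in rhat.items() if np.isfinite(v) and v > 1.05}
    if bad:
        warnings.warn(
            f"split R-hat above 1.05 for: {sorted(bad)} — consider a longer "
            "burn-in or more draws", ConvergenceWarning, stacklevel=2)

    return PosteriorResult(
        model=model, draws=kept, summaries=summaries, rhat=rhat,
        deviance_draws=dev, chains=chains, burn_in=burn_in,
        n_draws=draws, seed=seed,
    )


def compute_dic(result: PosteriorResult, submodel: str):
    """(Dbar, pD, DIC) for one submodel: frequency, magnitude or sums.

    Dbar is the posterior mean of -2 log likelihood; pD subtracts the
    deviance at the posterior means of the submodel's parameters;
    DIC = Dbar + pD.
    """
    if submodel not in ("frequency", "magnitude", "sums"):
        raise ValueError("submodel must be frequency, magnitude or sums")
    m, k = result.model, result.draws
    Dbar = float(result.deviance_draws[submodel].mean())
    lam = k["lam"].mean(axis=(0, 1))
    mu = k["mu"].mean(axis=(0, 1))
    delta = k["delta"].mean(axis=(0, 1)) if "delta" in k else None
    if submodel == "frequency":
        Dhat = m.deviance_frequency(lam)
    elif submodel == "magnitude":
        if m.family == "LN":
            Dhat = m.deviance_magnitude(mu, sigma2=float(k["sigma2"].mean()),
                                        delta=delta)
        else:
            Dhat = m.deviance_magnitude(mu, q_m=float(k["q_m"].mean()),
                                        delta=delta)
    else:
        if m.family == "LN":
            Dhat = m.deviance_sums(lam, mu, omega=k["omega"].mean(axis=(0, 1)),
                                   sigma2_s=float(k["sigma2_s"].mean()),
                                   delta=delta)
        else:
            Dhat = m.deviance_sums(lam, mu, q_m=float(k["q_m"].mean()),
                                   delta=delta)
    pD = Dbar - Dhat
    return Dbar, pD, Dbar + pD


def posterior_predict(result: PosteriorResult, dataset=None) -> pd.DataFrame:
    """Posterior-mean per-unit predictions of frequency, magnitude mean and sum.

    Predictions incorporate the unit-level random terms (lambda_u, mu_u).
    If ``dataset`` is given it must be the dataset the model was built
    from (checked by unit count).
    """
    m, k = result.model, result.draws
    if dataset is not None:
        units = dataset.unit_frame(levels=m.levels)
        if len(units) != len(m.n_u):
            raise ValueError("dataset does not match the fitted model")
    lam = k["lam"]
    mu = k["mu"]
    T = (np.einsum("up,cdup->cdu", m._agg["wsum"], k["delta"])
         if "delta" in k else 0.0)
    if m.family == "LN":
        s2 = k["sigma2"][..., None]
        mag = np.exp(mu + s2 / 2.0)
        muS = np.einsum("uk,cdk->cdu", m.X_s, k["omega"]) + T
        sums = np.exp(muS + k["sigma2_s"][..., None] / 2.0)
    else:
        mag = np.exp(mu)
        sums = lam * np.exp(mu + (T if np.ndim(T) else 0.0))
    return pd.DataFrame(
        {
            "unit": m.unit_ids,
            "n_observed": m.n_u,
            "S_observed": m.S_u,
            "frequency_pred": lam.mean(axis=(0, 1)),
            "magnitude_pred": mag.mean(axis=(0, 1)),
            "sums_pred": sums.mean(axis=(0, 1)),
        }
    ).set_index("unit")


# ---------------------------------------------------------------------------
# sklearn-style wrapper


class HierarchicalStoppedSums:
    """Estimator facade over build_model + run_mcmc + posterior_predict.

    Parameters mirror :func:`build_model` and :func:`run_mcmc`; after
    ``fit`` the posterior is in ``result_`` and the coefficient summary
    table in ``summary_``.
    """

    def __init__(self, design=None, family="GG", levels=2, priors=None,
                 chains=2, burn_in=5000, draws=10_000, seed=None):
        self.design = design
        self.family = family
        self.levels = levels
        self.priors = priors
        self.chains = chains
        self.burn_in = burn_in
        self.draws = draws
        self.seed = seed

    def get_params(self, deep=True):
        return {
            "design": self.design, "family": self.family, "levels": self.levels,
            "priors": self.priors, "chains": self.chains,
            "burn_in": self.burn_in, "draws": self.draws, "seed": self.seed,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, dataset, w=None, w_names=None):
        model = build_model(dataset, self.design or [], family=self.family,
                            levels=self.levels, priors=self.priors)
        if w is not None:
            model = extend_with_observation_predictors(model, w, names=w_names)
        self.model_ = model
        self.result_ = run_mcmc(model, chains=self.chains, burn_in=self.burn_in,
                                draws=self.draws, seed=self.seed)
        self.summary_ = self.result_.summaries
        return self

    def predict(self, dataset=None):
        return posterior_predict(self.result_, dataset)

    def dic(self, submodel):
        return compute_dic(self.result_, submodel)
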