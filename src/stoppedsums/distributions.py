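"""Frequency and magnitude distribution families for randomly stopped sums.

A randomly stopped sum is S = Z_1 + ... + Z_N: a random number N of
non-negative magnitudes Z. This module holds the two building blocks —
the *frequency* model for the count N and the *magnitude* model for the
individual Z — together with their parameterizations, samplers,
closed-form natural-scale moments, and the conditional-sum closure rules
(gamma magnitudes give gamma conditional sums; inverse-Gaussian
magnitudes give inverse-Gaussian conditional sums; log-normal magnitudes
have no closed-form conditional sum).

Conventions
-----------
* The negative binomial is stored in (event probability pi, scale phi),
  with mean ``theta = phi*pi/(1-pi)`` and variance
  ``omega_sq = phi*pi/(1-pi)**2``; converters to/from the
  (mean, dispersion) convention are provided.
* Gamma magnitudes are (shape, scale); the inverse Gaussian is
  (location theta = mean, shape kappa), so that n-fold convolution maps
  IG(theta, kappa) -> IG(n*theta, n**2*kappa).
* All linear predictors use the log link: a spec may carry coefficient
  names/values purely as provenance for fixture generation and fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "FrequencyModelSpec",
    "MagnitudeModelSpec",
    "ConditionalSumLaw",
    "negbin_from_prob_scale",
    "negbin_from_mean_dispersion",
    "sample_frequencies",
    "sample_magnitudes",
    "conditional_sum_law",
    "natural_moments",
]

FREQUENCY_FAMILIES = ("poisson", "negbin", "poisson_gamma", "poisson_lognormal")
MAGNITUDE_FAMILIES = ("exponential", "gamma", "lognormal", "invgauss")


class ParameterDomainError(ValueError):
    """A distribution parameter is outside its domain."""


class ConfigurationError(ValueError):
    """A spec is not fully parameterized for the requested operation."""


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class FrequencyModelSpec:
    """Distribution of the per-subject count N_j.

    Families:

    ``poisson``
        ``lam`` is the mean (and variance).
    ``negbin``
        event probability ``pi`` in (0, 1) and scale ``phi`` > 0; mean
        ``theta = phi*pi/(1-pi)``, variance ``omega_sq = phi*pi/(1-pi)**2``.
    ``poisson_gamma``
        Poisson rate mixed over Gamma(shape ``q``, rate ``q/eta``), so the
        mixing mean is ``eta``; the marginal count is negative binomial
        with mean ``eta`` and variance ``eta + eta**2/q``.
    ``poisson_lognormal``
        Poisson rate mixed over LogNormal(``mu_log``, ``sigma_log``);
        no closed-form pmf, moments by the tower rule.

    ``alpha``/``predictors`` optionally record log-link coefficients
    behind the location parameter (``log lambda_j = sum_k alpha_k x_kj``);
    they are provenance for fixture generation and fitting, not used by
    the samplers, which draw at the spec's own location.
    """

    family: str
    lam: float | None = None
    pi: float | None = None
    phi: float | None = None
    q: float | None = None
    eta: float | None = None
    mu_log: float | None = None
    sigma_log: float | None = None
    alpha: Sequence[float] | None = None
    predictors: Sequence[str] | None = None
    link: str = "log"

    def __post_init__(self):
        if self.family not in FREQUENCY_FAMILIES:
            raise ParameterDomainError(
                f"unknown frequency family {self.family!r}; "
                f"choose one of {FREQUENCY_FAMILIES}"
            )
        self._validate()

    def _validate(self):
        f = self.family
        if f == "poisson":
            if self.lam is None or self.lam < 0:
                raise ParameterDomainError("poisson requires lam >= 0")
        elif f == "negbin":
            if self.pi is None or not (0 < self.pi < 1):
                raise ParameterDomainError("negbin requires 0 < pi < 1")
            if self.phi is None or self.phi <= 0:
                raise ParameterDomainError("negbin requires phi > 0")
        elif f == "poisson_gamma":
            if self.q is None or self.q <= 0 or self.eta is None or self.eta <= 0:
                raise ParameterDomainError("poisson_gamma requires q > 0 and eta > 0")
        elif f == "poisson_lognormal":
            if self.mu_log is None or self.sigma_log is None or self.sigma_log <= 0:
                raise ParameterDomainError(
                    "poisson_lognormal requires mu_log and sigma_log > 0"
                )

    # -- negbin identities ------------------------------------------------
    @property
    def theta(self) -> float:
        """Expected count; for negbin, theta = phi*pi/(1-pi)."""
        return self.mean

    @property
    def omega_sq(self) -> float:
        """Count variance; for negbin, omega_sq = phi*pi/(1-pi)**2."""
        return self.variance

    @property
    def mean(self) -> float:
        f = self.family
        if f == "poisson":
            return float(self.lam)
        if f == "negbin":
            return float(self.phi * self.pi / (1.0 - self.pi))
        if f == "poisson_gamma":
            return float(self.eta)
        # poisson_lognormal: E[N] = E[lambda]
        return float(math.exp(self.mu_log + self.sigma_log**2 / 2.0))

    @property
    def variance(self) -> float:
        f = self.family
        if f == "poisson":
            return float(self.lam)
        if f == "negbin":
            return float(self.phi * self.pi / (1.0 - self.pi) ** 2)
        if f == "poisson_gamma":
            return float(self.eta + self.eta**2 / self.q)
        m = self.mean
        v_lam = (math.exp(self.sigma_log**2) - 1.0) * m**2
        return float(m + v_lam)

    def pmf(self, n) -> np.ndarray:
        """P(N = n); vectorized. poisson_lognormal has no closed form."""
        n = np.asarray(n)
        f = self.family
        if f == "poisson":
            return stats.poisson.pmf(n, self.lam)
        if f == "negbin":
            # numpy/scipy convention: successes phi, success prob 1-pi
            return stats.nbinom.pmf(n, self.phi, 1.0 - self.pi)
        if f == "poisson_gamma":
            # marginal is negbin with size q and mean eta
            p = self.q / (self.q + self.eta)
            return stats.nbinom.pmf(n, self.q, p)
        raise ConfigurationError("poisson_lognormal has no closed-form pmf")

    def to_dict(self) -> dict:
        d = {k: v for k, v in asdict(self).items() if v is not None}
        d["kind"] = "frequency"
        if d.get("alpha") is not None:
            d["alpha"] = list(d["alpha"])
        if d.get("predictors") is not None:
            d["predictors"] = list(d["predictors"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FrequencyModelSpec":
        d = {k: v for k, v in d.items() if k != "kind"}
        return cls(**d)


@dataclass
class MagnitudeModelSpec:
    """Distribution of the individual positive magnitudes Z_ij.

    Families (all with log link on the location):

    ``exponential``  mean ``mean`` (SD equals the mean).
    ``gamma``        (``shape``, ``scale``); mean shape*scale, SD sqrt(shape)*scale.
    ``lognormal``    log-scale mean ``mu_log`` and SD ``sigma_log``.
    ``invgauss``     location ``ig_theta`` (= mean) and shape ``ig_kappa``;
                     variance ``ig_theta**3 / ig_kappa``.

    ``beta``/``predictors`` optionally record log-link fixed coefficients
    on the location; ``sigma_u`` records the SD of an additive Gaussian
    noise term on the link scale, and ``sigma_eps`` the SD of random
    coefficient deviations — provenance fields used by fixture
    generation and the hierarchical estimator.
    """

    family: str
    mean_: float | None = None
    shape: float | None = None
    scale: float | None = None
    mu_log: float | None = None
    sigma_log: float | None = None
    ig_theta: float | None = None
    ig_kappa: float | None = None
    beta: Sequence[float] | None = None
    predictors: Sequence[str] | None = None
    sigma_u: float = 0.0
    sigma_eps: float = 0.0
    link: str = "log"

    def __post_init__(self):
        if self.family not in MAGNITUDE_FAMILIES:
            raise ParameterDomainError(
                f"unknown magnitude family {self.family!r}; "
                f"choose one of {MAGNITUDE_FAMILIES}"
            )
        self._validate()

    def _validate(self):
        f = self.family
        if f == "exponential":
            if self.mean_ is None or self.mean_ <= 0:
                raise ParameterDomainError("exponential requires mean > 0")
        elif f == "gamma":
            if (
                self.shape is None
                or self.shape <= 0
                or self.scale is None
                or self.scale <= 0
            ):
                raise ParameterDomainError("gamma requires shape > 0 and scale > 0")
        elif f == "lognormal":
            if self.mu_log is None or self.sigma_log is None or self.sigma_log <= 0:
                raise ParameterDomainError(
                    "lognormal requires mu_log and sigma_log > 0"
                )
        elif f == "invgauss":
            if (
                self.ig_theta is None
                or self.ig_theta <= 0
                or self.ig_kappa is None
                or self.ig_kappa <= 0
            ):
                raise ParameterDomainError("invgauss requires ig_theta, ig_kappa > 0")

    @property
    def mean(self) -> float:
        f = self.family
        if f == "exponential":
            return float(self.mean_)
        if f == "gamma":
            return float(self.shape * self.scale)
        if f == "lognormal":
            return float(math.exp(self.mu_log + self.sigma_log**2 / 2.0))
        return float(self.ig_theta)

    @property
    def sd(self) -> float:
        f = self.family
        if f == "exponential":
            return float(self.mean_)
        if f == "gamma":
            return float(math.sqrt(self.shape) * self.scale)
        if f == "lognormal":
            return float(
                self.mean * math.sqrt(math.exp(self.sigma_log**2) - 1.0)
            )
        return float(math.sqrt(self.ig_theta**3 / self.ig_kappa))

    def to_dict(self) -> dict:
        d = {k: v for k, v in asdict(self).items() if v is not None}
        d["kind"] = "magnitude"
        if d.get("beta") is not None:
            d["beta"] = list(d["beta"])
        if d.get("predictors") is not None:
            d["predictors"] = list(d["predictors"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MagnitudeModelSpec":
        d = {k: v for k, v in d.items() if k != "kind"}
        return cls(**d)


@dataclass
class ConditionalSumLaw:
    """Law of S = Z_1 + ... + Z_n for fixed n, when it has a closed form.

    family ``gamma``:    parameters (shape, scale)
    family ``invgauss``: parameters (theta, kappa)
    family ``none``:     no closed form (log-normal magnitudes)
    """

    family: str
    parameters: dict = field(default_factory=dict)
    n: int = 1

    def frozen(self):
        """The scipy frozen distribution of this law (family != 'none')."""
        if self.family == "gamma":
            return stats.gamma(self.parameters["shape"], scale=self.parameters["scale"])
        if self.family == "invgauss":
            theta, kappa = self.parameters["theta"], self.parameters["kappa"]
            # scipy invgauss(mu, scale): mean mu*scale, shape param = scale
            return stats.invgauss(theta / kappa, scale=kappa)
        raise ConfigurationError("no closed-form law for this magnitude family")


# ---------------------------------------------------------------------------
# operations


def negbin_from_prob_scale(pi: float, phi: float) -> FrequencyModelSpec:
    """Negative binomial frequency spec from event probability and scale.

    Mean theta = phi*pi/(1-pi), variance omega_sq = phi*pi/(1-pi)**2, so the
    variance/mean ratio is 1/(1-pi) > 1 (over-dispersion) for any valid pi.
    """
    if not (0.0 < pi < 1.0):
        raise ParameterDomainError(f"pi must lie in (0, 1), got {pi}")
    if phi <= 0.0:
        raise ParameterDomainError(f"phi must be positive, got {phi}")
    return FrequencyModelSpec(family="negbin", pi=pi, phi=phi)


def negbin_from_mean_dispersion(theta: float, phi: float) -> FrequencyModelSpec:
    """Negative binomial spec from mean theta and scale phi (pi = theta/(phi+theta))."""
    if theta <= 0 or phi <= 0:
        raise ParameterDomainError("theta and phi must be positive")
    return FrequencyModelSpec(family="negbin", pi=theta / (phi + theta), phi=phi)


def sample_frequencies(spec: FrequencyModelSpec, J: int, seed=None) -> np.ndarray:
    """Draw J counts n_j from the frequency model (step 1 of the simulator)."""
    if J < 1:
        raise ConfigurationError(f"J must be >= 1, got {J}")
    rng = _rng(seed)
    f = spec.family
    if f == "poisson":
        return rng.poisson(spec.lam, size=J)
    if f == "negbin":
        return rng.negative_binomial(spec.phi, 1.0 - spec.pi, size=J)
    if f == "poisson_gamma":
        lam = rng.gamma(spec.q, spec.eta / spec.q, size=J)
        return rng.poisson(lam)
    lam = rng.lognormal(spec.mu_log, spec.sigma_log, size=J)
    return rng.poisson(lam)


def sample_magnitudes(spec: MagnitudeModelSpec, n: int, seed=None) -> np.ndarray:
    """Draw n positive magnitudes Z (step 2 of the simulator); n=0 gives []."""
    if n < 0:
        raise ConfigurationError(f"n must be >= 0, got {n}")
    rng = _rng(seed)
    if n == 0:
        return np.empty(0)
    f = spec.family
    if f == "exponential":
        return rng.exponential(spec.mean_, size=n)
    if f == "gamma":
        return rng.gamma(spec.shape, spec.scale, size=n)
    if f == "lognormal":
        return rng.lognormal(spec.mu_log, spec.sigma_log, size=n)
    return rng.wald(spec.ig_theta, spec.ig_kappa, size=n)


def conditional_sum_law(spec: MagnitudeModelSpec, n: int) -> ConditionalSumLaw:
    """Closure law of the sum of n i.i.d. magnitudes.

    gamma(shape, scale) sums to gamma(n*shape, scale); an exponential with
    mean m is gamma(1, m) so sums to gamma(n, m); IG(theta, kappa) sums to
    IG(n*theta, n**2*kappa); the log-normal has no closed form.
    """
    if n < 1:
        raise ConfigurationError(f"n must be >= 1, got {n}")
    f = spec.family
    if f == "gamma":
        return ConditionalSumLaw(
            "gamma", {"shape": n * spec.shape, "scale": spec.scale}, n=n
        )
    if f == "exponential":
        return ConditionalSumLaw("gamma", {"shape": float(n), "scale": spec.mean_}, n=n)
    if f == "invgauss":
        return ConditionalSumLaw(
            "invgauss", {"theta": n * spec.ig_theta, "kappa": n**2 * spec.ig_kappa}, n=n
        )
    return ConditionalSumLaw("none", {}, n=n)


def natural_moments(spec) -> tuple[float, float]:
    """Closed-form natural-scale (mean, sd) of a frequency or magnitude spec."""
    if isinstance(spec, FrequencyModelSpec):
        return spec.mean, math.sqrt(spec.variance)
    if isinstance(spec, MagnitudeModelSpec):
        return spec.mean, spec.sd
    raise TypeError(f"expected a frequency or magnitude spec, got {type(spec)!r}")


def spec_from_dict(d: dict):
    """Rebuild a spec from its serialized dict (see ``to_dict``)."""
    kind = d.get("kind")
    if kind == "frequency" or d.get("family") in FREQUENCY_FAMILIES:
        return FrequencyModelSpec.from_dict(d)
    if kind == "magnitude" or d.get("family") in MAGNITUDE_FAMILIES:
        return MagnitudeModelSpec.from_dict(d)
    raise ConfigurationError(f"cannot interpret spec dict: {d!r}")
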