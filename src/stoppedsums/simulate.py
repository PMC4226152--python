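"""Simulation approximation of the sums distribution F_S and bootstrap GLMs.

The simulator realizes the three-step generative loop: draw a count n_j
per subject, draw n_j magnitudes, and sum them; repeating the loop
builds an empirical approximation of the compound (randomly stopped
sums) distribution. The same replicates drive a parametric bootstrap of
the sums-GLM coefficients: each replicate's simulated per-subject sums
are fit with a log-link GLM (log-normal or gamma), and the replicate
coefficients give means, medians and percentile intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .distributions import (
    FrequencyModelSpec,
    MagnitudeModelSpec,
    sample_frequencies,
    sample_magnitudes,
)

__all__ = [
    "SimulationResult",
    "SumsSummary",
    "BootstrapCoefficients",
    "simulate_sums",
    "sums_summary",
    "bootstrap_sums_glm",
]

logger = logging.getLogger(__name__)


@dataclass
class SimulationResult:
    """runs x J matrix of simulated sums, with the drawn counts alongside."""

    sums_matrix: np.ndarray
    counts_matrix: np.ndarray
    runs: int
    seed: object
    freq_spec: FrequencyModelSpec = None
    mag_spec: MagnitudeModelSpec = None

    @property
    def J(self) -> int:
        return self.sums_matrix.shape[1]


@dataclass
class SumsSummary:
    mean: float
    sd: float
    q25: float
    q50: float
    q75: float
    _values: np.ndarray = field(repr=False, default=None)

    def quantile(self, q):
        """Arbitrary quantile of the pooled simulated sums (monotone in q)."""
        return np.quantile(self._values, q)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "statistic": ["mean", "sd", "q25", "q50", "q75"],
                "value": [self.mean, self.sd, self.q25, self.q50, self.q75],
            }
        )


@dataclass
class BootstrapCoefficients:
    """Per-replicate fitted sums-GLM coefficients and their summaries."""

    draws: np.ndarray  # (effective runs, n_coef)
    names: list
    mean: np.ndarray
    median: np.ndarray
    ci_level: float
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    runs_requested: int
    runs_effective: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coefficient": self.names,
                "mean": self.mean,
                "median": self.median,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            }
        )


def _draw_replicates(freq_specs, mag_specs, J, runs, rng):
    """Vectorized draws: (runs, J) counts and sums for per-subject specs.

    freq_specs/mag_specs are length-J sequences (one spec per subject);
    subjects sharing a spec are drawn in one batch.
    """
    counts = np.empty((runs, J), dtype=np.int64)
    for j, spec in enumerate(freq_specs):
        counts[:, j] = sample_frequencies(spec, runs, rng).reshape(runs)
    sums = np.zeros((runs, J))
    for j, spec in enumerate(mag_specs):
        total = int(counts[:, j].sum())
        z = sample_magnitudes(spec, total, rng)
        # per-run segment sums for subject j; trailing zero-count runs
        # would index past the end, and their slots are zeroed below
        edges = np.minimum(np.concatenate([[0], np.cumsum(counts[:, j])[:-1]]),
                           max(total - 1, 0))
        sums[:, j] = np.add.reduceat(z, edges) if total else 0.0
        sums[counts[:, j] == 0, j] = 0.0
    return counts, sums


def simulate_sums(
    freq_spec: FrequencyModelSpec,
    mag_spec: MagnitudeModelSpec,
    J: int,
    runs: int = 10_000,
    seed=None,
) -> SimulationResult:
    """Approximate the sums distribution by the three-step simulation.

    Each of ``runs`` replicates draws J counts n_j, then n_j magnitudes per
    subject, and records the J sums. 10,000-20,000 runs give stable results.
    """
    if J < 1 or runs < 1:
        raise ValueError("J and runs must be >= 1")
    rng = np.random.default_rng(seed)
    counts, sums = _draw_replicates([freq_spec] * J, [mag_spec] * J, J, runs, rng)
    return SimulationResult(
        sums_matrix=sums,
        counts_matrix=counts,
        runs=runs,
        seed=seed,
        freq_spec=freq_spec,
        mag_spec=mag_spec,
    )


def sums_summary(result: SimulationResult) -> SumsSummary:
    """Mean, SD and quartiles of the pooled simulated sums."""
    v = np.asarray(result.sums_matrix).ravel()
    if v.size == 0:
        raise ValueError("empty simulation result")
    q25, q50, q75 = np.quantile(v, [0.25, 0.50, 0.75])
    return SumsSummary(
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)) if v.size > 1 else 0.0,
        q25=float(q25),
        q50=float(q50),
        q75=float(q75),
        _values=v,
    )


def _fit_one(sums, X, family):
    """Log-link sums GLM on one replicate; LN = OLS on log sums, GG = gamma GLM."""
    if family == "LN":
        res = sm.OLS(np.log(sums), X).fit()
        return res.params
    res = sm.GLM(sums, X, family=sm.families.Gamma(link=sm.families.links.Log())).fit()
    return res.params


def bootstrap_sums_glm(
    freq_specs,
    mag_specs,
    design,
    runs: int = 10_000,
    family: str = "LN",
    seed=None,
    ci_level: float = 0.95,
) -> BootstrapCoefficients:
    """Parametric bootstrap of sums-GLM coefficients.

    ``design`` is a J-row matrix/DataFrame of subject-level predictors (an
    intercept column is prepended if absent). ``freq_specs``/``mag_specs``
    give each subject's generating distributions, fixed at their supplied
    values across replicates. Per replicate, all subjects' sums are
    simulated, subjects with n_j = 0 are dropped (log 0 undefined), and
    the log-link sums GLM is fit; coefficient draws are summarized by
    mean, median and the percentile interval.
    """
    if family not in ("LN", "GG"):
        raise ValueError("family must be 'LN' or 'GG'")
    X = pd.DataFrame(design).copy()
    J = len(X)
    if len(freq_specs) != J or len(mag_specs) != J:
        raise ValueError("freq_specs, mag_specs and design must align by subject")
    if "const" not in X.columns and (
            X.shape[1] == 0 or not (X.iloc[:, 0] == 1).all()):
        X.insert(0, "const", 1.0)
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank-deficient")
    non_const = Xv[:, 1:]
    if non_const.size and any(
        np.unique(non_const[:, k]).size < 2 for k in range(non_const.shape[1])
    ):
        raise np.linalg.LinAlgError(
            "each non-intercept predictor needs >= 2 distinct design rows"
        )

    rng = np.random.default_rng(seed)
    counts, sums = _draw_replicates(freq_specs, mag_specs, J, runs, rng)

    draws = []
    skipped = 0
    for r in range(runs):
        keep = counts[r] > 0
        if keep.sum() < Xv.shape[1]:
            skipped += 1
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                draws.append(np.asarray(_fit_one(sums[r, keep], Xv[keep], family)))
        except Exception:  # non-convergent replicate: skip and log
            skipped += 1
    if skipped:
        logger.warning("bootstrap_sums_glm: skipped %d of %d replicates", skipped, runs)
    if not draws:
        raise RuntimeError("no replicate produced a successful fit")
    D = np.vstack(draws)
    lo, hi = (1 - ci_level) / 2, 1 - (1 - ci_level) / 2
    return BootstrapCoefficients(
        draws=D,
        names=names,
        mean=D.mean(axis=0),
        median=np.median(D, axis=0),
        ci_level=ci_level,
        ci_lower=np.quantile(D, lo, axis=0),
        ci_upper=np.quantile(D, hi, axis=0),
        runs_requested=runs,
        runs_effective=D.shape[0],
    )
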