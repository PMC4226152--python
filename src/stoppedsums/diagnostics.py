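"""Model evaluation for the sums model.

All diagnostics are pure functions of their inputs: log-scale
residuals, predicted-vs-observed correlations, side-by-side quantile
comparison of a simulated sums distribution against observed sums, and
pathology screening (skew, outliers) of bootstrap coefficient draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import BootstrapCoefficients, SimulationResult

__all__ = [
    "DiagnosticReport",
    "residuals_log_scale",
    "prediction_correlations",
    "compare_quantiles",
    "coefficient_pathology",
]


@dataclass
class DiagnosticReport:
    residuals_log: np.ndarray | None = None
    correlations: dict | None = None
    quantile_table: pd.DataFrame | None = None
    skew_stats: pd.DataFrame | None = None


def residuals_log_scale(observed, predicted) -> np.ndarray:
    """log(observed) - log(predicted), case by case."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have equal length")
    if np.any(observed <= 0) or np.any(predicted <= 0):
        raise ValueError("log-scale residuals require strictly positive values")
    return np.log(observed) - np.log(predicted)


def prediction_correlations(observed_means, predicted_means,
                            observed_sums, predicted_sums) -> dict:
    """Pearson correlations of predicted vs observed means and sums."""
    r_means = float(np.corrcoef(observed_means, predicted_means)[0, 1])
    r_sums = float(np.corrcoef(observed_sums, predicted_sums)[0, 1])
    return {"means": r_means, "sums": r_sums}


def _stats_row(v):
    v = np.asarray(v, dtype=float)
    q25, q50, q75 = np.quantile(v, [0.25, 0.5, 0.75])
    return {"q25": q25, "q50": q50, "q75": q75,
            "mean": v.mean(), "sd": v.std(ddof=1) if v.size > 1 else 0.0}


def compare_quantiles(simulated, observed) -> pd.DataFrame:
    """Side-by-side mean, SD and quartiles: model simulation vs observed sums."""
    if isinstance(simulated, SimulationResult):
        simulated = simulated.sums_matrix
    sim = np.asarray(simulated, dtype=float).ravel()
    obs = np.asarray(observed, dtype=float).ravel()
    if sim.size == 0 or obs.size == 0:
        raise ValueError("simulated and observed inputs must be non-empty")
    return pd.DataFrame(
        [_stats_row(sim), _stats_row(obs)], index=["model", "observed"]
    )[["q25", "q50", "q75", "mean", "sd"]]


def normality_screen(residuals, alpha: float = 0.01) -> dict:
    """Shapiro-Wilk screen of log-scale residuals (off by default in the CLI)."""
    stat, p = stats.shapiro(np.asarray(residuals, dtype=float))
    return {"statistic": float(stat), "p": float(p), "normal": bool(p > alpha)}


def coefficient_pathology(draws, names=None, iqr_factor: float = 3.0) -> pd.DataFrame:
    """Per-coefficient mean, median, skewness and extreme-draw count.

    Skewness is the adjusted Fisher-Pearson sample skewness; a draw is
    flagged as an outlier when it lies more than ``iqr_factor``
    interquartile ranges from the median.
    """
    if isinstance(draws, BootstrapCoefficients):
        names = names or draws.names
        draws = draws.draws
    D = np.atleast_2d(np.asarray(draws, dtype=float))
    if D.shape[0] == 1 and D.shape[1] > 1 and names is None:
        D = D.T
    if D.shape[0] < 100:
        raise ValueError("pathology screening needs at least 100 draws")
    names = list(names) if names is not None else [f"b{k}" for k in
                                                   range(D.shape[1])]
    rows = []
    for k, name in enumerate(names):
        v = D[:, k]
        med = np.median(v)
        iqr = np.subtract(*np.percentile(v, [75, 25]))
        cutoff = iqr_factor * iqr
        n_out = int(np.sum(np.abs(v - med) > cutoff)) if iqr > 0 else 0
        rows.append({
            "coefficient": name,
            "mean": v.mean(),
            "median": med,
            "skewness": float(stats.skew(v, bias=False)),
            "outliers": n_out,
        })
    return pd.DataFrame(rows).set_index("coefficient")
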