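"""Long-format data model, file I/O and synthetic fixture generation.

The canonical interchange format is long: one row per magnitude
observation, with a subject identifier, an optional round identifier,
the positive magnitude, and predictor columns. Per-unit counts n_j and
sums S_j are always derived from the rows, never stored, so they cannot
fall out of sync.

The fixture generator realizes the generative model the estimators
target: counts from a frequency family whose log mean is a linear
predictor in subject-level covariates, magnitudes from a log-link
magnitude family whose location carries fixed effects, optional
between-unit Gaussian variation on the link scale, and (three-level)
per-round intercepts. True parameters are recorded in the dataset
metadata for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .distributions import (
    FrequencyModelSpec,
    MagnitudeModelSpec,
    sample_frequencies,
)

__all__ = [
    "RSSDataset",
    "FixtureConfig",
    "read_long_table",
    "write_long_table",
    "generate_fixture",
]


class ValidationError(ValueError):
    pass


@dataclass
class RSSDataset:
    """Long-format randomly-stopped-sums data.

    ``frame`` has one row per magnitude observation. Predictors listed
    in ``subject_predictors`` must be constant within subject; those in
    ``round_predictors`` constant within round.
    """

    frame: pd.DataFrame
    subject_col: str = "subject"
    round_col: str | None = None
    magnitude_col: str = "magnitude"
    subject_predictors: list = field(default_factory=list)
    round_predictors: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frame = pd.DataFrame(self.frame).reset_index(drop=True)
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self):
        df = self.frame
        required = [self.subject_col, self.magnitude_col] + (
            [self.round_col] if self.round_col else []
        )
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"missing required columns: {missing}")
        dup = df.columns[df.columns.duplicated()].tolist()
        if dup:
            raise ValidationError(f"duplicate columns: {dup}")
        mag = df[self.magnitude_col]
        bad = df.index[(mag <= 0) | mag.isna()].tolist()
        if bad:
            raise ValidationError(
                f"non-positive or missing magnitudes at rows {bad[:10]}"
            )
        for col in self.subject_predictors:
            if col not in df.columns:
                raise ValidationError(f"subject predictor {col!r} not present")
            nun = df.groupby(self.subject_col)[col].nunique()
            off = nun[nun > 1].index.tolist()
            if off:
                raise ValidationError(
                    f"subject-level predictor {col!r} varies within "
                    f"subjects {off[:10]}"
                )
        for col in self.round_predictors:
            if col not in df.columns:
                raise ValidationError(f"round predictor {col!r} not present")
            if self.round_col is None:
                raise ValidationError("round predictors given without a round column")
            nun = df.groupby(self.round_col)[col].nunique()
            off = nun[nun > 1].index.tolist()
            if off:
                raise ValidationError(
                    f"round-level predictor {col!r} varies within rounds {off[:10]}"
                )

    # -- derived structure -------------------------------------------------
    def _unit_keys(self, levels: int):
        if levels == 3:
            if self.round_col is None:
                raise ValidationError("three-level analysis requires a round column")
            return [self.subject_col, self.round_col]
        return [self.subject_col]

    def unit_frame(self, levels: int = 2) -> pd.DataFrame:
        """One row per unit: count ``n``, sum ``S``, and unit-level predictors."""
        keys = self._unit_keys(levels)
        g = self.frame.groupby(keys, sort=True)
        out = g[self.magnitude_col].agg(n="count", S="sum")
        preds = list(dict.fromkeys(self.subject_predictors + self.round_predictors))
        for col in preds:
            out[col] = g[col].first()
        if levels == 3:
            out["_round"] = out.index.get_level_values(self.round_col)
        return out

    def observations(self, levels: int = 2):
        """(magnitudes, unit_index) aligned with ``unit_frame`` row order."""
        keys = self._unit_keys(levels)
        units = self.unit_frame(levels)
        codes = pd.MultiIndex.from_frame(self.frame[keys]) if levels == 3 else \
            pd.Index(self.frame[keys[0]])
        lut = {k: i for i, k in enumerate(units.index)}
        idx = np.array([lut[k] for k in codes])
        return self.frame[self.magnitude_col].to_numpy(dtype=float), idx

    @property
    def counts(self) -> pd.Series:
        return self.unit_frame(2)["n"]

    @property
    def sums(self) -> pd.Series:
        return self.unit_frame(2)["S"]

    def summary(self) -> str:
        uf = self.unit_frame(3 if self.round_col else 2)
        return (
            f"RSSDataset: {len(self.frame)} observations, "
            f"{self.frame[self.subject_col].nunique()} subjects"
            + (f", {self.frame[self.round_col].nunique()} rounds"
               if self.round_col else "")
            + f"; counts mean {uf['n'].mean():.2f}, "
            f"magnitude mean {self.frame[self.magnitude_col].mean():.1f}"
        )


def read_long_table(path, subject_col="subject", round_col=None,
                    magnitude_col="magnitude", subject_predictors=None,
                    round_predictors=None, delimiter=None) -> RSSDataset:
    """Read a delimited long-format table (comma default, tab accepted)."""
    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None
                     else "c")
    return RSSDataset(
        frame=df, subject_col=subject_col, round_col=round_col,
        magnitude_col=magnitude_col,
        subject_predictors=list(subject_predictors or []),
        round_predictors=list(round_predictors or []),
    )


def write_long_table(dataset: RSSDataset, path, delimiter=","):
    dataset.frame.to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# fixtures


@dataclass
class FixtureConfig:
    """Generating configuration for a synthetic two- or three-level dataset.

    ``alpha``/``beta`` map predictor names (plus "const") to log-link
    coefficients for the frequency and magnitude locations. Default
    design: a binary ``condition`` column splitting subjects in half.
    ``sigma_upsilon`` adds N(0, sigma_upsilon) unit-level variation to
    the magnitude location on the log scale. For three-level data,
    ``round_intercepts`` gives the per-round magnitude intercepts
    (overriding beta["const"]) and rounds get binary ``frame``/``deck_type``
    style predictors only if supplied in ``round_design``.
    """

    levels: int = 2
    J: int = 100
    rounds: int = 1
    freq_family: str = "negbin"
    freq_params: dict = field(default_factory=lambda: {"phi": 10.0})
    mag_family: str = "lognormal"
    mag_params: dict = field(default_factory=lambda: {"sigma_log": 0.447})
    alpha: dict = field(default_factory=lambda: {"const": np.log(10.0)})
    beta: dict = field(default_factory=lambda: {"const": 6.81})
    round_intercepts: list | None = None
    sigma_upsilon: float = 0.0
    design: pd.DataFrame | None = None
    round_design: pd.DataFrame | None = None
    seed: int = 0

    def to_manifest(self) -> dict:
        d = asdict(self)
        for k in ("design", "round_design"):
            if d[k] is not None:
                d[k] = pd.DataFrame(d[k]).to_dict(orient="list")
        return json.loads(json.dumps(d, default=float))


def _freq_spec_at(config, log_mean):
    mean = float(np.exp(log_mean))
    fam = config.freq_family
    p = config.freq_params
    if fam == "poisson":
        return FrequencyModelSpec(family="poisson", lam=mean)
    if fam == "negbin":
        phi = p["phi"]
        return FrequencyModelSpec(family="negbin", pi=mean / (phi + mean), phi=phi)
    if fam == "poisson_gamma":
        return FrequencyModelSpec(family="poisson_gamma", q=p["q"], eta=mean)
    raise ValidationError(f"unsupported fixture frequency family {fam!r}")


def generate_fixture(config: FixtureConfig) -> RSSDataset:
    """Draw a dataset from the configured hierarchical generative model."""
    rng = np.random.default_rng(config.seed)
    J = config.J
    # subject-level design
    if config.design is not None:
        X = pd.DataFrame(config.design).reset_index(drop=True)
        if len(X) != J:
            raise ValidationError("design must have J rows")
    else:
        cols = [c for c in set(config.alpha) | set(config.beta) if c != "const"]
        X = pd.DataFrame(index=range(J))
        for c in sorted(cols):
            X[c] = (np.arange(J) >= J / 2).astype(float)  # half/half split
    subj_cols = list(X.columns)

    rounds = config.rounds if config.levels == 3 else 1
    if config.levels == 3 and config.round_intercepts is not None \
            and len(config.round_intercepts) != rounds:
        raise ValidationError("round_intercepts length must equal rounds")
    round_design = (pd.DataFrame(config.round_design).reset_index(drop=True)
                    if config.round_design is not None else
                    pd.DataFrame(index=range(rounds)))
    round_cols = list(round_design.columns)

    mags, subj_rep, round_rep, cov_rep = [], [], [], []
    for j in range(J):
        for k in range(rounds):
            log_eta = config.alpha.get("const", 0.0)
            for c, a in config.alpha.items():
                if c == "const":
                    continue
                if c in subj_cols:
                    log_eta += a * X.loc[j, c]
                elif c in round_cols:
                    log_eta += a * round_design.loc[k, c]
            n = int(sample_frequencies(_freq_spec_at(config, log_eta), 1, rng)[0])

            if config.levels == 3 and config.round_intercepts is not None:
                loc = config.round_intercepts[k]
            else:
                loc = config.beta.get("const", 0.0)
            for c, b in config.beta.items():
                if c == "const":
                    continue
                if c in subj_cols:
                    loc += b * X.loc[j, c]
                elif c in round_cols:
                    loc += b * round_design.loc[k, c]
            if config.sigma_upsilon > 0:
                loc += rng.normal(0.0, config.sigma_upsilon)

            if n == 0:
                continue
            if config.mag_family == "lognormal":
                z = rng.lognormal(loc, config.mag_params["sigma_log"], size=n)
            elif config.mag_family == "gamma":
                shape = config.mag_params["shape"]
                z = rng.gamma(shape, np.exp(loc) / shape, size=n)
            elif config.mag_family == "exponential":
                z = rng.exponential(np.exp(loc), size=n)
            else:
                raise ValidationError(
                    f"unsupported fixture magnitude family {config.mag_family!r}"
                )
            mags.append(z)
            subj_rep.append(np.repeat(f"s{j:05d}", n))
            round_rep.append(np.repeat(f"r{k}", n))
            cov_rep.append(
                [float(X.loc[j, c]) for c in subj_cols]
                + [float(round_design.loc[k, c]) for c in round_cols]
            )

    counts = [len(m) for m in mags]
    frame = pd.DataFrame({
        "subject": np.concatenate(subj_rep) if mags else [],
        "magnitude": np.concatenate(mags) if mags else [],
    })
    if config.levels == 3:
        frame.insert(1, "round", np.concatenate(round_rep))
    cov = np.repeat(np.array(cov_rep, dtype=float).reshape(len(counts), -1),
                    counts, axis=0)
    for i, c in enumerate(subj_cols + round_cols):
        frame[c] = cov[:, i]
    meta = {"truth": config.to_manifest(), "units": "ms"}
    return RSSDataset(
        frame=frame,
        subject_col="subject",
        round_col="round" if config.levels == 3 else None,
        magnitude_col="magnitude",
        subject_predictors=subj_cols,
        round_predictors=round_cols,
        metadata=meta,
    )
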