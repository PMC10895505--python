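"""Synthetic two-arm trial generator with known interventional effects.

Emulates the schema and causal structure of a lay-counsellor behavioural
activation trial for depression: clinic clustering, treated-only process
mediators (session phase M1a, homework M1b, response M3a, extra sessions
M3b), a continuous activation score (M2, BADS-SF) measured in both arms,
a 12-month PHQ-9 outcome, and missing-at-random gaps in M2 and the outcome.

The generator's structural equations are linear and additive on the
mediator *codes*, so the true interventional effects have the closed form

    IE_block = sum over mediators m in block of  b_m * (E[m | a=1] - E[m | a=0])

where ``b_m`` is the outcome coefficient of ``m``.  Category-valued
mediators arise from latent Gaussian propensities cut at thresholds, whose
marginal means have no closed form; those are evaluated by a Monte-Carlo
oracle over a large simulated covariate population.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from .schema import ARM, CLUSTER, COLUMNS, COVARIATES, OUTCOME, SUBJECT, TrialDataset

#: centring constants for covariate contributions in the structural equations
#: (keeps intercepts interpretable as values at a typical subject)
CENTERS = {
    "age": 42.0,
    "education": 1.15,
    "marital_status": 0.9,
    "expectations": 0.9,
    "phq9_baseline": 18.3,
}
M2_CENTER = 22.0  # typical activation score; centres the M2 -> response path


@dataclass(frozen=True)
class CovariateParams:
    """Baseline covariate distributions (ages in years, scores on scale units)."""

    age_mean: float = 42.0
    age_sd: float = 12.0
    age_range: tuple[float, float] = (18.0, 65.0)
    education_probs: tuple[float, ...] = (0.35, 0.30, 0.20, 0.15)
    marital_probs: tuple[float, ...] = (0.25, 0.60, 0.15)
    expectations_probs: tuple[float, ...] = (0.30, 0.50, 0.20)
    # baseline PHQ-9 = 15 + 12 * Beta(a, b): supported on (15, 27), eligibility > 14
    phq9_baseline_beta: tuple[float, float] = (1.5, 4.0)


@dataclass(frozen=True)
class PathCoefficients:
    """Structural-equation coefficients: arm -> mediators -> outcome.

    Category mediators are generated from latent N(mean, 1) propensities cut
    at the given thresholds (category = number of thresholds below the
    latent value).  Covariate dicts map covariate name -> slope on the
    centred covariate.  Outcome coefficients act on the mediator codes.
    """

    # M1a: session phase completed, treated arm only
    m1a_mean: float = 0.0
    m1a_thresholds: tuple[float, ...] = (-1.405, -0.84, -0.126)
    m1a_covariates: Mapping[str, float] = field(default_factory=lambda: {"expectations": 0.15})
    # M1b: homework, conditional on attending at least one session
    m1b_on_m1a: float = 0.4
    m1b_thresholds: tuple[float, ...] = (-0.04, 1.126)
    m1b_covariates: Mapping[str, float] = field(default_factory=lambda: {"education": 0.10})
    # M2: behavioural activation, both arms
    m2_intercept: float = 25.0
    m2_arm: float = 1.0
    m2_on_m1a: float = 0.7
    m2_on_m1b: float = 0.3
    m2_covariates: Mapping[str, float] = field(
        default_factory=lambda: {"phq9_baseline": -0.30, "age": -0.02}
    )
    # M3a: response to treatment, treated arm only (depends on activation)
    m3a_intercept: float = 0.62
    m3a_on_m2: float = 0.05
    m3a_covariates: Mapping[str, float] = field(default_factory=dict)
    # M3b: extra sessions, non-responders in treated arm only
    m3b_mean: float = 0.0
    m3b_thresholds: tuple[float, ...] = (-0.84, 0.0)
    m3b_covariates: Mapping[str, float] = field(default_factory=dict)
    # outcome: 12-month PHQ-9
    y_intercept: float = 13.0
    y_arm: float = -2.3  # interventional direct effect
    y_m1a: float = 0.6
    y_m1b: float = 0.55
    y_m2: float = -0.233
    y_m3a: float = -1.0
    y_m3b: float = -0.8
    y_covariates: Mapping[str, float] = field(
        default_factory=lambda: {"phq9_baseline": 0.45, "age": 0.02, "education": -0.30}
    )


@dataclass(frozen=True)
class MissingnessModel:
    """MAR missingness: logit depends on centred covariates (+ arm); the
    intercept is solved so the marginal missing fraction equals ``prob``."""

    prob: float
    coefficients: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class MissingnessConfig:
    m2: MissingnessModel = field(
        default_factory=lambda: MissingnessModel(0.057, {"phq9_baseline": 0.15})
    )
    outcome: MissingnessModel = field(
        default_factory=lambda: MissingnessModel(0.093, {"phq9_baseline": 0.12, "age": 0.01})
    )


@dataclass(frozen=True)
class GeneratorConfig:
    n_subjects: int = 493
    n_clusters: int = 10
    allocation: float = 0.5
    seed: int = 0
    integer_scores: bool = False
    covariate_params: CovariateParams = field(default_factory=CovariateParams)
    paths: PathCoefficients = field(default_factory=PathCoefficients)
    residual_sd_m2: float = 8.0
    residual_sd_outcome: float = 5.5
    cluster_sd: float = 0.5
    missingness: MissingnessConfig = field(default_factory=MissingnessConfig)
    truth_oracle_n: int = 200_000

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if not (0.0 <= self.allocation <= 1.0):
            raise ValueError("allocation must lie in [0, 1]")
        if self.n_clusters <= 0 or self.n_clusters > self.n_subjects:
            raise ValueError("need 1 <= n_clusters <= n_subjects")
        for sd in (self.residual_sd_m2, self.residual_sd_outcome, self.cluster_sd):
            if sd < 0:
                raise ValueError("standard deviations must be nonnegative")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth interventional effects implied by a generator config."""

    true_total: float
    true_direct: float
    true_indirect: Mapping[str, float]
    derivation: str  # closed_form | monte_carlo_oracle

    def __post_init__(self) -> None:
        resid = self.true_direct + sum(self.true_indirect.values()) - self.true_total
        if abs(resid) > 1e-8:
            raise ValueError("truth additivity violated")


# ---------------------------------------------------------------------------
# structural draws (shared by the generator and the Monte-Carlo oracle)
# ---------------------------------------------------------------------------

def _cov_term(cov: pd.DataFrame, coefs: Mapping[str, float]) -> np.ndarray:
    out = np.zeros(len(cov))
    for name, c in coefs.items():
        if name not in cov.columns:
            raise ValueError(f"structural equation references unknown covariate {name!r}")
        out += c * (cov[name].to_numpy(dtype=float) - CENTERS.get(name, 0.0))
    return out


def _cut(latent: np.ndarray, thresholds) -> np.ndarray:
    return np.searchsorted(np.asarray(thresholds), latent).astype(float)


def _draw_mediators(
    cov: pd.DataFrame, arm: np.ndarray, p: PathCoefficients, sd_m2: float, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    n = len(arm)
    treated = arm == 1

    m1a = np.zeros(n)
    lat = p.m1a_mean + _cov_term(cov, p.m1a_covariates) + rng.standard_normal(n)
    m1a[treated] = _cut(lat, p.m1a_thresholds)[treated]

    m1b = np.zeros(n)
    lat = p.m1b_on_m1a * m1a + _cov_term(cov, p.m1b_covariates) + rng.standard_normal(n)
    attended = treated & (m1a >= 1)
    m1b[attended] = _cut(lat, p.m1b_thresholds)[attended]

    m2 = (
        p.m2_intercept
        + p.m2_arm * arm
        + p.m2_on_m1a * m1a
        + p.m2_on_m1b * m1b
        + _cov_term(cov, p.m2_covariates)
        + rng.normal(0.0, sd_m2, n)
    )

    m3a = np.zeros(n)
    prob = expit(p.m3a_intercept + p.m3a_on_m2 * (m2 - M2_CENTER) + _cov_term(cov, p.m3a_covariates))
    m3a[treated] = (rng.random(n) < prob).astype(float)[treated]

    m3b = np.zeros(n)
    lat = p.m3b_mean + _cov_term(cov, p.m3b_covariates) + rng.standard_normal(n)
    nonresp = treated & (m3a == 0)
    m3b[nonresp] = _cut(lat, p.m3b_thresholds)[nonresp]

    return {"m1a": m1a, "m1b": m1b, "m2": m2, "m3a": m3a, "m3b": m3b}


def _draw_covariates(n: int, cp: CovariateParams, rng: np.random.Generator) -> pd.DataFrame:
    age = np.clip(rng.normal(cp.age_mean, cp.age_sd, n), *cp.age_range)
    edu = rng.choice(len(cp.education_probs), size=n, p=cp.education_probs)
    mar = rng.choice(len(cp.marital_probs), size=n, p=cp.marital_probs)
    exp_ = rng.choice(len(cp.expectations_probs), size=n, p=cp.expectations_probs)
    a, b = cp.phq9_baseline_beta
    phq0 = 15.0 + 12.0 * rng.beta(a, b, n)
    return pd.DataFrame(
        {
            "age": age,
            "education": edu.astype(float),
            "marital_status": mar.astype(float),
            "expectations": exp_.astype(float),
            "phq9_baseline": phq0,
        }
    )


def _outcome_mean(cov: pd.DataFrame, arm: np.ndarray, med: Mapping[str, np.ndarray], p: PathCoefficients) -> np.ndarray:
    return (
        p.y_intercept
        + p.y_arm * arm
        + p.y_m1a * med["m1a"]
        + p.y_m1b * med["m1b"]
        + p.y_m2 * med["m2"]
        + p.y_m3a * med["m3a"]
        + p.y_m3b * med["m3b"]
        + _cov_term(cov, p.y_covariates)
    )


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def compute_truth(config: GeneratorConfig, n_oracle: int | None = None) -> SyntheticTruth:
    """True interventional effects under the generator's structural equations.

    Linear-additive configurations with no upstream dependence of M2 and no
    outcome contribution of the categorical mediators admit a closed form
    (product of structural coefficients); otherwise the mediator mean shifts
    are integrated by Monte Carlo over a large simulated population.
    """
    p = config.paths
    closed = (
        p.m2_on_m1a == 0.0
        and p.m2_on_m1b == 0.0
        and p.y_m1a == 0.0
        and p.y_m1b == 0.0
        and p.y_m3a == 0.0
        and p.y_m3b == 0.0
    )
    if closed:
        indirect = {"sessions": 0.0, "activation": p.y_m2 * p.m2_arm, "response": 0.0}
        direct = p.y_arm
        return SyntheticTruth(
            true_total=direct + sum(indirect.values()),
            true_direct=direct,
            true_indirect=indirect,
            derivation="closed_form",
        )

    n = int(n_oracle or config.truth_oracle_n)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    cov = _draw_covariates(n, config.covariate_params, rng)
    med1 = _draw_mediators(cov, np.ones(n), p, config.residual_sd_m2, rng)
    med0 = _draw_mediators(cov, np.zeros(n), p, config.residual_sd_m2, rng)
    delta = {m: float(np.mean(med1[m]) - np.mean(med0[m])) for m in med1}
    indirect = {
        "sessions": p.y_m1a * delta["m1a"] + p.y_m1b * delta["m1b"],
        "activation": p.y_m2 * delta["m2"],
        "response": p.y_m3a * delta["m3a"] + p.y_m3b * delta["m3b"],
    }
    direct = p.y_arm
    return SyntheticTruth(
        true_total=direct + sum(indirect.values()),
        true_direct=direct,
        true_indirect=indirect,
        derivation="monte_carlo_oracle",
    )


def generate_trial(
    config: GeneratorConfig, truth: SyntheticTruth | None = None
) -> tuple[TrialDataset, SyntheticTruth]:
    """Generate one complete synthetic trial plus its ground truth.

    Identical config (and seed) reproduces the dataset exactly.  Pass a
    precomputed ``truth`` to skip re-running the Monte-Carlo oracle when
    generating many replicates from one configuration.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    cov = _draw_covariates(n, config.covariate_params, rng)

    # deterministic permuted allocation: arm sizes fixed by the config
    n_treated = round(n * config.allocation)
    arm = np.zeros(n)
    arm[:n_treated] = 1.0
    arm = arm[rng.permutation(n)]

    # balanced clinic assignment, then permuted
    clusters = np.resize(np.arange(1, config.n_clusters + 1), n)
    clusters = clusters[rng.permutation(n)]

    med = _draw_mediators(cov, arm, config.paths, config.residual_sd_m2, rng)

    cluster_eff = rng.normal(0.0, config.cluster_sd, config.n_clusters)
    y = (
        _outcome_mean(cov, arm, med, config.paths)
        + cluster_eff[clusters.astype(int) - 1]
        + rng.normal(0.0, config.residual_sd_outcome, n)
    )

    if config.integer_scores:
        y = np.clip(_round_half_up(y), 0.0, 27.0)
        cov["phq9_baseline"] = np.clip(_round_half_up(cov["phq9_baseline"]), 15.0, 27.0)

    df = pd.DataFrame({SUBJECT: np.arange(1, n + 1), CLUSTER: clusters, ARM: arm})
    for c in COVARIATES:
        df[c] = cov[c].to_numpy()
    for m, vals in med.items():
        df[m] = vals
    df[OUTCOME] = y

    dataset = TrialDataset(df=df[list(COLUMNS)], integer_scores=config.integer_scores)
    dataset.validate()
    if truth is None:
        truth = compute_truth(config)
    return dataset, truth


def _solve_intercept(xb: np.ndarray, prob: float) -> float:
    if prob <= 0.0:
        return -np.inf
    if prob >= 1.0:
        return np.inf
    return brentq(lambda c: float(np.mean(expit(c + xb))) - prob, -40.0, 40.0)


def impose_missingness(dataset: TrialDataset, config: GeneratorConfig) -> TrialDataset:
    """Delete M2 and outcome values under the configured MAR mechanism.

    Missingness probabilities depend only on baseline covariates and arm,
    never on the value being deleted; the marginal missing fraction matches
    each model's ``prob`` in expectation.
    """
    for col in ("m2", OUTCOME):
        if dataset.df[col].isna().any():
            raise ValueError(f"{col} already has missing values")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    df = dataset.df.copy()
    for col, model in (("m2", config.missingness.m2), (OUTCOME, config.missingness.outcome)):
        xb = np.zeros(len(df))
        for name, c in model.coefficients.items():
            if name == ARM:
                xb += c * df[ARM].to_numpy(dtype=float)
            elif name in COVARIATES:
                xb += c * (df[name].to_numpy(dtype=float) - CENTERS.get(name, 0.0))
            else:
                raise ValueError(f"missingness model references unknown covariate {name!r}")
        c0 = _solve_intercept(xb, model.prob)
        p = expit(c0 + xb)
        drop = rng.random(len(df)) < p
        df.loc[drop, col] = np.nan
    return TrialDataset(df=df, integer_scores=dataset.integer_scores)


# ---------------------------------------------------------------------------
# round-trippable structured-text serialisation
# ---------------------------------------------------------------------------

def config_to_yaml(config: GeneratorConfig) -> str:
    return yaml.safe_dump(dataclasses.asdict(config), sort_keys=False)


def config_from_yaml(text: str) -> GeneratorConfig:
    raw = yaml.safe_load(text)
    raw["covariate_params"] = CovariateParams(
        **{k: tuple(v) if isinstance(v, list) else v for k, v in raw["covariate_params"].items()}
    )
    raw["paths"] = PathCoefficients(
        **{k: tuple(v) if isinstance(v, list) else v for k, v in raw["paths"].items()}
    )
    miss = raw["missingness"]
    raw["missingness"] = MissingnessConfig(
        m2=MissingnessModel(**miss["m2"]), outcome=MissingnessModel(**miss["outcome"])
    )
    return GeneratorConfig(**raw)


def truth_to_yaml(truth: SyntheticTruth) -> str:
    return yaml.safe_dump(dataclasses.asdict(truth), sort_keys=False)


def truth_from_yaml(text: str) -> SyntheticTruth:
    raw = yaml.safe_load(text)
    return SyntheticTruth(
        true_total=raw["true_total"],
        true_direct=raw["true_direct"],
        true_indirect=dict(raw["true_indirect"]),
        derivation=raw["derivation"],
    )
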