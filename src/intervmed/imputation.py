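"""Single stochastic imputation of M2 and the 12-month outcome by chained
equations, run separately within each trial arm.

Both variables are score scales treated as continuous, so each chain step
is a Bayesian linear regression: the residual variance is drawn from its
scaled inverse-chi-square posterior, coefficients from their normal
posterior given that variance, and the missing values are filled with
posterior-predictive draws (never conditional-mean fills).  The procedure
is designed to be executed exactly once inside each bootstrap resample,
with a resample-specific seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import build_design
from .schema import ARM, COVARIATES, NOMINAL_COVARIATES, OUTCOME, TrialDataset

logger = logging.getLogger(__name__)

TREATED_ONLY_MEDIATORS = ("m1a", "m1b", "m3a", "m3b")

#: outcome scores are truncated into their support after imputation
SCORE_BOUNDS = {OUTCOME: (0.0, 27.0)}


def _default_predictors() -> dict[str, list[str]]:
    base = list(COVARIATES) + [ARM]
    return {
        "m2": base + [OUTCOME] + list(TREATED_ONLY_MEDIATORS),
        OUTCOME: base + ["m2"] + list(TREATED_ONLY_MEDIATORS),
    }


@dataclass(frozen=True)
class ImputationSpec:
    """What to impute, with which predictors, and how many chain sweeps.

    Treated-only mediators appear among the default predictors but are
    constant (all zero) in the control stratum; constant columns are
    dropped per stratum, which realises the "treated stratum only" rule.
    """

    variables_to_impute: tuple[str, ...] = ("m2", OUTCOME)
    predictors: Mapping[str, Sequence[str]] = field(default_factory=_default_predictors)
    n_burnin: int = 10
    by_arm: bool = True

    def __post_init__(self) -> None:
        if self.n_burnin < 1:
            raise ValueError("n_burnin must be >= 1")
        for var in self.variables_to_impute:
            if var in self.predictors.get(var, ()):
                raise ValueError(f"{var} cannot predict itself")


def _posterior_predictive_fill(
    X_obs: np.ndarray, y_obs: np.ndarray, X_mis: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw sigma^2 and beta from their posterior, then predictive values."""
    n, p = X_obs.shape
    XtX = X_obs.T @ X_obs
    # tiny jitter keeps the draw defined when a stratum is nearly collinear
    XtX_reg = XtX + 1e-8 * np.eye(p)
    beta_hat = np.linalg.solve(XtX_reg, X_obs.T @ y_obs)
    resid = y_obs - X_obs @ beta_hat
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / rng.chisquare(dof)
    cov = sigma2 * np.linalg.inv(XtX_reg)
    beta = rng.multivariate_normal(beta_hat, cov, method="cholesky")
    return X_mis @ beta + rng.normal(0.0, np.sqrt(sigma2), len(X_mis))


def _impute_stratum(
    df: pd.DataFrame, spec: ImputationSpec, rng: np.random.Generator, label: str
) -> pd.DataFrame:
    df = df.copy()
    miss = {v: df[v].isna().to_numpy() for v in spec.variables_to_impute}
    active = [v for v in spec.variables_to_impute if miss[v].any()]
    if not active:
        return df
    for v in active:
        obs = df[v].dropna().to_numpy()
        if len(obs) == 0:
            raise ValueError(f"no observed values of {v} in stratum {label}; cannot impute")
        # initialise missing cells with random draws from the observed values
        df.loc[miss[v], v] = rng.choice(obs, size=int(miss[v].sum()), replace=True)

    for v in spec.variables_to_impute:
        extra = [p for p in spec.predictors.get(v, []) if df[p].isna().any() and p not in spec.variables_to_impute]
        if extra:
            raise ValueError(f"predictors with missing values not in the chain: {extra}")

    categorical = {k: (tuple(lv), lv[0]) for k, lv in NOMINAL_COVARIATES.items()}
    n_filled = {v: int(miss[v].sum()) for v in active}
    for _ in range(spec.n_burnin):
        for v in active:
            preds = [p for p in spec.predictors.get(v, []) if p in df.columns]
            # drop columns constant in this stratum (e.g. arm, or treated-only
            # mediators in the control arm)
            preds = [p for p in preds if df[p].nunique() > 1]
            X, _ = build_design(df, preds, categorical)
            y = df[v].to_numpy(dtype=float)
            filled = _posterior_predictive_fill(X[~miss[v]], y[~miss[v]], X[miss[v]], rng)
            lo_hi = SCORE_BOUNDS.get(v)
            if lo_hi:
                filled = np.clip(filled, *lo_hi)
            df.loc[miss[v], v] = filled
    logger.info("imputed %s cells in stratum %s", n_filled, label)
    return df


def impute_chained(
    dataset: TrialDataset, spec: ImputationSpec, rng: np.random.Generator | int = 0
) -> TrialDataset:
    """Return a completed copy of the dataset; observed values are untouched.

    Draws are stochastic posterior-predictive values; two different seeds
    give different imputations.  A dataset with no missing cells is
    returned unchanged.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    other = [
        c
        for c in dataset.df.columns
        if c not in spec.variables_to_impute and dataset.df[c].isna().any()
    ]
    if other:
        raise ValueError(f"missingness outside variables_to_impute: {other}")
    if not dataset.df[list(spec.variables_to_impute)].isna().any().any():
        return dataset.copy()

    df = dataset.df
    if spec.by_arm:
        parts = []
        for a, sub in df.groupby(ARM, sort=True):
            parts.append(_impute_stratum(sub, spec, rng, label=f"arm={a:g}"))
        out = pd.concat(parts).sort_index()
    else:
        out = _impute_stratum(df, spec, rng, label="all")
    return TrialDataset(df=out, integer_scores=dataset.integer_scores)
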