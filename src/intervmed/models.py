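"""Mediator and outcome regressions, AIC covariate selection, mediator draws.

Families follow the trial analysis: linear models for the session-phase
code (M1a) and the activation score (M2), proportional-odds models for
homework (M1b) and extra sessions (M3b), logistic for response (M3a), and
a linear outcome model for 12-month PHQ-9.  Treated-only mediators are
fitted on treated-arm records; their control-arm (unexposed) distribution
is degenerate at the reference category and never touches the model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from . import _ordinal
from .design import Categorical, build_design, check_full_rank
from .schema import ARM, NOMINAL_COVARIATES, OUTCOME, BlockStructure, TrialDataset

logger = logging.getLogger(__name__)

RIDGE_FALLBACK = 1e-4  # weak ridge on slopes for separated categorical fits


@dataclass
class FittedModel:
    """A fitted regression supporting mean prediction and stochastic draws.

    ``coefficients`` align with ``predictor_names`` (which include ``const``
    for linear/logistic fits; ordinal fits absorb the intercept into the
    ``cutpoints``).  ``levels`` are the actual category codes a draw can
    return; for the linear-on-codes mediator (M1a) draws are rounded
    half-up and clamped into ``levels``.
    """

    family: str
    target: str
    terms: tuple[str, ...]
    predictor_names: tuple[str, ...]
    coefficients: np.ndarray
    categorical: dict = field(default_factory=dict)
    cutpoints: np.ndarray | None = None
    residual_sd: float | None = None
    levels: tuple[int, ...] | None = None
    n_obs: int = 0
    aic: float = float("nan")
    treated_only: bool = False
    reference: float = 0.0
    round_to_levels: bool = False
    degenerate: bool = False
    constant_value: float | None = None
    ridge_used: bool = False
    parent: str | None = None

    def __post_init__(self) -> None:
        if self.family == "linear" and self.residual_sd is None and not self.degenerate:
            raise ValueError("linear model requires residual_sd")
        if self.family != "linear" and self.residual_sd is not None:
            raise ValueError("residual_sd only valid for linear family")
        if self.cutpoints is not None and np.any(np.diff(self.cutpoints) <= 0):
            raise ValueError("cutpoints must be strictly increasing")

    @property
    def has_intercept(self) -> bool:
        return self.family != "ordinal"

    def _design(self, data) -> np.ndarray:
        X, names = build_design(data, self.terms, self.categorical, intercept=self.has_intercept)
        return X

    def linear_predictor(self, data) -> np.ndarray:
        if self.degenerate:
            n = len(data) if isinstance(data, pd.DataFrame) else len(next(iter(data.values())))
            return np.full(n, self.constant_value, dtype=float)
        return self._design(data) @ self.coefficients

    def predict_mean(self, data) -> np.ndarray:
        eta = self.linear_predictor(data)
        if self.degenerate:
            return eta
        if self.family == "linear":
            return eta
        if self.family == "logistic":
            lv = self.levels or (0, 1)
            p = expit(eta)
            return lv[0] + (lv[-1] - lv[0]) * p
        probs = _ordinal.category_probs(eta, self.cutpoints)
        return probs @ np.asarray(self.levels, dtype=float)

    def category_probs(self, data) -> np.ndarray:
        """(n, K) category probabilities (ordinal/logistic only); rows sum to 1."""
        eta = self.linear_predictor(data)
        if self.family == "logistic":
            p = expit(eta)
            return np.column_stack([1 - p, p])
        if self.family == "ordinal":
            return _ordinal.category_probs(eta, self.cutpoints)
        raise ValueError("category_probs undefined for linear family")

    def draw(self, data, rng: np.random.Generator, u: np.ndarray | None = None) -> np.ndarray:
        """One stochastic draw per row.

        ``u`` optionally supplies the underlying uniform/normal variates so
        that counterfactual draws can share common random numbers: normals
        for the linear family, uniforms otherwise.
        """
        if self.degenerate:
            n = len(data) if isinstance(data, pd.DataFrame) else len(next(iter(data.values())))
            return np.full(n, self.constant_value, dtype=float)
        eta = self.linear_predictor(data)
        if self.family == "linear":
            eps = rng.standard_normal(len(eta)) if u is None else u
            out = eta + self.residual_sd * eps
            if self.round_to_levels:
                lv = np.asarray(self.levels, dtype=float)
                out = np.clip(np.floor(out + 0.5), lv.min(), lv.max())
            return out
        uu = rng.random(len(eta)) if u is None else u
        if self.family == "logistic":
            lv = self.levels or (0, 1)
            return np.where(uu < expit(eta), float(lv[-1]), float(lv[0]))
        # ordinal: invert the cumulative distribution implied by the cutpoints
        cum = expit(self.cutpoints[None, :] - eta[:, None])
        idx = (uu[:, None] > cum).sum(axis=1)
        return np.asarray(self.levels, dtype=float)[idx]

    def summary_dict(self) -> dict:
        """Serialisable audit summary."""
        return {
            "family": self.family,
            "target": self.target,
            "terms": list(self.terms),
            "coefficients": {n: float(c) for n, c in zip(self.predictor_names, self.coefficients)},
            "cutpoints": None if self.cutpoints is None else [float(c) for c in self.cutpoints],
            "residual_sd": None if self.residual_sd is None else float(self.residual_sd),
            "n_obs": int(self.n_obs),
            "aic": float(self.aic),
            "degenerate": bool(self.degenerate),
            "ridge_used": bool(self.ridge_used),
        }


def _degenerate_model(family, target, value, n, **kw) -> FittedModel:
    warnings.warn(f"{target} is constant in the fitting data; returning a point-mass model")
    resid = 0.0 if family == "linear" else None
    return FittedModel(
        family=family,
        target=target,
        terms=(),
        predictor_names=(),
        coefficients=np.empty(0),
        residual_sd=resid,
        n_obs=n,
        degenerate=True,
        constant_value=float(value),
        **kw,
    )


def _fit_linear(y, X, names) -> tuple[np.ndarray, float, float]:
    res = sm.OLS(y, X).fit()
    dof = max(len(y) - X.shape[1], 1)
    resid_sd = float(np.sqrt(res.ssr / dof))
    return np.asarray(res.params), resid_sd, float(res.aic)


def _fit_logistic(y, X) -> tuple[np.ndarray, float, bool]:
    """Returns (params incl. intercept first, aic, ridge_used)."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        params = np.asarray(res.params)
        if res.mle_retvals.get("converged", True) and np.max(np.abs(params)) < 30:
            return params, float(res.aic), False
    except Exception:
        pass
    # separation fallback: weak ridge on slopes via the cumulative-logit solver
    logger.info("logistic fit separated; refitting with ridge %.0e on slopes", RIDGE_FALLBACK)
    beta, tau, nll, _ = _ordinal.fit_proportional_odds(
        X[:, 1:], y.astype(int), 2, ridge=RIDGE_FALLBACK
    )
    params = np.concatenate([[-tau[0]], beta])
    aic = 2 * X.shape[1] + 2 * nll
    return params, float(aic), True


def _fit_ordinal(y_codes, X, n_cats) -> tuple[np.ndarray, np.ndarray, float, bool]:
    beta, tau, nll, ok = _ordinal.fit_proportional_odds(X, y_codes, n_cats)
    if not ok or (len(beta) and np.max(np.abs(beta)) > 30):
        logger.info("ordinal fit separated; refitting with ridge %.0e on slopes", RIDGE_FALLBACK)
        beta, tau, nll, _ = _ordinal.fit_proportional_odds(X, y_codes, n_cats, ridge=RIDGE_FALLBACK)
        return beta, tau, 2 * (len(beta) + n_cats - 1) + 2 * nll, True
    return beta, tau, 2 * (len(beta) + n_cats - 1) + 2 * nll, False


def fit_mediator_model(
    dataset: TrialDataset,
    mediator: str,
    structure: BlockStructure,
    covariates: Sequence[str],
) -> FittedModel:
    """Fit the declared-family regression for one mediator.

    Treated-only mediators are fitted on treated-arm records only; M2 keeps
    both arms with ``arm`` as a predictor.  A declared within-block parent
    (m1b <- m1a, m3b <- m3a) enters as a predictor.
    """
    spec = structure.spec(mediator)
    df = dataset.df
    if spec.treated_only:
        df = df[df[ARM] == 1]
    if np.isnan(df[mediator].to_numpy(dtype=float)).any():
        df = df.dropna(subset=[mediator])
    if len(df) == 0:
        raise ValueError(f"no observations available to fit {mediator}")

    terms = list(covariates)
    if spec.parent is not None:
        terms.append(spec.parent)
    if not spec.treated_only:
        terms.append(ARM)
    categorical = {k: v for k, v in NOMINAL_COVARIATES.items() if k in terms}
    categorical = {k: (tuple(v), v[0]) for k, v in categorical.items()}

    y = df[mediator].to_numpy(dtype=float)
    meta = dict(treated_only=spec.treated_only, reference=float(spec.reference), parent=spec.parent)

    if np.all(y == y[0]):
        return _degenerate_model(spec.family, mediator, y[0], len(y), levels=spec.levels, **meta)

    X, names = build_design(df, terms, categorical, intercept=spec.family != "ordinal")

    if spec.family == "linear":
        params, resid_sd, aic = _fit_linear(y, X, names)
        return FittedModel(
            family="linear",
            target=mediator,
            terms=tuple(terms),
            predictor_names=tuple(names),
            coefficients=params,
            categorical=categorical,
            residual_sd=resid_sd,
            levels=spec.levels,
            round_to_levels=spec.levels is not None,
            n_obs=len(y),
            aic=aic,
            **meta,
        )
    if spec.family == "logistic":
        params, aic, ridge = _fit_logistic(y, X)
        return FittedModel(
            family="logistic",
            target=mediator,
            terms=tuple(terms),
            predictor_names=tuple(names),
            coefficients=params,
            categorical=categorical,
            levels=spec.levels or (0, 1),
            n_obs=len(y),
            aic=aic,
            ridge_used=ridge,
            **meta,
        )
    # ordinal: code observed levels by rank; unobserved levels get probability 0
    observed = tuple(int(v) for v in np.unique(y))
    codes = np.searchsorted(observed, y).astype(int)
    beta, tau, aic, ridge = _fit_ordinal(codes, X, len(observed))
    return FittedModel(
        family="ordinal",
        target=mediator,
        terms=tuple(terms),
        predictor_names=tuple(names),
        coefficients=beta,
        categorical=categorical,
        cutpoints=tau,
        levels=observed,
        n_obs=len(y),
        aic=aic,
        ridge_used=ridge,
        **meta,
    )


def fit_outcome_model(
    dataset: TrialDataset,
    structure: BlockStructure,
    covariates: Sequence[str],
    interactions: Sequence[str] = (),
) -> FittedModel:
    """Linear model of the outcome on arm, all mediators, and confounders.

    Multi-level categorical mediators enter as indicator contrasts against
    their unexposed reference.  Structural-zero collinearity (treated-only
    indicators spanning the arm column) raises with the offending columns
    named.
    """
    df = dataset.df
    if df[OUTCOME].isna().any():
        raise ValueError("outcome has missing values; impute before fitting the outcome model")
    terms = [ARM] + list(structure.mediator_names) + list(covariates) + list(interactions)
    categorical = {k: (tuple(v), v[0]) for k, v in NOMINAL_COVARIATES.items() if k in covariates}
    categorical.update(
        {name: (lv, ref) for name, (lv, ref) in structure.categorical_levels().items()}
    )
    X, names = build_design(df, terms, categorical)
    check_full_rank(X, names)
    y = df[OUTCOME].to_numpy(dtype=float)
    params, resid_sd, aic = _fit_linear(y, X, names)
    return FittedModel(
        family="linear",
        target=OUTCOME,
        terms=tuple(terms),
        predictor_names=tuple(names),
        coefficients=params,
        categorical=categorical,
        residual_sd=resid_sd,
        n_obs=len(y),
        aic=aic,
        treated_only=False,
    )


def _aic_for(dataset, target, terms, family, categorical) -> float:
    df = dataset.df.dropna(subset=[target])
    y = df[target].to_numpy(dtype=float)
    X, names = build_design(df, terms, categorical, intercept=family != "ordinal")
    if family == "linear":
        # gaussian AIC up to a constant; same ordering as the statsmodels value
        n = len(y)
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        ssr = float(resid @ resid)
        return n * np.log(max(ssr, 1e-300) / n) + 2 * X.shape[1]
    if family == "logistic":
        _, aic, _ = _fit_logistic(y, X)
        return aic
    observed = np.unique(y)
    codes = np.searchsorted(observed, y).astype(int)
    _, _, aic, _ = _fit_ordinal(codes, X, len(observed))
    return aic


def select_covariates_aic(
    dataset: TrialDataset,
    base_terms: Sequence[str],
    candidates: Sequence[str],
    family: str = "linear",
    target: str = OUTCOME,
    categorical: Categorical | None = None,
) -> list[str]:
    """Greedy forward selection: repeatedly add the candidate with the
    largest AIC decrease; stop when no candidate strictly decreases AIC."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if categorical is None:
        categorical = {k: (tuple(v), v[0]) for k, v in NOMINAL_COVARIATES.items()}
    selected = list(base_terms)
    pool = [c for c in candidates if c not in selected]

    if family == "linear":
        # cache each term's design columns once; candidate fits are then
        # cheap least-squares solves
        df = dataset.df.dropna(subset=[target])
        y = df[target].to_numpy(dtype=float)
        n = len(y)
        blocks = {
            t: build_design(df, [t], categorical, intercept=False)[0]
            for t in set(selected) | set(pool)
        }

        def aic_of(terms: Sequence[str]) -> float:
            X = np.column_stack([np.ones(n)] + [blocks[t] for t in terms])
            resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
            ssr = float(resid @ resid)
            return n * np.log(max(ssr, 1e-300) / n) + 2 * X.shape[1]

    else:

        def aic_of(terms: Sequence[str]) -> float:
            return _aic_for(dataset, target, terms, family, categorical)

    current = aic_of(selected)
    while pool:
        aics = [(aic_of(selected + [c]), c) for c in pool]
        best_aic, best = min(aics, key=lambda t: t[0])
        if best_aic >= current:
            break
        selected.append(best)
        pool.remove(best)
        current = best_aic
    return selected


def draw_mediator(
    model: FittedModel,
    covariate_data,
    arm_level: int,
    parent_value: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    u: np.ndarray | None = None,
) -> np.ndarray:
    """Subject-specific stochastic draw of a mediator at a set arm level.

    For a treated-only mediator at ``arm_level=0`` the fitted model is
    bypassed and the unexposed reference level is returned with
    probability 1.
    """
    if isinstance(covariate_data, pd.DataFrame):
        n = len(covariate_data)
        data = {c: covariate_data[c].to_numpy(dtype=float) for c in covariate_data.columns}
    else:
        data = dict(covariate_data)
        n = len(next(iter(data.values())))
    if model.treated_only and arm_level == 0:
        return np.full(n, model.reference)
    data[ARM] = np.full(n, float(arm_level))
    if parent_value is not None:
        if model.parent is None:
            raise ValueError(f"{model.target} declares no within-block parent")
        data[model.parent] = np.asarray(parent_value, dtype=float)
    if rng is None and u is None:
        raise ValueError("provide rng or u")
    return model.draw(data, rng, u=u)
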