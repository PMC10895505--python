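"""Interventional effect decomposition by Monte-Carlo g-computation.

For each subject i and Monte-Carlo copy j, block values G_k(a) are drawn
from the fitted mediator models given covariates at arm level a (treated-
only blocks are degenerate at the unexposed reference under a=0).  With g
the outcome model's linear predictor and blocks in the configured order
(B1, B2, B3), per-(i, j) contrasts are

    TE  = g(1, G1(1), G2(1), G3(1)) - g(0, G1(0), G2(0), G3(0))
    DE  = g(1, G1(0), G2(0), G3(0)) - g(0, G1(0), G2(0), G3(0))
    IE1 = g(1, G1(1), G2(0), G3(0)) - g(1, G1(0), G2(0), G3(0))
    IE2 = g(1, G1(1), G2(1), G3(0)) - g(1, G1(1), G2(0), G3(0))
    IE3 = g(1, G1(1), G2(1), G3(1)) - g(1, G1(1), G2(1), G3(0))

averaged over all (i, j).  The same draws G_k(a) are reused in every term
in which they appear, so the telescoping identity DE + IE1 + IE2 + IE3 = TE
holds exactly, not just in expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .design import build_design
from .models import FittedModel
from .schema import ARM, COVARIATES, NOMINAL_COVARIATES, OUTCOME, BlockStructure, TrialDataset

#: below this |total| (PHQ-9 points) the proportion mediated is undefined
DEGENERATE_TOTAL_TOL = 1e-6


@dataclass(frozen=True)
class MonteCarloConfig:
    """Controls the Monte-Carlo integration over counterfactual draws."""

    m_copies: int = 1000
    seed: int = 0
    block_order: tuple[str, ...] | None = None  # default: declared order
    common_random_numbers: bool = True

    def __post_init__(self) -> None:
        if self.m_copies < 1:
            raise ValueError("m_copies must be >= 1")


@dataclass(frozen=True)
class EffectDecomposition:
    """Total/direct/indirect effects on the PHQ-9 mean-difference scale."""

    total: float
    direct: float
    indirect: Mapping[str, float]
    m_copies: int
    seed: int

    @property
    def additivity_residual(self) -> float:
        return self.direct + sum(self.indirect.values()) - self.total

    def as_dict(self) -> dict[str, float]:
        out = {"total": self.total, "direct": self.direct}
        out.update({f"indirect_{k}": v for k, v in self.indirect.items()})
        return out

    def effect_names(self) -> list[str]:
        return list(self.as_dict())


def proportion_mediated(decomp: EffectDecomposition, block: str) -> float:
    """Percent of the total effect mediated through one block."""
    if abs(decomp.total) < DEGENERATE_TOTAL_TOL:
        raise ZeroDivisionError(
            f"total effect {decomp.total:g} is below {DEGENERATE_TOTAL_TOL:g}; "
            "proportion mediated is undefined"
        )
    return 100.0 * decomp.indirect[block] / decomp.total


class _BlockSampler:
    """Draws one block's mediators for a chunk of expanded rows, reusing
    uniforms/normals across arm levels when common random numbers are on.

    Mediator models are additive in covariates, arm and the within-block
    parent, so the covariate part of each linear predictor is computed once
    per subject and the arm/parent contributions are added per draw.
    """

    def __init__(self, structure: BlockStructure, block: str, models: Mapping[str, FittedModel], crn: bool):
        self.mediators = structure.mediators_in(block)
        self.specs = {m: structure.spec(m) for m in self.mediators}
        self.models = {m: models[m] for m in self.mediators}
        self.crn = crn
        self._base: dict[str, np.ndarray] = {}
        self._arm_coef: dict[str, float] = {}
        self._parent_coef: dict[str, float] = {}

    def precompute(self, cov_df: pd.DataFrame) -> None:
        n = len(cov_df)
        for m in self.mediators:
            model, spec = self.models[m], self.specs[m]
            if model.degenerate:
                self._base[m] = np.full(n, model.constant_value)
                self._arm_coef[m] = self._parent_coef[m] = 0.0
                continue
            data = {c: cov_df[c].to_numpy(dtype=float) for c in cov_df.columns}
            data[ARM] = np.zeros(n)
            if spec.parent is not None:
                data[spec.parent] = np.zeros(n)
            self._base[m] = model.linear_predictor(data)
            coef = dict(zip(model.predictor_names, model.coefficients))
            self._arm_coef[m] = float(coef.get(ARM, 0.0))
            self._parent_coef[m] = float(coef.get(spec.parent, 0.0)) if spec.parent else 0.0

    def _draw_from_eta(self, model: FittedModel, eta: np.ndarray, u: np.ndarray) -> np.ndarray:
        if model.degenerate:
            return eta.copy()
        if model.family == "linear":
            out = eta + model.residual_sd * u
            if model.round_to_levels:
                lv = np.asarray(model.levels, dtype=float)
                out = np.clip(np.floor(out + 0.5), lv.min(), lv.max())
            return out
        if model.family == "logistic":
            lv = model.levels or (0, 1)
            from scipy.special import expit

            return np.where(u < expit(eta), float(lv[-1]), float(lv[0]))
        cum = 1.0 / (1.0 + np.exp(-(model.cutpoints[None, :] - eta[:, None])))
        idx = (u[:, None] > cum).sum(axis=1)
        return np.asarray(model.levels, dtype=float)[idx]

    def draw(self, idx: np.ndarray, rng: np.random.Generator) -> dict[int, dict[str, np.ndarray]]:
        n = len(idx)
        variates = {}
        for m in self.mediators:
            kind = "normal" if self.models[m].family == "linear" else "uniform"
            per_arm = 1 if self.crn else 2
            vs = [
                rng.standard_normal(n) if kind == "normal" else rng.random(n)
                for _ in range(per_arm)
            ]
            variates[m] = vs if not self.crn else [vs[0], vs[0]]
        out: dict[int, dict[str, np.ndarray]] = {}
        for a in (0, 1):
            vals: dict[str, np.ndarray] = {}
            for m in self.mediators:
                model, spec = self.models[m], self.specs[m]
                if spec.treated_only and a == 0:
                    vals[m] = np.full(n, float(spec.reference))
                    continue
                eta = self._base[m][idx] + self._arm_coef[m] * a
                if spec.parent is not None:
                    eta = eta + self._parent_coef[m] * vals[spec.parent]
                vals[m] = self._draw_from_eta(model, eta, variates[m][a])
            out[a] = vals
        return out


def decompose(
    dataset: TrialDataset,
    structure: BlockStructure,
    mediator_models: Mapping[str, FittedModel],
    outcome_model: FittedModel,
    mc: MonteCarloConfig,
) -> EffectDecomposition:
    """Monte-Carlo g-computation decomposition of the total effect."""
    for m in structure.mediator_names:
        if m not in mediator_models:
            raise ValueError(f"no fitted model supplied for mediator {m}")
        if m not in outcome_model.terms:
            raise ValueError(f"outcome model does not contain mediator {m}")
    order = tuple(mc.block_order) if mc.block_order else structure.block_names
    if sorted(order) != sorted(structure.block_names):
        raise ValueError("block_order must be a permutation of the declared blocks")

    df = dataset.df
    n = len(df)
    rng = np.random.default_rng(mc.seed)
    samplers = {b: _BlockSampler(structure, b, mediator_models, mc.common_random_numbers) for b in order}

    cov_base = {c: df[c].to_numpy(dtype=float) for c in COVARIATES}
    for b in order:
        samplers[b].precompute(df[list(COVARIATES)])

    # split the outcome model into terms that are fixed given covariates and
    # terms touching arm or a mediator, which change across scenarios
    dynamic_vars = {ARM, *structure.mediator_names}
    static_terms, dynamic_terms = [], []
    for t in outcome_model.terms:
        parts = {p.strip() for p in t.split(":")}
        (dynamic_terms if parts & dynamic_vars else static_terms).append(t)
    coef = dict(zip(outcome_model.predictor_names, outcome_model.coefficients))

    def _coef_vector(names: Sequence[str]) -> np.ndarray:
        return np.array([coef[nm] for nm in names])

    # scenarios: (arm, number of leading blocks switched to their a=1 draws)
    n_blocks = len(order)
    scen_sums = np.zeros(n_blocks + 2)  # [g(0, none), g(1, none), g(1, upto1), ..., g(1, all)]
    total_rows = 0

    chunk = max(1, min(mc.m_copies, int(2_000_000 // max(n, 1)) or 1))
    done = 0
    while done < mc.m_copies:
        c = min(chunk, mc.m_copies - done)
        done += c
        idx = np.tile(np.arange(n), c)
        cov_data = {k: v[idx] for k, v in cov_base.items()}
        rows = n * c
        total_rows += rows

        X_s, names_s = build_design(cov_data, static_terms, outcome_model.categorical)
        static_sum = float((X_s @ _coef_vector(names_s)).sum())

        draws = {b: samplers[b].draw(idx, rng) for b in order}

        def g_sum(arm_value: float, k_switched: int) -> float:
            data = dict(cov_data)
            data[ARM] = np.full(rows, arm_value)
            for j, b in enumerate(order):
                a = 1 if j < k_switched else 0
                data.update(draws[b][a])
            X_d, names_d = build_design(
                data, dynamic_terms, outcome_model.categorical, intercept=False
            )
            return static_sum + float((X_d @ _coef_vector(names_d)).sum())

        scen_sums[0] += g_sum(0.0, 0)
        for k in range(n_blocks + 1):
            scen_sums[1 + k] += g_sum(1.0, k)

    means = scen_sums / total_rows
    direct = means[1] - means[0]
    indirect = {order[k]: means[2 + k] - means[1 + k] for k in range(n_blocks)}
    total = means[1 + n_blocks] - means[0]
    return EffectDecomposition(
        total=float(total),
        direct=float(direct),
        indirect={b: float(indirect[b]) for b in structure.block_names},
        m_copies=mc.m_copies,
        seed=mc.seed,
    )


def total_effect_regression(dataset: TrialDataset, covariates: Sequence[str] = ()) -> float:
    """Arm coefficient of a linear outcome fit without mediators; serves as a
    cross-check of the Monte-Carlo total effect."""
    df = dataset.df
    if df[OUTCOME].isna().any():
        raise ValueError("outcome has missing values; impute first")
    categorical = {k: (tuple(v), v[0]) for k, v in NOMINAL_COVARIATES.items() if k in covariates}
    X, names = build_design(df, [ARM] + list(covariates), categorical)
    res = sm.OLS(df[OUTCOME].to_numpy(dtype=float), X).fit()
    return float(res.params[names.index(ARM)])


def serialise_decomposition(decomp: EffectDecomposition, structure: BlockStructure) -> str:
    """Structured text mirroring the published effects table layout."""
    lines = [f"total\t{decomp.total:.6f}", f"direct\t{decomp.direct:.6f}"]
    for b in structure.block_names:
        lines.append(f"indirect_{b}\t{decomp.indirect[b]:.6f}")
    for b in structure.block_names:
        try:
            pm = proportion_mediated(decomp, b)
            lines.append(f"proportion_mediated_{b}\t{pm:.2f}")
        except ZeroDivisionError:
            lines.append(f"proportion_mediated_{b}\tundefined")
    return "\n".join(lines) + "\n"
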