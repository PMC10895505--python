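"""The full estimation pipeline: imputation -> model fits -> decomposition.

One `MediationPipeline` instance captures everything that is fixed across
bootstrap resamples (block structure, covariate lists, Monte-Carlo size);
calling it on a dataset with an rng performs one complete estimation with
a fresh single imputation, which is exactly the unit of work the cluster
bootstrap re-executes per resample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .effects import EffectDecomposition, MonteCarloConfig, decompose
from .imputation import ImputationSpec, impute_chained
from .models import FittedModel, fit_mediator_model, fit_outcome_model, select_covariates_aic
from .schema import ARM, COVARIATES, NOMINAL_COVARIATES, BlockStructure, TrialDataset, default_block_structure


@dataclass
class MediationPipeline:
    """Maps a dataset to an EffectDecomposition.

    ``mediator_covariates`` are included in every mediator model (the trial
    analysis kept age, education, baseline PHQ-9, expectations and marital
    status, chosen by AIC).  Outcome-model confounders are selected per run
    by greedy AIC forward search among ``outcome_candidates`` on top of arm
    and the mediators.
    """

    structure: BlockStructure = field(default_factory=default_block_structure)
    imputation: ImputationSpec | None = field(default_factory=ImputationSpec)
    mediator_covariates: Sequence[str] = COVARIATES
    outcome_candidates: Sequence[str] = COVARIATES
    select_outcome_covariates: bool = True
    interactions: Sequence[str] = ()
    mc: MonteCarloConfig = field(default_factory=MonteCarloConfig)

    def fit_models(self, dataset: TrialDataset) -> tuple[dict[str, FittedModel], FittedModel, list[str]]:
        mediator_models = {
            m: fit_mediator_model(dataset, m, self.structure, self.mediator_covariates)
            for m in self.structure.mediator_names
        }
        base = [ARM] + list(self.structure.mediator_names)
        if self.select_outcome_covariates:
            categorical = {k: (tuple(v), v[0]) for k, v in NOMINAL_COVARIATES.items()}
            categorical.update(self.structure.categorical_levels())
            selected = select_covariates_aic(
                dataset, base, self.outcome_candidates, family="linear", categorical=categorical
            )
            confounders = [t for t in selected if t not in base]
        else:
            confounders = list(self.outcome_candidates)
        outcome_model = fit_outcome_model(dataset, self.structure, confounders, self.interactions)
        return mediator_models, outcome_model, confounders

    def __call__(self, dataset: TrialDataset, rng: np.random.Generator) -> EffectDecomposition:
        has_missing = any(
            np.isnan(dataset.df[c].to_numpy(dtype=float)).any() for c in ("m2", "phq9_12m")
        )
        if self.imputation is not None and has_missing:
            seed = int(rng.integers(0, 2**31 - 1))
            dataset = impute_chained(dataset, self.imputation, np.random.default_rng(seed))
        mediator_models, outcome_model, _ = self.fit_models(dataset)
        mc = MonteCarloConfig(
            m_copies=self.mc.m_copies,
            seed=int(rng.integers(0, 2**31 - 1)),
            block_order=self.mc.block_order,
            common_random_numbers=self.mc.common_random_numbers,
        )
        return decompose(dataset, self.structure, mediator_models, outcome_model, mc)
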