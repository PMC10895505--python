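"""Cluster bootstrap with bias-corrected percentile intervals.

Each resample draws clinics (clusters) with replacement, keeping every
drawn clinic's full membership, and re-executes the entire estimation
pipeline — a fresh single imputation, model fits, and the Monte-Carlo
decomposition — with a resample-specific seed.  Intervals are BC (bias
corrected, no acceleration): the bias factor z0 is the normal quantile of
the fraction of replicates below the point estimate (ties counted half),
and the bounds are empirical quantiles at Phi(2 z0 + z_{alpha/2}) and
Phi(2 z0 + z_{1-alpha/2}).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .effects import EffectDecomposition
from .schema import CLUSTER, TrialDataset

logger = logging.getLogger(__name__)

#: pipeline contract: (dataset, rng) -> EffectDecomposition
Pipeline = Callable[[TrialDataset, np.random.Generator], EffectDecomposition]


@dataclass(frozen=True)
class BootstrapConfig:
    n_resamples: int = 1000
    alpha: float = 0.05
    resample_unit: str = "cluster"  # cluster | subject
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.resample_unit not in ("cluster", "subject"):
            raise ValueError("resample_unit must be 'cluster' or 'subject'")


@dataclass(frozen=True)
class BootstrapResult:
    point: EffectDecomposition
    replicates: Mapping[str, np.ndarray]
    intervals: Mapping[str, tuple[float, float]]
    n_failed: int
    alpha: float

    def replicates_frame(self) -> pd.DataFrame:
        """Replicate vectors as a table, exportable for diagnostics."""
        return pd.DataFrame({k: np.asarray(v) for k, v in self.replicates.items()})


def bc_interval(point: float, replicates: np.ndarray, alpha: float = 0.05) -> tuple[float, float]:
    """Bias-corrected percentile interval from bootstrap replicates."""
    reps = np.asarray(replicates, dtype=float)
    if reps.size == 0:
        raise ValueError("replicates must be non-empty")
    if np.all(reps == point):
        warnings.warn("all bootstrap replicates equal the point estimate; degenerate interval")
        return (float(point), float(point))
    b = reps.size
    frac = (np.sum(reps < point) + 0.5 * np.sum(reps == point)) / b
    if frac <= 0.0 or frac >= 1.0:
        clamp = norm.ppf(1.0 - 1.0 / (2.0 * b))
        z0 = clamp if frac >= 1.0 else -clamp
        logger.info("bias factor clamped to %+.3f (all replicates on one side)", z0)
    else:
        z0 = norm.ppf(frac)
    lo_level = norm.cdf(2.0 * z0 + norm.ppf(alpha / 2.0))
    hi_level = norm.cdf(2.0 * z0 + norm.ppf(1.0 - alpha / 2.0))
    lo = float(np.quantile(reps, lo_level))  # linear interpolation between order stats
    hi = float(np.quantile(reps, hi_level))
    return (lo, hi)


def _resample(dataset: TrialDataset, unit: str, rng: np.random.Generator) -> TrialDataset:
    df = dataset.df
    if unit == "subject":
        idx = rng.integers(0, len(df), size=len(df))
        out = df.iloc[idx].reset_index(drop=True)
        return TrialDataset(df=out, integer_scores=dataset.integer_scores)
    clusters = np.sort(df[CLUSTER].unique())
    drawn = rng.choice(clusters, size=len(clusters), replace=True)
    parts = []
    for new_id, c in enumerate(drawn, start=1):
        part = df[df[CLUSTER] == c].copy()
        part[CLUSTER] = new_id  # each draw becomes its own clinic copy
        parts.append(part)
    out = pd.concat(parts, ignore_index=True)
    return TrialDataset(df=out, integer_scores=dataset.integer_scores)


def cluster_bootstrap(
    dataset: TrialDataset, pipeline: Pipeline, config: BootstrapConfig
) -> BootstrapResult:
    """Nonparametric bootstrap of the full estimation pipeline.

    The point estimate is computed on the original data; each of the
    ``n_resamples`` resamples re-runs ``pipeline`` (which performs its own
    single imputation) with an independent child seed.  Failed resamples
    are logged, counted, and excluded — never retried.
    """
    if dataset.n_clusters < 1:
        raise ValueError("dataset has no clusters")
    if config.resample_unit == "cluster" and dataset.n_clusters == 1:
        warnings.warn("only one cluster: cluster resampling is degenerate")

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_resamples + 1)
    point = pipeline(dataset, np.random.default_rng(seeds[0]))
    names = point.effect_names()

    reps: dict[str, list[float]] = {k: [] for k in names}
    n_failed = 0
    for i in range(config.n_resamples):
        rng = np.random.default_rng(seeds[i + 1])
        boot = _resample(dataset, config.resample_unit, rng)
        try:
            est = pipeline(boot, rng)
        except Exception as exc:  # noqa: BLE001 - any estimation failure is dropped
            n_failed += 1
            logger.warning("bootstrap resample %d failed: %s", i, exc)
            continue
        for k, v in est.as_dict().items():
            reps[k].append(v)
    if n_failed == config.n_resamples:
        raise RuntimeError("all bootstrap resamples failed")

    replicates = {k: np.asarray(v) for k, v in reps.items()}
    point_vals = point.as_dict()
    intervals = {
        k: bc_interval(point_vals[k], replicates[k], config.alpha) for k in names
    }
    return BootstrapResult(
        point=point,
        replicates=replicates,
        intervals=intervals,
        n_failed=n_failed,
        alpha=config.alpha,
    )
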