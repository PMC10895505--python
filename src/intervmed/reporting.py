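"""End-to-end analysis runner and report tables.

``run_analysis`` reads a trial table, validates it against the canonical
schema, runs imputation, model fits, the Monte-Carlo decomposition and the
cluster bootstrap, and writes three text artefacts to the output
directory: an effects table (point estimates, BC intervals, percent
mediated), a remission comparison table for the experimental arm, and a
YAML run manifest recording configuration, seeds and software versions.
"""

from __future__ import annotations

import dataclasses
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .effects import DEGENERATE_TOTAL_TOL, MonteCarloConfig, proportion_mediated
from .imputation import ImputationSpec, impute_chained
from .pipeline import MediationPipeline
from .schema import (
    ARM,
    MEDIATORS,
    OUTCOME,
    BlockStructure,
    SchemaError,
    TrialDataset,
    default_block_structure,
)
from .uncertainty import BootstrapConfig, BootstrapResult, cluster_bootstrap

#: PHQ-9 score below which a participant counts as remitted
DEFAULT_REMISSION_THRESHOLD = 10.0


@dataclass
class AnalysisConfig:
    """Configuration of one full analysis run."""

    input_path: str
    output_dir: str
    column_map: Mapping[str, str] | None = None
    structure: BlockStructure = field(default_factory=default_block_structure)
    imputation: ImputationSpec = field(default_factory=ImputationSpec)
    mc: MonteCarloConfig = field(default_factory=MonteCarloConfig)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    remission_threshold: float = DEFAULT_REMISSION_THRESHOLD
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.remission_threshold <= 27.0):
            raise ValueError("remission_threshold must lie in (0, 27]")


def remission_table(
    dataset: TrialDataset, threshold: float = DEFAULT_REMISSION_THRESHOLD
) -> pd.DataFrame:
    """Mediator summaries by 12-month remission status, experimental arm only.

    Remission is outcome score strictly below ``threshold``.  Continuous
    mediators are summarised by mean (SD); categorical mediators by percent
    in each level.
    """
    df = dataset.df
    if df[OUTCOME].isna().any():
        raise ValueError("outcome has missing values; impute first")
    treated = df[df[ARM] == 1]
    if len(treated) == 0:
        raise ValueError("no treated records")
    remit = treated[OUTCOME] < threshold
    groups = {"remission": treated[remit], "no_remission": treated[~remit]}
    for name, g in groups.items():
        if len(g) == 0:
            import warnings

            warnings.warn(f"remission table: group {name!r} is empty")

    rows = []
    for m in MEDIATORS:
        if m == "m2":
            row = {"mediator": m, "statistic": "mean (sd)"}
            for name, g in groups.items():
                row[name] = (
                    f"{g[m].mean():.1f} ({g[m].std():.1f})" if len(g) else ""
                )
            row["n_remission"] = int(remit.sum())
            row["n_no_remission"] = int((~remit).sum())
            rows.append(row)
        else:
            levels = sorted(treated[m].unique())
            for lv in levels:
                row = {"mediator": m, "statistic": f"level {lv:g} (%)"}
                for name, g in groups.items():
                    row[name] = f"{100.0 * (g[m] == lv).mean():.1f}" if len(g) else ""
                row["n_remission"] = int(remit.sum())
                row["n_no_remission"] = int((~remit).sum())
                rows.append(row)
    return pd.DataFrame(rows)


def effects_table(result: BootstrapResult, structure: BlockStructure) -> pd.DataFrame:
    """Point estimates with BC intervals and percent mediated, one row per
    effect, printed at one decimal (percent mediated as whole percents)."""
    d = result.point
    labels = {
        "total": "Total effect",
        "direct": "Direct effect",
        "indirect_sessions": "Indirect: characteristics of sessions (M1)",
        "indirect_activation": "Indirect: behavioural activation (M2)",
        "indirect_response": "Indirect: non-response and extra sessions (M3)",
    }
    rows = []
    for key, value in d.as_dict().items():
        lo, hi = result.intervals[key]
        row = {
            "effect": labels.get(key, key),
            "estimate": f"{value:.1f}",
            "bc_95_ci": f"({lo:.1f}, {hi:.1f})",
        }
        if key.startswith("indirect_") and abs(d.total) >= DEGENERATE_TOTAL_TOL:
            row["pct_mediated"] = f"{proportion_mediated(d, key.removeprefix('indirect_')):.0f}"
        else:
            row["pct_mediated"] = ""
        rows.append(row)
    return pd.DataFrame(rows)


def _manifest(config: AnalysisConfig, dataset: TrialDataset, result: BootstrapResult) -> dict:
    return {
        "intervmed_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "input": str(config.input_path),
        "n_subjects": len(dataset),
        "n_clusters": int(dataset.n_clusters),
        "n_missing": dataset.n_missing(),
        "seed": int(config.seed),
        "mc_copies": int(config.mc.m_copies),
        "n_resamples": int(config.bootstrap.n_resamples),
        "n_failed_resamples": int(result.n_failed),
        "alpha": float(config.bootstrap.alpha),
        "resample_unit": config.bootstrap.resample_unit,
        "remission_threshold": float(config.remission_threshold),
        "point_estimates": {k: float(v) for k, v in result.point.as_dict().items()},
        "intervals": {k: [float(lo), float(hi)] for k, (lo, hi) in result.intervals.items()},
    }


def run_analysis(config: AnalysisConfig, dataset: TrialDataset | None = None):
    """Run the complete analysis and write report files.

    Returns (BootstrapResult, dict of output paths).  ``dataset`` may be
    passed directly (e.g. a freshly generated synthetic trial); otherwise
    it is read from ``config.input_path``.
    """
    if dataset is None:
        dataset = TrialDataset.from_csv(config.input_path, column_map=config.column_map)
    violations = dataset.validate(strict=False)
    if violations:
        raise SchemaError(violations)
    if (dataset.df[ARM] == 1).sum() == 0 or (dataset.df[ARM] == 0).sum() == 0:
        raise SchemaError(["both trial arms must be populated"])

    pipeline = MediationPipeline(
        structure=config.structure, imputation=config.imputation, mc=config.mc
    )
    boot_cfg = dataclasses.replace(config.bootstrap, seed=config.seed)
    result = cluster_bootstrap(dataset, pipeline, boot_cfg)

    # the remission table is reported on imputed data
    imputed = impute_chained(
        dataset, config.imputation, np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    )

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "effects": outdir / "effects_table.csv",
        "remission": outdir / "remission_table.csv",
        "replicates": outdir / "bootstrap_replicates.csv",
        "manifest": outdir / "manifest.yaml",
    }
    effects_table(result, config.structure).to_csv(paths["effects"], index=False)
    remission_table(imputed, config.remission_threshold).to_csv(paths["remission"], index=False)
    result.replicates_frame().to_csv(paths["replicates"], index=False)
    paths["manifest"].write_text(yaml.safe_dump(_manifest(config, dataset, result), sort_keys=False))
    return result, paths
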