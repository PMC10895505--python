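"""Canonical trial schema: columns, mediator block structure, dataset container.

The analysis operates on a two-arm individually randomised depression trial
with clinic-level clustering.  The outcome is the PHQ-9 score at 12 months
(0-27, continuous in the analysis); mediators are grouped into three ordered
blocks, each of which receives one interventional indirect effect:

* sessions   — M1a, phase of counselling sessions completed (0 none .. 3
               phase 3) and M1b, proportion of homework completed (0 none,
               1 <=50%, 2 >50%);
* activation — M2, behavioural activation (BADS-SF score, continuous,
               measured in both arms);
* response   — M3a, responded to treatment (binary) and M3b, number of extra
               sessions offered on non-response (0, 1, 2).

M1a, M1b, M3a and M3b exist only under the intervention: in the control arm
they sit at a degenerate "unexposed" reference category (0).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: baseline covariates measured before randomisation
COVARIATES = ("age", "education", "marital_status", "expectations", "phq9_baseline")

#: mediators in causal/temporal order
MEDIATORS = ("m1a", "m1b", "m2", "m3a", "m3b")

OUTCOME = "phq9_12m"
ARM = "arm"
CLUSTER = "cluster_id"
SUBJECT = "subject_id"

#: canonical column order of a trial table
COLUMNS = (SUBJECT, CLUSTER, ARM) + COVARIATES + MEDIATORS + (OUTCOME,)

#: nominal covariates expanded to indicator contrasts in design matrices
NOMINAL_COVARIATES: Mapping[str, tuple[int, ...]] = {"marital_status": (0, 1, 2)}


@dataclass(frozen=True)
class MediatorSpec:
    """Declares how one mediator is modelled and drawn.

    ``levels`` is None for a genuinely continuous mediator; for categorical
    mediators it is the full level set with ``reference`` the "unexposed"
    category.  ``treated_only`` mediators are degenerate at the reference in
    the control arm; ``parent`` names the within-block predecessor included
    as a predictor in this mediator's model.
    """

    name: str
    family: str  # linear | ordinal | logistic
    block: str
    levels: tuple[int, ...] | None = None
    reference: int = 0
    treated_only: bool = True
    parent: str | None = None

    def __post_init__(self) -> None:
        if self.family not in ("linear", "ordinal", "logistic"):
            raise ValueError(f"unknown family {self.family!r} for {self.name}")
        if self.levels is not None and self.reference not in self.levels:
            raise ValueError(f"reference level {self.reference} of {self.name} not in level set")


@dataclass(frozen=True)
class BlockStructure:
    """Ordered mediator blocks, each carrying one indirect effect."""

    blocks: tuple[tuple[str, tuple[str, ...]], ...]
    mediators: tuple[MediatorSpec, ...]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        declared = {m.name for m in self.mediators}
        for block, meds in self.blocks:
            for m in meds:
                if m in seen:
                    raise ValueError(f"mediator {m} assigned to both {seen[m]} and {block}")
                if m not in declared:
                    raise ValueError(f"mediator {m} in block {block} has no MediatorSpec")
                seen[m] = block
        for spec in self.mediators:
            if spec.name not in seen:
                raise ValueError(f"mediator {spec.name} belongs to no block")
            if spec.parent is not None and seen.get(spec.parent) != seen[spec.name]:
                raise ValueError(f"parent of {spec.name} must be in the same block")

    @property
    def block_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.blocks)

    def mediators_in(self, block: str) -> tuple[str, ...]:
        for name, meds in self.blocks:
            if name == block:
                return meds
        raise KeyError(block)

    def spec(self, mediator: str) -> MediatorSpec:
        for m in self.mediators:
            if m.name == mediator:
                return m
        raise KeyError(mediator)

    @property
    def mediator_names(self) -> tuple[str, ...]:
        return tuple(m for _, meds in self.blocks for m in meds)

    def categorical_levels(self) -> dict[str, tuple[tuple[int, ...], int]]:
        """Mediator -> (levels, reference) for indicator expansion; binary and
        continuous mediators are left as single numeric columns."""
        out = {}
        for m in self.mediators:
            if m.levels is not None and len(m.levels) > 2:
                out[m.name] = (m.levels, m.reference)
        return out


def default_block_structure() -> BlockStructure:
    """The three-block structure of the trial: sessions, activation, response."""
    mediators = (
        MediatorSpec("m1a", "linear", "sessions", levels=(0, 1, 2, 3)),
        MediatorSpec("m1b", "ordinal", "sessions", levels=(0, 1, 2), parent="m1a"),
        MediatorSpec("m2", "linear", "activation", treated_only=False),
        MediatorSpec("m3a", "logistic", "response", levels=(0, 1)),
        MediatorSpec("m3b", "ordinal", "response", levels=(0, 1, 2), parent="m3a"),
    )
    blocks = (
        ("sessions", ("m1a", "m1b")),
        ("activation", ("m2",)),
        ("response", ("m3a", "m3b")),
    )
    return BlockStructure(blocks=blocks, mediators=mediators)


class SchemaError(ValueError):
    """Raised when a trial table violates the canonical schema."""

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        super().__init__("trial table schema violations:\n  " + "\n  ".join(self.violations))


@dataclass
class TrialDataset:
    """Subject-level trial table; the single source of truth for all stages.

    Wraps a DataFrame with the canonical columns.  Missing values (allowed
    only in ``m2`` and ``phq9_12m``) are NaN.
    """

    df: pd.DataFrame
    integer_scores: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError([f"missing column {c}" for c in missing])
        self.df = self.df.loc[:, list(COLUMNS)].reset_index(drop=True)

    # -- basic properties -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_clusters(self) -> int:
        return self.df[CLUSTER].nunique()

    @property
    def arm(self) -> np.ndarray:
        return self.df[ARM].to_numpy()

    def n_missing(self) -> dict[str, int]:
        return {c: int(self.df[c].isna().sum()) for c in ("m2", OUTCOME)}

    def validate(self, strict: bool = True) -> list[str]:
        """Check TrialRecord invariants; return violations (raise if strict)."""
        df = self.df
        v: list[str] = []
        if not df[ARM].isin([0, 1]).all():
            v.append("arm must be 0/1")
        else:
            ctrl = df[ARM] == 0
            for m in ("m1a", "m1b", "m3a", "m3b"):
                if (df.loc[ctrl, m] != 0).any():
                    v.append(f"control-arm records must have {m} at the unexposed level 0")
            if ((df["m1b"] > 0) & (df["m1a"] < 1)).any():
                v.append("m1b > 0 requires m1a >= 1 (homework requires a session)")
            if ((df["m3b"] > 0) & (df["m3a"] != 0)).any():
                v.append("m3b > 0 requires m3a = 0 (extra sessions only on non-response)")
        if (df["phq9_baseline"] <= 14).any():
            v.append("phq9_baseline must exceed 14 (trial eligibility)")
        for col, lo, hi in (("m1a", 0, 3), ("m1b", 0, 2), ("m3a", 0, 1), ("m3b", 0, 2)):
            if (~df[col].isin(range(lo, hi + 1))).any():
                v.append(f"{col} outside level set {list(range(lo, hi + 1))}")
        y = df[OUTCOME].dropna()
        if self.integer_scores and len(y) and ((y < 0) | (y > 27)).any():
            v.append("phq9_12m outside [0, 27]")
        for c in COLUMNS:
            if c in ("m2", OUTCOME):
                continue
            if df[c].isna().any():
                v.append(f"missing values not allowed in {c}")
        if strict and v:
            raise SchemaError(v)
        return v

    # -- IO ---------------------------------------------------------------
    def to_csv(self, path_or_buf=None) -> str | None:
        """Write as comma-separated text; empty field encodes missing."""
        return self.df.to_csv(path_or_buf, index=False, na_rep="")

    @classmethod
    def from_csv(
        cls,
        path_or_buf,
        column_map: Mapping[str, str] | None = None,
        integer_scores: bool = False,
        validate: bool = True,
    ) -> "TrialDataset":
        """Read a delimited trial table.

        ``column_map`` maps canonical names to the file's column names, so an
        externally deposited table can be adapted without code changes.
        """
        df = pd.read_csv(path_or_buf)
        if column_map:
            unknown = [src for src in column_map.values() if src not in df.columns]
            if unknown:
                raise SchemaError([f"mapped column {c} not in input" for c in unknown])
            df = df.rename(columns={src: dst for dst, src in column_map.items()})
        ds = cls(df=df, integer_scores=integer_scores)
        if validate:
            ds.validate()
        return ds

    def copy(self) -> "TrialDataset":
        return replace(self, df=self.df.copy())

    def equals(self, other: "TrialDataset") -> bool:
        return self.df.equals(other.df)
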