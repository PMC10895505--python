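"""Design-matrix construction shared by all regression fits and predictions.

A term is either a column name or a ``a:b`` interaction.  Columns declared
categorical are expanded to indicator contrasts against their reference
level using the *declared* level set, so design matrices keep identical
columns across bootstrap resamples even when a level is unobserved.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

# categorical declaration: column -> (levels, reference)
Categorical = Mapping[str, tuple[Sequence[int], int]]


def _column(data, name: str) -> np.ndarray:
    if isinstance(data, pd.DataFrame):
        if name not in data.columns:
            raise KeyError(f"design term {name!r} not in data")
        return np.asarray(data[name], dtype=float)
    if name not in data:
        raise KeyError(f"design term {name!r} not in data")
    return np.asarray(data[name], dtype=float)


def _expand(data, name: str, categorical: Categorical) -> list[tuple[str, np.ndarray]]:
    if name in categorical:
        levels, ref = categorical[name]
        x = _column(data, name)
        return [(f"{name}[{lv}]", (x == lv).astype(float)) for lv in levels if lv != ref]
    return [(name, _column(data, name))]


def build_design(
    data,
    terms: Sequence[str],
    categorical: Categorical | None = None,
    intercept: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Build (X, column_names) from a DataFrame or dict of equal-length arrays."""
    categorical = categorical or {}
    cols: list[tuple[str, np.ndarray]] = []
    for term in terms:
        parts = [p.strip() for p in term.split(":")]
        expanded = _expand(data, parts[0], categorical)
        for part in parts[1:]:
            nxt = []
            for lbl, arr in expanded:
                for lbl2, arr2 in _expand(data, part, categorical):
                    nxt.append((f"{lbl}:{lbl2}", arr * arr2))
            expanded = nxt
        cols.extend(expanded)
    if not cols:
        n = len(data) if isinstance(data, pd.DataFrame) else len(next(iter(data.values())))
    else:
        n = len(cols[0][1])
    names = (["const"] if intercept else []) + [lbl for lbl, _ in cols]
    parts_arr = ([np.ones(n)] if intercept else []) + [arr for _, arr in cols]
    X = np.column_stack(parts_arr) if parts_arr else np.empty((n, 0))
    return X, names


def check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    """Raise naming the offending columns if X is rank deficient."""
    if X.shape[1] == 0:
        return
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # pivoted QR: columns beyond the numerical rank are the culprits
        from scipy.linalg import qr

        _, r, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
        bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        bad += [names[p] for p in piv[len(diag):]]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {', '.join(bad) or 'undetermined'}"
        )
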