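"""Internal design-matrix construction shared by weights and cox."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["design_matrix", "check_full_rank"]


def _is_categorical(s: pd.Series) -> bool:
    return (
        isinstance(s.dtype, pd.CategoricalDtype)
        or s.dtype == object
        or pd.api.types.is_bool_dtype(s)
    )


def design_matrix(
    df: pd.DataFrame,
    covariates: Sequence[str],
    *,
    intercept: bool = False,
) -> tuple[np.ndarray, list[str]]:
    """Numeric design matrix: numerics pass through, categoricals become
    drop-first indicators in declared (or first-appearance) level order."""
    cols: list[np.ndarray] = []
    names: list[str] = []
    if intercept:
        cols.append(np.ones(len(df)))
        names.append("intercept")
    for c in covariates:
        if c not in df.columns:
            raise KeyError(f"covariate '{c}' not in data")
        s = df[c]
        if _is_categorical(s):
            if not isinstance(s.dtype, pd.CategoricalDtype):
                s = pd.Categorical(s, categories=list(dict.fromkeys(s)))
            else:
                s = pd.Categorical(s)
            for lev in s.categories[1:]:
                cols.append((np.asarray(s) == lev).astype(float))
                names.append(f"{c}[{lev}]")
        else:
            cols.append(s.to_numpy(dtype=float))
            names.append(c)
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return X, names


def check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    """Raise naming (approximately) collinear columns if X is rank deficient."""
    if X.shape[1] == 0:
        return
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        diag = np.abs(np.diag(np.linalg.qr(X, mode="r")))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[i] for i in np.where(diag < tol)[0]]
        raise ValueError(
            f"design matrix is rank deficient (rank {r} < {X.shape[1]}); "
            f"collinear column(s): {bad or 'undetermined'}"
        )
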