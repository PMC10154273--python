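"""Pre-residualization of phenotypes on fixed-effect covariates.

The variance-component engine fits random effects only, so phenotypes are
first regressed (OLS) on an intercept plus covariates — typically age and
sex, optionally a practice-effect dummy for repeat assessments — and the
residuals carry forward. With this two-stage design the ML variance
fractions coincide with what a joint REML fit would give.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CovariateSpec",
    "ResidualizedPhenotype",
    "practice_indicator",
    "residualize",
]

PRACTICE_COLUMN = "practice"


@dataclass(frozen=True)
class CovariateSpec:
    """Which fixed-effect columns to residualize on.

    Numeric columns enter as-is; non-numeric columns are expanded to
    indicator contrasts against the lexicographically first level.
    ``include_practice`` adds the 0/1 repeat-assessment dummy (0 at a
    subject's first observation of the phenotype, 1 afterwards).
    """

    covariates: tuple[str, ...] = ()
    include_practice: bool = False

    def __post_init__(self):
        object.__setattr__(self, "covariates", tuple(self.covariates))


@dataclass
class ResidualizedPhenotype:
    """Residuals plus fit bookkeeping.

    ``values`` is indexed like the retained (complete-case) rows of the
    input table; ``df_used`` counts linearly independent regressors
    including the intercept — the degrees of freedom consumed before the
    unbiased total-variance estimate.
    """

    values: pd.Series
    df_used: int
    coefficients: dict[str, float]
    n_obs: int
    n_dropped: int
    dropped_columns: tuple[str, ...] = ()
    phenotype: str = ""

    def __post_init__(self):
        self.n_obs = int(self.n_obs)
        if self.n_obs != len(self.values):
            raise ValueError("n_obs does not match residual length")


def practice_indicator(
    table: pd.DataFrame,
    *,
    phenotype: str | None = None,
    subject_col: str = "subject_id",
    visit_col: str = "visit",
) -> pd.Series:
    """0/1 repeat-assessment dummy.

    For each subject, the earliest observation with non-missing phenotype
    (or earliest observation overall when ``phenotype`` is None) gets 0 —
    the first instance of data for that participant — and every later
    observation gets 1. Visits must be orderable and unique per subject.
    """
    for col in (subject_col, visit_col):
        if col not in table.columns:
            raise KeyError(f"required column {col!r} missing from table")
    if table.duplicated(subset=[subject_col, visit_col]).any():
        bad = table.loc[
            table.duplicated(subset=[subject_col, visit_col]), [subject_col, visit_col]
        ]
        raise ValueError(
            f"duplicate (subject, visit) rows: {bad.to_records(index=False).tolist()}"
        )

    if phenotype is not None:
        present = table[phenotype].notna()
    else:
        present = pd.Series(True, index=table.index)

    out = pd.Series(1, index=table.index, dtype=int)
    observed = table.loc[present]
    first_visit = observed.groupby(subject_col)[visit_col].transform("min")
    is_first = observed[visit_col] == first_visit
    out.loc[observed.index[is_first]] = 0
    out.loc[~present] = 0  # rows without data are not repeat assessments
    return out


def _design_matrix(
    table: pd.DataFrame, spec: CovariateSpec
) -> tuple[np.ndarray, list[str], list[str]]:
    """Intercept + covariate columns, categorical levels expanded against
    the lexicographically first level; collinear columns dropped greedily
    in column order. Returns (X, kept names, dropped names)."""
    cols: list[tuple[str, np.ndarray]] = [("intercept", np.ones(len(table)))]
    for name in spec.covariates:
        if name not in table.columns:
            raise KeyError(f"covariate {name!r} missing from table")
        col = table[name]
        if pd.api.types.is_numeric_dtype(col):
            cols.append((name, col.to_numpy(dtype=float)))
        else:
            levels = sorted(col.astype(str).unique())
            for lev in levels[1:]:  # reference = lexicographically first
                cols.append(
                    (f"{name}[{lev}]", (col.astype(str) == lev).to_numpy(float))
                )
    if spec.include_practice:
        cols.append((PRACTICE_COLUMN, table[PRACTICE_COLUMN].to_numpy(dtype=float)))

    kept: list[tuple[str, np.ndarray]] = []
    dropped: list[str] = []
    rank = 0
    for name, v in cols:
        candidate = np.column_stack([c for _, c in kept] + [v])
        new_rank = np.linalg.matrix_rank(candidate)
        if new_rank > rank:
            kept.append((name, v))
            rank = new_rank
        else:
            dropped.append(name)
    if dropped:
        logger.warning("dropped collinear design column(s): %s", dropped)
    X = np.column_stack([c for _, c in kept])
    return X, [n for n, _ in kept], dropped


def residualize(
    table: pd.DataFrame,
    spec: CovariateSpec,
    phenotype: str,
) -> ResidualizedPhenotype:
    """OLS-residualize one phenotype on intercept + covariates.

    Rows with a missing phenotype or any missing covariate are dropped
    (complete cases, counted per phenotype). Returns residuals aligned to
    the retained rows, the regressor degrees of freedom, and the fitted
    coefficients.
    """
    if phenotype not in table.columns:
        raise KeyError(f"phenotype {phenotype!r} missing from table")

    work = table.copy()
    if spec.include_practice:
        if PRACTICE_COLUMN not in work.columns:
            work[PRACTICE_COLUMN] = practice_indicator(work, phenotype=phenotype)

    needed = [phenotype, *spec.covariates]
    if spec.include_practice:
        needed.append(PRACTICE_COLUMN)
    for name in needed:
        if name not in work.columns:
            raise KeyError(f"covariate {name!r} missing from table")
    complete = work[needed].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info(
            "residualize(%s): dropped %d incomplete row(s), retained %d",
            phenotype, n_dropped, int(complete.sum()),
        )
    work = work.loc[complete]

    y = work[phenotype].to_numpy(dtype=float)
    X, names, dropped_cols = _design_matrix(work, spec)
    n, p = X.shape
    if n <= p:
        raise ValueError(
            f"too few complete observations ({n}) for {p} regressors"
        )

    if np.ptp(y) == 0.0:
        warnings.warn(
            f"phenotype {phenotype!r} has zero variance; residuals are all zero",
            stacklevel=2,
        )
        beta = np.zeros(p)
        beta[0] = y[0] if n else 0.0
        resid = np.zeros(n)
    else:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta

    return ResidualizedPhenotype(
        values=pd.Series(resid, index=work.index, name=phenotype),
        df_used=p,
        coefficients=dict(zip(names, beta.tolist())),
        n_obs=n,
        n_dropped=n_dropped,
        dropped_columns=tuple(dropped_cols),
        phenotype=phenotype,
    )
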