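"""Iterative forest-based imputation of categorical indicators.

Missing indicator categories are filled by a fully conditional,
non-parametric scheme in the missForest style: missing cells are
initialised with the per-variable mode, then the variables are cycled
in order of increasing missingness, each regressed on all others with a
random-forest classifier fitted on its observed rows and its missing
cells replaced by forest predictions. Iteration stops when the fraction
of imputed cells that changed rises compared to the previous sweep (the
usual proxy for the out-of-bag stopping rule), or after ``max_iter``
sweeps; on a rise the previous sweep's values are kept.

Single imputation only — the study design this mirrors fills each cell
once rather than pooling over multiple imputations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier


@dataclass
class ImputationResult:
    """Completed matrix plus the imputation trace."""

    completed: pd.DataFrame
    n_iterations_run: int
    change_fractions: list[float] = field(default_factory=list)
    seed: int = 0

    def as_log(self) -> dict:
        return {
            "n_iterations_run": self.n_iterations_run,
            "change_fractions": self.change_fractions,
            "seed": self.seed,
        }


def _mode(series: pd.Series):
    """Most frequent observed category; ties -> smallest category code."""
    counts = series.value_counts()
    top = counts[counts == counts.iloc[0]]
    return min(top.index)


def impute(
    matrix: pd.DataFrame,
    max_iter: int = 10,
    seed: int = 0,
    n_estimators: int = 100,
) -> ImputationResult:
    """Fill missing categories by iterative random-forest imputation.

    ``matrix`` holds integer category codes with missing cells as NA
    (nullable integer dtype). Observed cells are never modified.
    Deterministic under ``seed``: each forest gets a seed derived from
    the master seed, the variable index and the sweep number.
    """
    if matrix.shape[1] < 2:
        raise ValueError("imputation needs at least two variables")
    miss = matrix.isna()
    fully_missing = miss.all(axis=0)
    if fully_missing.any():
        name = fully_missing.index[fully_missing][0]
        raise ValueError(f"variable {name!r} has no observed values")

    n_missing = int(miss.to_numpy().sum())
    if n_missing == 0:
        return ImputationResult(matrix.copy(), 0, [], seed)

    # mode initialisation, then sweeps over variables by increasing missingness
    work = matrix.copy()
    for col in work.columns:
        if miss[col].any():
            work.loc[miss[col], col] = _mode(matrix[col].dropna())
    work = work.astype("int64")
    order = miss.sum().sort_values(kind="stable").index
    order = [c for c in order if miss[c].any()]

    prev_change = np.inf
    snapshot = work.copy()
    fractions: list[float] = []
    n_done = 0
    for it in range(max_iter):
        changed = 0
        for j, col in enumerate(order):
            other = [c for c in work.columns if c != col]
            obs = ~miss[col]
            forest = RandomForestClassifier(
                n_estimators=n_estimators,
                random_state=(seed * 1_000_003 + it * 101 + j) % (2**31),
                n_jobs=1,
            )
            forest.fit(work.loc[obs, other], work.loc[obs, col])
            pred = forest.predict(work.loc[miss[col], other])
            changed += int((work.loc[miss[col], col].to_numpy() != pred).sum())
            work.loc[miss[col], col] = pred
        frac = changed / n_missing
        fractions.append(frac)
        if frac > prev_change:
            work = snapshot  # keep the previous, more settled sweep
            break
        snapshot = work.copy()
        prev_change = frac
        n_done = it + 1
        if frac == 0.0:
            break

    completed = work.astype("Int64")
    observed_ok = (completed.where(~miss) == matrix.where(~miss)) | miss
    assert observed_ok.all().all(), "observed cells must be preserved"
    return ImputationResult(completed, n_done, fractions, seed)
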