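"""Latent class analysis: maximum-likelihood finite mixtures of
independent multinomials over categorical indicators.

The model: each patient belongs to one of K unobserved classes with
prior weights pi_k; given the class, the J indicators are independent
and indicator j takes category c with probability theta_{k,j,c} (local
independence). Fitting is by expectation–maximisation from several
random starts; the E-step runs in log space on a one-hot encoding of
the data, so each iteration is two dense matrix products and scales to
cohort-sized samples.

Fit statistics follow the usual mixture-model conventions:

* ``BIC = -2 ll + p ln n`` with ``p = (K-1) + K * sum_j (C_j - 1)``;
* entropy ``EN = -sum_ik tau_ik ln tau_ik`` (0 ln 0 = 0);
* scaled relative entropy ``E = 1 - EN / (n ln K)`` (1 for K = 1);
* integrated completed likelihood ``ICL = BIC + 2 EN``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp, rel_entr

from .config import CATEGORY_CODES

_FLOOR = 1e-10  # probability floor before renormalisation (underflow guard)


@dataclass
class PosteriorMatrix:
    """Posterior class memberships and the MAP assignment."""

    tau: np.ndarray  # (n, K), rows sum to 1
    map_labels: np.ndarray  # 1-based; ties broken toward the lowest class

    @property
    def entropy(self) -> float:
        t = np.maximum(self.tau, 1e-300)  # 0 ln 0 = 0 without log-domain noise
        return float(-np.sum(self.tau * np.log(t)))


@dataclass
class LCAModel:
    """A fitted latent class model."""

    K: int
    class_weights: np.ndarray  # (K,)
    item_response: dict[str, np.ndarray]  # col -> (K, C_col)
    columns: tuple[str, ...]
    category_codes: dict[str, tuple[int, ...]]
    log_likelihood: float
    n_obs: int
    n_iter: int
    converged: bool
    best_restart: int
    seed: int
    ll_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    entropy: float = float("nan")

    @property
    def n_params(self) -> int:
        return (self.K - 1) + self.K * sum(
            len(self.category_codes[c]) - 1 for c in self.columns)

    @property
    def bic(self) -> float:
        return -2.0 * self.log_likelihood + self.n_params * np.log(self.n_obs)

    @property
    def relative_entropy(self) -> float:
        if self.K == 1:
            return 1.0
        return 1.0 - self.entropy / (self.n_obs * np.log(self.K))

    @property
    def icl(self) -> float:
        return self.bic + 2.0 * self.entropy

    def reordered(self, order: np.ndarray) -> "LCAModel":
        """Model with classes permuted (``order[i]`` = old index of new class i)."""
        return LCAModel(
            K=self.K,
            class_weights=self.class_weights[order],
            item_response={c: th[order] for c, th in self.item_response.items()},
            columns=self.columns,
            category_codes=self.category_codes,
            log_likelihood=self.log_likelihood,
            n_obs=self.n_obs,
            n_iter=self.n_iter,
            converged=self.converged,
            best_restart=self.best_restart,
            seed=self.seed,
            ll_trace=self.ll_trace,
            entropy=self.entropy,
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "K": self.K,
            "class_weights": self.class_weights.tolist(),
            "item_response": {c: th.tolist() for c, th in self.item_response.items()},
            "columns": list(self.columns),
            "category_codes": {c: list(v) for c, v in self.category_codes.items()},
            "log_likelihood": self.log_likelihood,
            "n_obs": self.n_obs,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "best_restart": self.best_restart,
            "seed": self.seed,
            "entropy": self.entropy,
            "bic": self.bic,
            "icl": self.icl,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "LCAModel":
        d = json.loads(Path(path).read_text())
        return cls(
            K=d["K"],
            class_weights=np.asarray(d["class_weights"]),
            item_response={c: np.asarray(v) for c, v in d["item_response"].items()},
            columns=tuple(d["columns"]),
            category_codes={c: tuple(v) for c, v in d["category_codes"].items()},
            log_likelihood=d["log_likelihood"],
            n_obs=d["n_obs"],
            n_iter=d["n_iter"],
            converged=d["converged"],
            best_restart=d["best_restart"],
            seed=d["seed"],
            entropy=d["entropy"],
        )


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------


def _category_codes_for(matrix: pd.DataFrame) -> dict[str, tuple[int, ...]]:
    return {c: tuple(CATEGORY_CODES.get(c, tuple(sorted(matrix[c].unique()))))
            for c in matrix.columns}


def _one_hot(matrix: pd.DataFrame, codes: dict[str, tuple[int, ...]]) -> tuple[np.ndarray, list[slice]]:
    """Dense one-hot encoding; returns the matrix and per-column slices."""
    blocks, slices, start = [], [], 0
    for col in matrix.columns:
        cats = codes[col]
        lookup = {v: i for i, v in enumerate(cats)}
        vals = matrix[col].to_numpy()
        idx = np.asarray([lookup[v] for v in vals])
        block = np.zeros((len(matrix), len(cats)))
        block[np.arange(len(matrix)), idx] = 1.0
        blocks.append(block)
        slices.append(slice(start, start + len(cats)))
        start += len(cats)
    return np.concatenate(blocks, axis=1), slices


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------


def _m_step(tau: np.ndarray, X: np.ndarray, slices: list[slice]) -> tuple[np.ndarray, np.ndarray]:
    nk = tau.sum(axis=0)
    pi = np.maximum(nk / tau.shape[0], _FLOOR)
    pi = pi / pi.sum()
    theta = tau.T @ X  # (K, S) expected counts
    for sl in slices:
        block = np.maximum(theta[:, sl], _FLOOR)
        theta[:, sl] = block / block.sum(axis=1, keepdims=True)
    return pi, theta


def _e_step(pi: np.ndarray, theta: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    logp = X @ np.log(theta).T + np.log(pi)  # (n, K)
    norm = logsumexp(logp, axis=1)
    tau = np.exp(logp - norm[:, None])
    return tau, float(norm.sum())


def fit_lca(
    matrix: pd.DataFrame,
    K: int,
    restarts: int = 20,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int = 0,
) -> LCAModel:
    """Fit a K-class model by EM over ``restarts`` random initialisations.

    Restart r uses seed ``seed + r`` to draw initial responsibilities;
    the restart with the best final log-likelihood wins (ties: lowest
    restart index). Convergence: relative log-likelihood change below
    ``tol``. Raises on missing cells or a non-finite likelihood.
    """
    if matrix.isna().any().any():
        raise ValueError("fit_lca requires a completed matrix (no missing cells)")
    if K < 1:
        raise ValueError("K must be >= 1")
    n = len(matrix)
    if n <= K:
        raise ValueError("need more observations than classes")
    n_patterns = len(matrix.drop_duplicates())
    if K > n_patterns:
        warnings.warn(f"K={K} exceeds the {n_patterns} distinct response patterns")

    codes = _category_codes_for(matrix)
    X, slices = _one_hot(matrix, codes)

    best: tuple[float, int] | None = None
    best_state = None
    for r in range(restarts if K > 1 else 1):
        rng = np.random.default_rng(seed + r)
        tau = rng.random((n, K)) + 1e-3
        tau /= tau.sum(axis=1, keepdims=True)
        ll_prev = -np.inf
        trace = []
        converged = False
        for it in range(max_iter):
            pi, theta = _m_step(tau, X, slices)
            tau, ll = _e_step(pi, theta, X)
            if not np.isfinite(ll):
                raise FloatingPointError("non-finite log-likelihood during EM")
            trace.append(ll)
            if ll_prev > -np.inf and (ll - ll_prev) < tol * abs(ll):
                converged = True
                break
            ll_prev = ll
        if best is None or ll > best[0] + 1e-12:
            best = (ll, r)
            best_state = (pi, theta, tau, np.asarray(trace), converged, it + 1)

    pi, theta, tau, trace, converged, n_iter = best_state
    ent = float(-np.sum(np.where(tau > 0, tau * np.log(tau), 0.0)))
    item_response = {col: theta[:, sl] for col, sl in zip(matrix.columns, slices)}
    return LCAModel(
        K=K,
        class_weights=pi,
        item_response=item_response,
        columns=tuple(matrix.columns),
        category_codes=codes,
        log_likelihood=best[0],
        n_obs=n,
        n_iter=n_iter,
        converged=converged,
        best_restart=best[1],
        seed=seed,
        ll_trace=trace,
        entropy=ent,
    )


def log_likelihood(model: LCAModel, matrix: pd.DataFrame) -> float:
    """Log-likelihood of a (possibly different) dataset under a model."""
    X, slices = _one_hot(matrix[list(model.columns)], model.category_codes)
    theta = np.concatenate([model.item_response[c] for c in model.columns], axis=1)
    _, ll = _e_step(model.class_weights, theta, X)
    return ll


def posterior(model: LCAModel, matrix: pd.DataFrame) -> PosteriorMatrix:
    """Posterior class memberships tau_ik for each row, in log space."""
    X, _ = _one_hot(matrix[list(model.columns)], model.category_codes)
    theta = np.concatenate([model.item_response[c] for c in model.columns], axis=1)
    tau, _ = _e_step(model.class_weights, theta, X)
    return PosteriorMatrix(tau=tau, map_labels=np.argmax(tau, axis=1) + 1)


def information_criteria(model: LCAModel, post: PosteriorMatrix) -> tuple[float, float, float, float]:
    """(BIC, entropy, scaled relative entropy, ICL) from a fitted model."""
    en = post.entropy
    bic = model.bic
    e = 1.0 if model.K == 1 else 1.0 - en / (model.n_obs * np.log(model.K))
    return bic, en, e, bic + 2.0 * en


def discriminatory_power(model: LCAModel) -> pd.Series:
    """Rank indicators by how strongly classes differ on them.

    Score per indicator: the class-weighted Kullback–Leibler divergence
    of each class-conditional category distribution from the mixture
    marginal, ``sum_k pi_k KL(theta_kj || mean_j)``. An indicator with
    identical distributions in every class scores 0; the score is
    invariant to class relabelling. Returned sorted descending.
    """
    scores = {}
    for col in model.columns:
        theta = model.item_response[col]
        marginal = model.class_weights @ theta
        kl = rel_entr(theta, marginal[None, :]).sum(axis=1)
        scores[col] = float(model.class_weights @ kl)
    return pd.Series(scores).sort_values(ascending=False, kind="stable")


def order_by_disease_stage(
    model: LCAModel, stage_cols: tuple[str, ...] = ("medication_cat", "complication_cat")
) -> LCAModel:
    """Canonical reporting order: classes sorted by mean disease stage.

    The stage score of class k is the mean (over the stage columns) of
    the expected category code; classes are numbered from the earliest
    stage upwards, matching the early / progressing / progressed
    narrative ordering. Ties keep the original order.
    """
    cols = [c for c in stage_cols if c in model.columns]
    if not cols:
        return model
    score = np.zeros(model.K)
    for c in cols:
        codes = np.asarray(model.category_codes[c], dtype=float)
        score += model.item_response[c] @ codes
    score /= len(cols)
    return model.reordered(np.argsort(score, kind="stable"))
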