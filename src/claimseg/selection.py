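"""Model selection and stability validation for the latent class model.

Implements an extended selection strategy that balances model fit
against cluster separation rather than trusting a single criterion:

1. a local-independence screen drops one indicator from every pair with
   rank correlation >= 0.50;
2. the sample is split 70/30 into training and validation data;
3. 1- to ``Kmax``-class models are fitted on the training data and
   summarised by BIC, ICL, entropy, average silhouette width (ASW, on
   the simple-matching distance) and classification-quality measures;
4. the candidate class numbers are the BIC-elbow K, the ASW-maximising
   K and the ICL-minimising K; the smallest K endorsed by at least two
   criteria is chosen (falling back to the ASW winner), subject to the
   constraints that every class holds >= 5% of the sample and has an
   average posterior membership >= 0.80;
5. partition stability is checked by bootstrap refits (adjusted Rand
   index and pairwise co-assignment Jaccard index against the reference
   partition) and confirmed on the held-out validation data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score
from sklearn.metrics.cluster import contingency_matrix

from .lca import LCAModel, fit_lca, posterior

# ---------------------------------------------------------------------------
# Local-independence screen
# ---------------------------------------------------------------------------


@dataclass
class ScreenResult:
    correlation: pd.DataFrame
    flagged_pairs: list[tuple[str, str, float]]
    dropped: list[str]
    retained: pd.DataFrame


def correlation_screen(matrix: pd.DataFrame, threshold: float = 0.50) -> ScreenResult:
    """Flag indicator pairs violating local independence and drop one each.

    Correlation is Spearman's rank correlation on the ordinal category
    codes (for the binary sex variable this coincides with the phi-type
    association). Within each flagged pair the member with the *smaller*
    mean absolute correlation to the remaining indicators is dropped:
    of two collinear measurements, the one sharing less structure with
    the rest of the indicator set carries mostly idiosyncratic noise
    and is the redundant copy. Ties drop the later column.
    """
    corr = matrix.astype("float64").corr(method="spearman")
    flagged = []
    for i, a in enumerate(corr.columns):
        for b in corr.columns[i + 1:]:
            r = corr.loc[a, b]
            if abs(r) >= threshold:
                flagged.append((a, b, float(r)))
    dropped: list[str] = []
    remaining = list(corr.columns)
    active = [p for p in flagged]
    while active:
        a, b, _ = active[0]
        others_a = [c for c in remaining if c not in (a, b)]
        others_b = others_a
        mean_a = corr.loc[a, others_a].abs().mean() if others_a else 0.0
        mean_b = corr.loc[b, others_b].abs().mean() if others_b else 0.0
        if mean_a < mean_b:
            drop = a
        elif mean_b < mean_a:
            drop = b
        else:  # tie: later column order
            drop = b if remaining.index(b) > remaining.index(a) else a
        dropped.append(drop)
        remaining.remove(drop)
        active = [(x, y, r) for x, y, r in active if drop not in (x, y)]
    return ScreenResult(corr, flagged, dropped, matrix[remaining])


# ---------------------------------------------------------------------------
# Splitting and the fit grid
# ---------------------------------------------------------------------------


def split_sample(n: int, ratio: float = 0.7, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/validation index split (seeded)."""
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(np.floor(ratio * n))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def average_silhouette(
    matrix: pd.DataFrame,
    labels: np.ndarray,
    subsample: int = 10_000,
    seed: int = 0,
) -> float:
    """Average silhouette width on the simple-matching distance.

    d(i, i') = fraction of indicators on which the two profiles differ.
    Mean distances from a point to a cluster are computed exactly from
    the cluster-conditional category frequencies (O(nJ) instead of
    O(n^2)); when n exceeds ``subsample`` the mean of s(i) is taken
    over a seeded row subsample. Members of singleton clusters get
    s(i) = 0 by convention.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("silhouette needs >= 2 non-empty clusters")
    n, J = matrix.shape
    X = matrix.to_numpy().astype(np.int64)
    if X.min() < 0:
        raise ValueError("category codes must be non-negative integers")
    width = int(X.max()) + 1
    sizes = {c: int((labels == c).sum()) for c in classes}
    # match_sum[i, c] = number of (column, value) agreements of row i with
    # cluster c, summed over the cluster's rows; gives exact mean simple-
    # matching distances without any pairwise loop.
    match_sum = np.zeros((n, len(classes)))
    for ci, c in enumerate(classes):
        mask = labels == c
        for j in range(J):
            counts = np.bincount(X[mask, j], minlength=width)
            match_sum[:, ci] += counts[X[:, j]]
    # mean distance from row i to cluster c (including self if member)
    mean_dist = 1.0 - match_sum / (J * np.array([sizes[c] for c in classes]))
    rows = np.arange(n)
    if n > subsample:
        rows = np.sort(np.random.default_rng(seed).choice(n, subsample, replace=False))
    s_vals = np.zeros(len(rows))
    class_index = {c: i for i, c in enumerate(classes)}
    for out_i, i in enumerate(rows):
        ci = class_index[labels[i]]
        nc = sizes[labels[i]]
        if nc == 1:
            s_vals[out_i] = 0.0
            continue
        a = mean_dist[i, ci] * nc / (nc - 1)  # exclude the zero self-distance
        b = np.min(np.delete(mean_dist[i], ci))
        s_vals[out_i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return float(s_vals.mean())


@dataclass
class FitSummary:
    """Per-K criteria table plus the fitted models."""

    table: pd.DataFrame  # index K; columns loglik, bic, icl, entropy, ...
    models: dict[int, LCAModel]


def fit_grid(
    matrix: pd.DataFrame,
    Kmax: int = 10,
    restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
    asw_subsample: int = 10_000,
) -> FitSummary:
    """Fit 1..Kmax class models and tabulate all selection criteria."""
    rows, models = [], {}
    for K in range(1, Kmax + 1):
        model = fit_lca(matrix, K, restarts=restarts, tol=tol,
                        max_iter=max_iter, seed=seed + 1000 * K)
        post = posterior(model, matrix)
        shares = np.bincount(post.map_labels - 1, minlength=K) / len(matrix)
        avg_post = np.array([
            post.tau[post.map_labels == k + 1, k].mean() if (post.map_labels == k + 1).any()
            else 0.0
            for k in range(K)
        ])
        asw = np.nan
        if K >= 2 and len(np.unique(post.map_labels)) >= 2:
            asw = average_silhouette(matrix, post.map_labels,
                                     subsample=asw_subsample, seed=seed)
        rows.append({
            "K": K, "loglik": model.log_likelihood, "bic": model.bic,
            "icl": model.icl, "entropy": model.entropy,
            "relative_entropy": model.relative_entropy, "asw": asw,
            "min_class_share": float(shares.min()),
            "min_avg_posterior": float(avg_post.min()),
            "converged": model.converged,
        })
        models[K] = model
    return FitSummary(pd.DataFrame(rows).set_index("K"), models)


# ---------------------------------------------------------------------------
# Decision rule
# ---------------------------------------------------------------------------


def bic_elbow(bic: np.ndarray | pd.Series) -> int:
    """K at the elbow of the BIC curve (max second difference).

    The elbow is the interior K maximising
    ``BIC(K-1) - 2 BIC(K) + BIC(K+1)``; ties go to the smaller K. A
    perfectly linear sequence has no elbow — the smallest interior K is
    returned with a warning.
    """
    b = np.asarray(bic, dtype=float)
    if len(b) < 3:
        raise ValueError("elbow heuristic needs >= 3 BIC values")
    d2 = b[:-2] - 2 * b[1:-1] + b[2:]
    if np.allclose(d2, d2[0]):
        warnings.warn("BIC sequence has no distinct elbow (linear)")
    return int(np.argmax(np.round(d2, 12))) + 2  # interior K, 1-based K grid


@dataclass
class SelectionReport:
    candidates: dict[str, int]  # criterion -> K
    chosen_K: int | None
    constraints: dict[str, float]
    constraint_checks: list[dict]
    trace: list[str] = field(default_factory=list)
    failed: bool = False


def select(
    summary: FitSummary,
    min_class_share: float = 0.05,
    min_avg_posterior: float = 0.80,
) -> SelectionReport:
    """Choose K from the criteria grid with constraint fallback.

    Candidates: BIC-elbow K, ASW-maximising K, ICL-minimising K. The
    smallest K backed by >= 2 criteria wins, else the ASW winner. A
    candidate violating the class-share or posterior constraint is
    skipped in favour of the next candidate by ASW rank; if no
    candidate survives, the report carries ``failed=True``.
    """
    tab = summary.table
    k_elbow = bic_elbow(tab["bic"].to_numpy())
    k_asw = int(tab["asw"].idxmax())
    k_icl = int(tab["icl"].idxmin())
    candidates = {"bic_elbow": k_elbow, "max_asw": k_asw, "min_icl": k_icl}
    trace = [f"candidates: elbow={k_elbow}, asw={k_asw}, icl={k_icl}"]

    votes = pd.Series(list(candidates.values())).value_counts()
    majority = sorted(votes.index[votes >= 2])
    if majority:
        first_choice = int(majority[0])
        trace.append(f"majority of criteria -> K={first_choice}")
    else:
        first_choice = k_asw
        trace.append("no majority among criteria -> fall back to max-ASW K")

    # constraint fallback order: first choice, then candidates by ASW rank
    order = [first_choice] + [
        k for k in sorted(set(candidates.values()),
                          key=lambda k: -tab.loc[k, "asw"] if np.isfinite(tab.loc[k, "asw"]) else np.inf)
        if k != first_choice
    ]
    checks = []
    chosen = None
    for k in order:
        share_ok = tab.loc[k, "min_class_share"] >= min_class_share
        post_ok = tab.loc[k, "min_avg_posterior"] >= min_avg_posterior
        checks.append({"K": k, "min_class_share": float(tab.loc[k, "min_class_share"]),
                       "share_ok": bool(share_ok),
                       "min_avg_posterior": float(tab.loc[k, "min_avg_posterior"]),
                       "posterior_ok": bool(post_ok)})
        if share_ok and post_ok:
            chosen = k
            trace.append(f"K={k} satisfies constraints -> chosen")
            break
        trace.append(f"K={k} violates constraints -> next candidate")
    failed = chosen is None
    if failed:
        trace.append("no candidate satisfies the constraints")
    return SelectionReport(
        candidates=candidates, chosen_K=chosen,
        constraints={"min_class_share": min_class_share,
                     "min_avg_posterior": min_avg_posterior},
        constraint_checks=checks, trace=trace, failed=failed,
    )


# ---------------------------------------------------------------------------
# Partition agreement and stability
# ---------------------------------------------------------------------------


def compare_partitions(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """(adjusted Rand index, pairwise co-assignment Jaccard index).

    Both are label-permutation invariant. The Jaccard index counts
    pairs co-assigned in both partitions over pairs co-assigned in at
    least one.
    """
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("partitions must have equal length")
    ari = float(adjusted_rand_score(a, b))
    cont = contingency_matrix(a, b)
    n11 = (cont * (cont - 1) // 2).sum()
    pairs_a = (cont.sum(axis=1) * (cont.sum(axis=1) - 1) // 2).sum()
    pairs_b = (cont.sum(axis=0) * (cont.sum(axis=0) - 1) // 2).sum()
    denom = pairs_a + pairs_b - n11
    jaccard = 1.0 if denom == 0 else float(n11 / denom)
    return ari, jaccard


def match_classes(reference: np.ndarray, other: np.ndarray, K: int) -> np.ndarray:
    """Relabel ``other`` to maximise agreement with ``reference``.

    Solves the optimal one-to-one assignment over the K x K confusion
    matrix and returns the relabelled partition.
    """
    conf = np.zeros((K, K), dtype=int)
    for r, o in zip(reference, other):
        conf[r - 1, o - 1] += 1
    row, col = linear_sum_assignment(-conf)
    mapping = {int(c) + 1: int(r) + 1 for r, c in zip(row, col)}
    return np.asarray([mapping.get(int(o), int(o)) for o in other])


@dataclass
class StabilityReport:
    mean_ari: float
    mean_jaccard: float
    per_resample: pd.DataFrame
    min_avg_posterior: float = float("nan")
    passed: bool | None = None


def bootstrap_stability(
    matrix: pd.DataFrame,
    model: LCAModel,
    B: int = 100,
    seed: int = 0,
    restarts: int = 5,
) -> StabilityReport:
    """Partition stability under bootstrap resampling and refitting.

    Each resample draws n rows with replacement, refits a K-class model
    from fresh restarts, MAP-classifies the resampled rows and compares
    against the reference MAP partition restricted to those rows (after
    optimal class matching). Reports the mean adjusted Rand and Jaccard
    indices over resamples.
    """
    if B == 0:
        return StabilityReport(float("nan"), float("nan"),
                               pd.DataFrame(columns=["ari", "jaccard"]))
    ref = posterior(model, matrix).map_labels
    n = len(matrix)
    rng = np.random.default_rng(seed)
    records = []
    for b in range(B):
        idx = rng.integers(0, n, n)
        sub = matrix.iloc[idx]
        refit = fit_lca(sub, model.K, restarts=restarts,
                        seed=int(rng.integers(0, 2**31 - 1)))
        lab = posterior(refit, sub).map_labels
        lab = match_classes(ref[idx], lab, model.K)
        ari, jac = compare_partitions(ref[idx], lab)
        records.append({"ari": ari, "jaccard": jac})
    per = pd.DataFrame(records)
    return StabilityReport(float(per["ari"].mean()), float(per["jaccard"].mean()), per)


def holdout_confirmation(
    model: LCAModel,
    validation: pd.DataFrame,
    seed: int = 0,
    restarts: int = 10,
    min_avg_posterior: float = 0.80,
) -> StabilityReport:
    """Confirm the chosen model on held-out data.

    (a) classifies the validation rows with the training model (E-step
    only) and computes the smallest class-average MAP posterior;
    (b) refits K fresh on the validation data and compares the two
    partitions (ARI, Jaccard) after class matching. The pass flag
    requires the posterior floor to hold.
    """
    if len(validation) == 0:
        raise ValueError("validation set is empty")
    post = posterior(model, validation)
    avg_post = np.array([
        post.tau[post.map_labels == k + 1, k].mean()
        if (post.map_labels == k + 1).any() else 0.0
        for k in range(model.K)
    ])
    refit = fit_lca(validation, model.K, restarts=restarts, seed=seed)
    lab = match_classes(post.map_labels, posterior(refit, validation).map_labels, model.K)
    ari, jac = compare_partitions(post.map_labels, lab)
    min_post = float(avg_post.min())
    return StabilityReport(
        mean_ari=ari, mean_jaccard=jac,
        per_resample=pd.DataFrame([{"ari": ari, "jaccard": jac}]),
        min_avg_posterior=min_post,
        passed=bool(min_post >= min_avg_posterior),
    )
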