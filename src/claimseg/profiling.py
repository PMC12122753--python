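"""Class profiling: descriptive tables, top diagnoses and odds ratios.

After the latent class model is chosen and applied to the full cohort,
each class is characterised by its indicator response distributions and
mean response values, its comorbidity and complication profile, its
most frequent emergency-department and main-hospital discharge
diagnoses, and the rates of the two dichotomous outcomes (recurrent ED
visit in the index year; at least one inpatient admission). Differences
in the outcome odds between classes are quantified by univariate and
age-adjusted logistic regression with class 1 as reference; with a
single categorical predictor the fitted odds ratio equals the
contingency-table cross-product ratio, which serves as an internal
cross-check.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import CATEGORY_CODES, INDICATOR_COLUMNS
from .lca import LCAModel, PosteriorMatrix
from .synthetic import ClaimsTables

# ---------------------------------------------------------------------------
# ED site filtering and top diagnoses
# ---------------------------------------------------------------------------


def explode_ed_diagnoses(ed_visits: pd.DataFrame) -> pd.DataFrame:
    """One row per (visit, ED diagnosis code)."""
    df = ed_visits.assign(icd=ed_visits["ed_icd_codes"].fillna("").str.split(";"))
    df = df.explode("icd")
    df = df[df["icd"].astype(str).str.len() > 0]
    return df[["visit_id", "patient_id", "site_id", "icd"]]


def site_outlier_filter(
    ed_visits: pd.DataFrame,
    n_sd: float = 3.0,
    absolute_threshold: float | None = None,
) -> list:
    """Sites whose mean diagnoses-per-visit is anomalously high.

    Default rule: a site is excluded when its mean diagnoses-per-visit
    exceeds the mean of the *other* sites' means by more than ``n_sd``
    of their standard deviation (leave-one-out, so a single extreme
    site cannot mask itself by inflating the spread it is tested
    against). An absolute threshold can be supplied instead. With
    fewer than two sites nothing is excluded (a warning is emitted).
    """
    diag = explode_ed_diagnoses(ed_visits)
    per_visit = diag.groupby("visit_id").size()
    visits = ed_visits.set_index("visit_id")
    counts = per_visit.reindex(visits.index).fillna(0)
    site_means = counts.groupby(visits["site_id"]).mean()
    if len(site_means) < 2:
        warnings.warn("only one ED site present; outlier filter skipped")
        return []
    if absolute_threshold is not None:
        bad = site_means[site_means > absolute_threshold]
        return sorted(bad.index.tolist())
    excluded = []
    for site, mean in site_means.items():
        others = site_means.drop(site)
        spread = others.std(ddof=1) if len(others) > 1 else 0.0
        if mean > others.mean() + n_sd * spread and mean > others.mean():
            excluded.append(site)
    return sorted(excluded)


def top_diagnoses(
    tables: ClaimsTables,
    assignment: pd.Series | None = None,
    source: str = "ED",
    level: int = 3,
    n: int = 10,
    exclude_sites: list | None = None,
) -> dict[str, pd.DataFrame]:
    """Most frequent truncated ICD codes, overall and per class.

    ``source``: "ED" counts every diagnosis of every visit (a patient
    presenting repeatedly is counted repeatedly); "main_hospital"
    counts the main discharge diagnosis of admitted visits. Codes are
    dot-stripped and truncated to ``level`` characters; ties break
    lexicographically.
    """
    visits = tables.ed_visits
    if exclude_sites:
        visits = visits[~visits["site_id"].isin(exclude_sites)]
    if source == "ED":
        codes = explode_ed_diagnoses(visits)[["patient_id", "icd"]]
    elif source == "main_hospital":
        adm = visits[(visits["admitted"].astype(int) == 1)
                     & (visits["main_hospital_icd"].fillna("") != "")]
        codes = adm.rename(columns={"main_hospital_icd": "icd"})[["patient_id", "icd"]]
    else:
        raise ValueError("source must be 'ED' or 'main_hospital'")
    codes = codes.assign(icd=codes["icd"].str.replace(".", "", regex=False)
                         .str.upper().str.slice(0, level))

    def ranked(df: pd.DataFrame) -> pd.DataFrame:
        counts = (df.groupby("icd").size().rename("count").reset_index()
                  .sort_values(["count", "icd"], ascending=[False, True], kind="stable"))
        out = counts.head(n).reset_index(drop=True)
        out["share"] = out["count"] / max(len(df), 1)
        return out

    result = {"overall": ranked(codes)}
    if assignment is not None:
        joined = codes.merge(assignment.rename("class_"), left_on="patient_id",
                             right_index=True, how="inner")
        for k in sorted(assignment.unique()):
            result[f"class_{k}"] = ranked(joined[joined["class_"] == k])
    return result


# ---------------------------------------------------------------------------
# Class profiles
# ---------------------------------------------------------------------------


@dataclass
class ClassProfile:
    label: int
    size: int
    share: float
    response_distributions: dict[str, pd.Series]  # indicator -> P(category)
    mean_response: dict[str, float]
    cci_distribution: pd.Series | None
    outcome_rates: dict[str, float]


def class_profiles(
    assignment: pd.Series,
    matrix: pd.DataFrame,
    outcomes: pd.DataFrame | None = None,
    cci: pd.DataFrame | None = None,
) -> list[ClassProfile]:
    """Empirical per-class profiles from the MAP assignment.

    Distributions are relative frequencies of the observed (completed)
    indicator categories; mean response is the average category code,
    the quantity plotted in average-response-pattern figures.
    """
    profiles = []
    n = len(assignment)
    for k in sorted(assignment.unique()):
        members = assignment.index[assignment == k]
        sub = matrix.loc[members]
        dists, means = {}, {}
        for col in matrix.columns:
            cats = CATEGORY_CODES.get(col, tuple(sorted(matrix[col].dropna().unique())))
            vc = sub[col].value_counts(normalize=True).reindex(cats).fillna(0.0)
            dists[col] = vc
            means[col] = float(sub[col].astype("float64").mean())
        cci_dist = None
        if cci is not None:
            cci_dist = (cci.loc[members, "cci_cat"]
                        .value_counts(normalize=True)
                        .reindex(["0", "1-2", "3-4", ">=5"]).fillna(0.0))
        rates = {}
        if outcomes is not None:
            for oc in outcomes.columns:
                rates[oc] = float(outcomes.loc[members, oc].mean())
        profiles.append(ClassProfile(
            label=int(k), size=len(members), share=len(members) / n,
            response_distributions=dists, mean_response=means,
            cci_distribution=cci_dist, outcome_rates=rates,
        ))
    return profiles


def profiles_to_frames(profiles: list[ClassProfile]) -> dict[str, pd.DataFrame]:
    """Flatten profiles into tidy tables (sizes, distributions, means)."""
    sizes = pd.DataFrame([{"class": p.label, "n": p.size, "share": p.share,
                           **{f"rate_{k}": v for k, v in p.outcome_rates.items()}}
                          for p in profiles])
    dist_rows = []
    for p in profiles:
        for col, dist in p.response_distributions.items():
            for cat, prob in dist.items():
                dist_rows.append({"class": p.label, "indicator": col,
                                  "category": cat, "probability": prob})
    means = pd.DataFrame([{"class": p.label, **p.mean_response} for p in profiles])
    return {"class_sizes": sizes,
            "response_distributions": pd.DataFrame(dist_rows),
            "mean_responses": means}


# ---------------------------------------------------------------------------
# Logistic odds ratios
# ---------------------------------------------------------------------------


@dataclass
class RegressionResult:
    outcome: str
    term: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    adjusted: bool
    reference: str


def logistic_or(
    outcome: pd.Series,
    assignment: pd.Series,
    age_cat: pd.Series | None = None,
    alpha: float = 0.05,
) -> list[RegressionResult]:
    """Class odds ratios for a binary outcome, class 1 as reference.

    Fits a maximum-likelihood logistic regression with dummy-coded
    class membership (optionally plus dummy-coded age bands) and
    returns exponentiated coefficients with Wald confidence intervals
    from the observed-information covariance. Raises on separation (a
    class whose outcome is constant), naming the offending cell.
    """
    y = outcome.astype(int)
    classes = sorted(assignment.unique())
    ref = classes[0]
    for k in classes:
        sub = y[assignment == k]
        if sub.nunique() < 2:
            raise ValueError(
                f"separation: outcome {outcome.name!r} is constant in class {k}")
    X = pd.get_dummies(assignment.astype("category"), prefix="class",
                       drop_first=True, dtype=float)
    adjusted = age_cat is not None
    if adjusted:
        X = pd.concat([X, pd.get_dummies(age_cat.astype("category"), prefix="age",
                                         drop_first=True, dtype=float)], axis=1)
    X = sm.add_constant(X)
    fit = sm.Logit(np.asarray(y), np.asarray(X)).fit(disp=0, method="newton", tol=1e-10)
    params = pd.Series(fit.params, index=X.columns)
    conf = pd.DataFrame(fit.conf_int(alpha=alpha), index=X.columns,
                        columns=["low", "high"])
    results = [RegressionResult(outcome.name or "outcome", f"class_{ref}",
                                1.0, 1.0, 1.0, adjusted, f"class_{ref}")]
    for col in X.columns:
        if col == "const":
            continue
        results.append(RegressionResult(
            outcome=outcome.name or "outcome",
            term=col,
            odds_ratio=float(np.exp(params[col])),
            ci_low=float(np.exp(conf.loc[col, "low"])),
            ci_high=float(np.exp(conf.loc[col, "high"])),
            adjusted=adjusted,
            reference=f"class_{ref}",
        ))
    return results


def or_from_counts(events: np.ndarray, non_events: np.ndarray) -> list[RegressionResult]:
    """Odds ratios from per-class (event, non-event) counts.

    Expands the aggregate 2 x K table to patient-level data and runs the
    same logistic-regression path as :func:`logistic_or`, so published
    summary tables can be re-analysed directly.
    """
    events = np.asarray(events, dtype=int)
    non_events = np.asarray(non_events, dtype=int)
    y, cls = [], []
    for k, (e, ne) in enumerate(zip(events, non_events), start=1):
        y += [1] * e + [0] * ne
        cls += [k] * (e + ne)
    return logistic_or(pd.Series(y, name="outcome"), pd.Series(cls))


def regression_frame(results: list[RegressionResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "outcome": r.outcome, "term": r.term, "odds_ratio": r.odds_ratio,
        "ci_low": r.ci_low, "ci_high": r.ci_high, "adjusted": r.adjusted,
        "reference": r.reference,
    } for r in results])


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------


def summary_report(
    outdir: str | Path,
    *,
    seeds: dict | None = None,
    config: dict | None = None,
    attrition: dict | None = None,
    selection_trace: list[str] | None = None,
    frames: dict[str, pd.DataFrame] | None = None,
) -> Path:
    """Write all report tables as CSV plus a JSON run manifest.

    The manifest records seeds, a hash of the configuration, attrition
    counts and the model-selection trace, so a run is reproducible and
    auditable from its output directory alone.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = frames or {}
    for name, df in frames.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    config_json = json.dumps(config or {}, sort_keys=True, default=str)
    manifest = {
        "seeds": seeds or {},
        "config_hash": hashlib.sha256(config_json.encode()).hexdigest(),
        "attrition": attrition or {},
        "selection_trace": selection_trace or [],
        "tables_written": sorted(frames),
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return path
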