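"""Cohort extraction: find, validate and type-allocate diabetes patients.

The study population is built in three steps over the claims tables:

I.   *Screen* — every patient with at least one diabetes code (E10–E14)
     among validated outpatient diagnoses in the two years (8 calendar
     quarters) before the index quarter, among the 2016 emergency-
     department diagnoses, or as main hospital diagnosis. Outpatient
     diagnoses count only with qualifier "confirmed" or "condition
     after"; ED and hospital diagnoses are taken at face value. The
     index visit is the first ED visit in 2016.
II.  *Validate* — an M2Q-style criterion with fallbacks, tested in
     order; the first condition met is recorded:
     (1) DM coded in >=2 distinct lookback quarters (outpatient);
     (2) DM coded in one lookback quarter and among the 2016 ED
         diagnoses;
     (3) DM coded once (outpatient lookback or ED) plus >=1 insulin or
         OAD prescription in the lookback;
     (4) DM as main hospital diagnosis.
     Quarters need not be consecutive; diagnosis and prescription need
     not share a quarter.
III. *Allocate* — classify the diabetes type from the combination of
     E10/E11 codes, insulin/OAD prescriptions and DMP enrolment; only
     type 2 patients are kept. The exact published allocation algorithm
     is not public, so a documented reconstruction is used (see
     :func:`allocate_dm_type`); it is config-overridable.

Finally the cohort is restricted to patients appearing at least once in
the outpatient data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CodeConfig, DEFAULT_CODES, QUALIFIER_VALID, strip_icd
from .quarters import q_index_series, quarter_of_date
from .synthetic import ClaimsTables


@dataclass(frozen=True)
class AttritionReport:
    """Patient counts at each stage of the selection funnel."""

    eligible: int
    any_dm_code: int
    validated_dm: int
    t2dm: int
    outpatient_case: int

    def __post_init__(self):
        funnel = (self.eligible, self.any_dm_code, self.validated_dm,
                  self.t2dm, self.outpatient_case)
        if any(a < b for a, b in zip(funnel, funnel[1:])):
            raise ValueError("attrition funnel must be non-increasing")

    def as_dict(self) -> dict[str, int]:
        return {
            "eligible": self.eligible,
            "any_dm_code": self.any_dm_code,
            "validated_dm": self.validated_dm,
            "t2dm": self.t2dm,
            "outpatient_case": self.outpatient_case,
        }


def _startswith_any(series: pd.Series, prefixes: tuple[str, ...]) -> pd.Series:
    stripped = series.map(strip_icd)
    return stripped.str.startswith(tuple(strip_icd(p) for p in prefixes))


def index_visits(ed_visits: pd.DataFrame) -> pd.DataFrame:
    """First 2016 ED visit per patient (ties broken by visit_id)."""
    visits = ed_visits.copy()
    visits["visit_date"] = pd.to_datetime(visits["visit_date"])
    if (visits["visit_date"].dt.year != 2016).any():
        raise ValueError("ED visit outside the 2016 index year")
    visits = visits.sort_values(["patient_id", "visit_date", "visit_id"])
    first = visits.groupby("patient_id", as_index=False).first()
    first["index_quarter"] = first["visit_date"].map(quarter_of_date)
    return first


@dataclass
class _Evidence:
    """Per-patient DM evidence aggregated over the relevant windows."""

    frame: pd.DataFrame  # indexed by patient_id

    def __getitem__(self, col):
        return self.frame[col]


def collect_dm_evidence(tables: ClaimsTables, codes: CodeConfig = DEFAULT_CODES) -> pd.DataFrame:
    """Aggregate the DM evidence each validation/allocation step needs.

    Returns one row per patient with an ED visit: distinct lookback
    quarters with a validated outpatient DM code, presence of DM among
    ED / main-hospital diagnoses, insulin/OAD prescriptions in the
    lookback, per-type code flags and DMP enrolment.
    """
    idx = index_visits(tables.ed_visits)
    ev = idx.set_index("patient_id")[["index_quarter"]].copy()
    lb_start = ev["index_quarter"] - 8

    diag = tables.outpatient_diagnoses
    diag = diag[diag["qualifier"].isin(QUALIFIER_VALID)].copy()
    if len(diag):
        diag["qi"] = q_index_series(diag["quarter"])
        diag = diag.merge(ev["index_quarter"], left_on="patient_id", right_index=True)
        in_lb = (diag["qi"] >= diag["index_quarter"] - 8) & (diag["qi"] < diag["index_quarter"])
        dm = diag[in_lb & _startswith_any(diag["icd_code"], codes.dm_icd_prefixes)]
        ev["n_dm_quarters"] = dm.groupby("patient_id")["qi"].nunique()
        for flag, prefix in (("has_e10", codes.t1dm_prefix), ("has_e11", codes.t2dm_prefix)):
            sub = dm[_startswith_any(dm["icd_code"], (prefix,))]
            ev[flag] = ev.index.isin(sub["patient_id"])
        other = tuple(p for p in codes.dm_icd_prefixes
                      if p not in (codes.t1dm_prefix, codes.t2dm_prefix))
        sub = dm[_startswith_any(dm["icd_code"], other)] if other else dm.iloc[0:0]
        ev["has_e12_14"] = ev.index.isin(sub["patient_id"])
    else:
        ev["n_dm_quarters"] = 0
        ev["has_e10"] = ev["has_e11"] = ev["has_e12_14"] = False
    ev["n_dm_quarters"] = ev["n_dm_quarters"].fillna(0).astype(int)

    # 2016 ED diagnoses (all visits, not only the index visit)
    ed = tables.ed_visits.assign(
        codes=tables.ed_visits["ed_icd_codes"].fillna("").str.split(";"))
    ed = ed.explode("codes")
    ed = ed[ed["codes"].astype(str).str.len() > 0]
    ed_dm = ed[_startswith_any(ed["codes"], codes.dm_icd_prefixes)]
    ev["has_ed_dm"] = ev.index.isin(ed_dm["patient_id"])
    ev["has_ed_e11"] = ev.index.isin(
        ed_dm[_startswith_any(ed_dm["codes"], (codes.t2dm_prefix,))]["patient_id"])
    ev["has_ed_e10"] = ev.index.isin(
        ed_dm[_startswith_any(ed_dm["codes"], (codes.t1dm_prefix,))]["patient_id"])

    mhd = tables.ed_visits[tables.ed_visits["main_hospital_icd"].fillna("") != ""]
    mhd_dm = mhd[_startswith_any(mhd["main_hospital_icd"], codes.dm_icd_prefixes)]
    ev["has_mhd_dm"] = ev.index.isin(mhd_dm["patient_id"])
    ev["has_mhd_e11"] = ev.index.isin(
        mhd_dm[_startswith_any(mhd_dm["main_hospital_icd"], (codes.t2dm_prefix,))]["patient_id"])
    ev["has_mhd_e10"] = ev.index.isin(
        mhd_dm[_startswith_any(mhd_dm["main_hospital_icd"], (codes.t1dm_prefix,))]["patient_id"])

    rx = tables.prescriptions
    if len(rx):
        rx = rx.copy()
        rx["qi"] = q_index_series(rx["quarter"])
        rx = rx.merge(ev["index_quarter"], left_on="patient_id", right_index=True)
        rx = rx[(rx["qi"] >= rx["index_quarter"] - 8) & (rx["qi"] < rx["index_quarter"])]
        atc = rx["atc_code"].astype(str).str.upper()
        ev["has_insulin"] = ev.index.isin(
            rx[atc.str.startswith(codes.insulin_atc_prefix)]["patient_id"])
        ev["has_oad"] = ev.index.isin(
            rx[atc.str.startswith(codes.oad_atc_prefix)]["patient_id"])
    else:
        ev["has_insulin"] = ev["has_oad"] = False

    dmp = tables.dmp
    ev["t1dmp"] = ev.index.isin(dmp[dmp["programme"] == "T1DMP"]["patient_id"]) if len(dmp) else False
    ev["t2dmp"] = ev.index.isin(dmp[dmp["programme"] == "T2DMP"]["patient_id"]) if len(dmp) else False

    # outpatient presence anywhere (diagnoses or billing)
    present = set(tables.outpatient_diagnoses["patient_id"]) | set(
        tables.billing_events["patient_id"])
    ev["outpatient_case"] = ev.index.isin(present)
    return ev


def find_dm_candidates(tables: ClaimsTables, codes: CodeConfig = DEFAULT_CODES) -> set:
    """Step I: patients with any DM code in lookback, ED or hospital data."""
    ev = collect_dm_evidence(tables, codes)
    mask = (ev["n_dm_quarters"] > 0) | ev["has_ed_dm"] | ev["has_mhd_dm"]
    return set(ev.index[mask])


def validate_dm(evidence_row) -> int | None:
    """Step II: first validation condition met (1–4), or None.

    Conditions are tested in order, so a patient meeting both (1) and
    (3) is recorded under (1). Condition (2) therefore effectively means
    *exactly* one qualifying outpatient quarter plus an ED DM code.
    """
    if evidence_row["n_dm_quarters"] >= 2:
        return 1
    if evidence_row["n_dm_quarters"] >= 1 and evidence_row["has_ed_dm"]:
        return 2
    has_rx = evidence_row["has_insulin"] or evidence_row["has_oad"]
    if (evidence_row["n_dm_quarters"] >= 1 or evidence_row["has_ed_dm"]) and has_rx:
        return 3
    if evidence_row["has_mhd_dm"]:
        return 4
    return None


def allocate_dm_type(evidence_row) -> str:
    """Step III: diabetes type from codes, prescriptions and DMP.

    Reconstructed rule (the published algorithm is in non-public
    supplementary material): type 1 iff E10 is coded without any E11
    alongside insulin-only therapy, or the patient is enrolled in the
    type-1 DMP and not the type-2 DMP; otherwise type 2 iff E11 is
    coded, an OAD is prescribed, or the patient is in the type-2 DMP;
    E12–E14-only coders under insulin-only therapy are "other"; the
    remainder is "unclear". Only "T2DM" enters the cohort.
    """
    has_e10 = evidence_row["has_e10"] or evidence_row["has_ed_e10"] or evidence_row["has_mhd_e10"]
    has_e11 = evidence_row["has_e11"] or evidence_row["has_ed_e11"] or evidence_row["has_mhd_e11"]
    insulin, oad = evidence_row["has_insulin"], evidence_row["has_oad"]
    if (has_e10 and not has_e11 and insulin and not oad) or (
            evidence_row["t1dmp"] and not evidence_row["t2dmp"]):
        return "T1DM"
    if has_e11 or oad or evidence_row["t2dmp"]:
        return "T2DM"
    if evidence_row["has_e12_14"] and not has_e10 and not has_e11 and insulin and not oad:
        return "other"
    return "unclear"


def build_cohort(
    tables: ClaimsTables, codes: CodeConfig = DEFAULT_CODES
) -> tuple[pd.DataFrame, AttritionReport]:
    """Run steps I–III plus the outpatient-presence filter.

    Returns one row per cohort member (patient_id, index visit and
    quarter, validation condition, evidence summary) and the attrition
    report of the selection funnel.
    """
    if len(tables.ed_visits) == 0:
        return (pd.DataFrame(columns=["patient_id", "index_quarter", "validation_condition",
                                      "dm_type"]),
                AttritionReport(0, 0, 0, 0, 0))
    ev = collect_dm_evidence(tables, codes)
    eligible = len(ev)
    candidates = (ev["n_dm_quarters"] > 0) | ev["has_ed_dm"] | ev["has_mhd_dm"]
    ev = ev[candidates]
    conditions = ev.apply(validate_dm, axis=1)
    validated = ev[conditions.notna()]
    conditions = conditions[conditions.notna()].astype(int)
    dm_type = validated.apply(allocate_dm_type, axis=1)
    t2dm = validated[dm_type == "T2DM"]
    final = t2dm[t2dm["outpatient_case"]]

    members = final.reset_index()[["patient_id", "index_quarter", "n_dm_quarters",
                                   "has_insulin", "has_oad", "t2dmp"]]
    members["validation_condition"] = conditions.loc[final.index].values
    members["dm_type"] = "T2DM"
    idx = index_visits(tables.ed_visits).set_index("patient_id")
    members["index_visit_date"] = idx.loc[members["patient_id"], "visit_date"].values
    report = AttritionReport(
        eligible=eligible,
        any_dm_code=int(candidates.sum()),
        validated_dm=len(validated),
        t2dm=len(t2dm),
        outpatient_case=len(final),
    )
    return members, report
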