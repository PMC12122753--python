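"""Per-patient categorical indicator construction.

Builds the segmentation variables from the claims tables for each
cohort member: demographics (sex, age band at the index visit), disease
stage (number of documented diabetes complication groups, diabetes
medication), health-care utilisation (quarters with contact per
physician specialty level) and process quality of care (quarters with
HbA1c, microalbuminuria, creatinine and fundus-examination billing).
All utilisation variables count *distinct calendar quarters* with at
least one matching event in the four quarters before the index quarter,
because German outpatient billing is quarterly — the number of contacts
within a quarter is not meaningful.

An event that never occurs is coded as category 0 ("not performed") as
soon as the patient appears at least once in the outpatient data;
patients entirely absent from the outpatient tables get missing
utilisation indicators instead. The medication indicator is missing —
not zero — for patients whose region transmitted no prescription data.
"""

from __future__ import annotations

import pandas as pd

from .charlson import charlson_scores_by_patient
from .config import (CATEGORY_CODES, CodeConfig, DEFAULT_CODES, INDICATOR_COLUMNS,
                     QUALIFIER_VALID, age_category, cci_category,
                     complication_category, quarter_count_category, strip_icd)
from .quarters import LookbackWindow, lookback_quarters, q_index_series
from .synthetic import ClaimsTables

__all__ = [
    "lookback_quarters", "quarters_with_event", "complication_group_count",
    "medication_category", "age_and_sex", "build_indicator_matrix",
    "charlson_table",
]


def quarters_with_event(
    patient_events: pd.DataFrame,
    window: LookbackWindow,
    billing_codes: frozenset[str] | None = None,
    specialty_group: str | None = None,
) -> tuple[int, int]:
    """Distinct window quarters with a matching billing event.

    Select events either by billing-code set or by specialty group.
    Returns ``(count, category)`` with the 0 / 1–2 / 3–4 coding.
    """
    if (billing_codes is None) == (specialty_group is None):
        raise ValueError("select by exactly one of billing_codes / specialty_group")
    df = patient_events
    if specialty_group is not None:
        df = df[df["specialty_group"] == specialty_group]
    else:
        df = df[df["billing_code"].isin(billing_codes)]
    qi = df["quarter"].map(lambda s: q_index_series(pd.Series([s])).iloc[0]) if len(df) else pd.Series(dtype=int)
    count = int(qi[qi.isin(window.quarters)].nunique())
    return count, quarter_count_category(count)


def complication_group_count(
    patient_diagnoses: pd.DataFrame, window: LookbackWindow,
    codes: CodeConfig = DEFAULT_CODES,
) -> tuple[int, int]:
    """Distinct diabetes complication groups documented in the window.

    Groups are read off the 4th digit of validated E10–E14 codes
    (metabolic, kidney, eye, neuro-vascular, multiple). Returns
    ``(n_groups, category)``.
    """
    df = patient_diagnoses
    df = df[df["qualifier"].isin(QUALIFIER_VALID)]
    if len(df) == 0:
        return 0, 0
    qi = df["quarter"].map(lambda s: q_index_series(pd.Series([s])).iloc[0])
    df = df[qi.isin(window.quarters)]
    groups = set()
    gmap = codes.group_map
    dm_prefixes = tuple(strip_icd(p) for p in codes.dm_icd_prefixes)
    for code in df["icd_code"]:
        c = strip_icd(code)
        if c.startswith(dm_prefixes) and len(c) >= 4:
            group = gmap.get(c[3])
            if group:
                groups.add(group)
    return len(groups), complication_category(len(groups))


def medication_category(
    patient_rx: pd.DataFrame, window: LookbackWindow,
    codes: CodeConfig = DEFAULT_CODES, rx_data_available: bool = True,
) -> int | None:
    """Diabetes medication category, or None if prescriptions untransmitted."""
    if not rx_data_available:
        return None
    if len(patient_rx) == 0:
        return 0
    qi = patient_rx["quarter"].map(lambda s: q_index_series(pd.Series([s])).iloc[0])
    df = patient_rx[qi.isin(window.quarters)]
    atc = df["atc_code"].astype(str).str.upper()
    insulin = atc.str.startswith(codes.insulin_atc_prefix).any()
    oad = atc.str.startswith(codes.oad_atc_prefix).any()
    return {(False, False): 0, (False, True): 1, (True, False): 2, (True, True): 3}[
        (bool(insulin), bool(oad))]


def age_and_sex(patient_row, visits_2016: pd.DataFrame) -> tuple[int, int]:
    """Age band and sex at the (mean) 2016 ED visit age.

    Claims carry birth years only, so age = visit year − birth year;
    with several visits the mean age is taken and half-integers round
    half-up before banding.
    """
    years = pd.to_datetime(visits_2016["visit_date"]).dt.year
    ages = years - int(patient_row["birth_year"])
    mean_age = float(ages.mean())
    rounded = int(mean_age + 0.5)  # round half-up; ages are non-negative
    return age_category(rounded), int(patient_row["sex"])


def build_indicator_matrix(
    cohort: pd.DataFrame, tables: ClaimsTables, codes: CodeConfig = DEFAULT_CODES
) -> pd.DataFrame:
    """Assemble the indicator matrix (one row per cohort member).

    Missing cells (nullable ``Int64``): the medication category for
    patients without transmitted prescription data, and all
    claims-derived indicators for patients absent from the outpatient
    tables.
    """
    if len(cohort) == 0:
        return pd.DataFrame(columns=list(INDICATOR_COLUMNS)).astype("Int64")
    members = cohort.set_index("patient_id")
    patients = tables.patients.set_index("patient_id").loc[members.index]

    # vectorised pre-computation of quarter indices, restricted to members
    diag = tables.outpatient_diagnoses
    diag = diag[diag["patient_id"].isin(members.index)].copy()
    if len(diag):
        diag["qi"] = q_index_series(diag["quarter"])
    bill = tables.billing_events
    bill = bill[bill["patient_id"].isin(members.index)].copy()
    if len(bill):
        bill["qi"] = q_index_series(bill["quarter"])
    rx = tables.prescriptions
    rx = rx[rx["patient_id"].isin(members.index)].copy()
    if len(rx):
        rx["qi"] = q_index_series(rx["quarter"])
    visits = tables.ed_visits.copy()
    visits["visit_date"] = pd.to_datetime(visits["visit_date"])

    present = set(diag["patient_id"]) | set(bill["patient_id"])
    diag_g = {pid: g for pid, g in diag.groupby("patient_id")} if len(diag) else {}
    bill_g = {pid: g for pid, g in bill.groupby("patient_id")} if len(bill) else {}
    rx_g = {pid: g for pid, g in rx.groupby("patient_id")} if len(rx) else {}
    vis_g = {pid: g for pid, g in visits.groupby("patient_id")}

    specialty_cols = {ind: grp for grp, ind in codes.specialty_map}
    exam_sets = codes.exam_code_sets
    qualifiers = set(QUALIFIER_VALID)
    rows = []
    for pid, member in members.iterrows():
        window = lookback_quarters(int(member["index_quarter"]), 4)
        wset = set(window.quarters)
        age_cat, sex = age_and_sex(patients.loc[pid], vis_g[pid])
        row: dict[str, object] = {"patient_id": pid, "sex": sex, "age_cat": age_cat}
        if pid not in present:
            for col in INDICATOR_COLUMNS[2:]:
                row[col] = pd.NA
            rows.append(row)
            continue
        pdiag = diag_g.get(pid)
        groups = set()
        if pdiag is not None:
            sub = pdiag[(pdiag["qi"].isin(wset)) & pdiag["qualifier"].isin(qualifiers)]
            gmap = codes.group_map
            dm_pref = tuple(strip_icd(p) for p in codes.dm_icd_prefixes)
            for code in sub["icd_code"]:
                c = strip_icd(code)
                if c.startswith(dm_pref) and len(c) >= 4 and c[3] in gmap:
                    groups.add(gmap[c[3]])
        row["complication_cat"] = complication_category(len(groups))

        if not patients.loc[pid, "rx_data_available"]:
            row["medication_cat"] = pd.NA
        else:
            prx = rx_g.get(pid)
            if prx is None:
                row["medication_cat"] = 0
            else:
                sub = prx[prx["qi"].isin(wset)]
                atc = sub["atc_code"].astype(str).str.upper()
                insulin = bool(atc.str.startswith(codes.insulin_atc_prefix).any())
                oad = bool(atc.str.startswith(codes.oad_atc_prefix).any())
                row["medication_cat"] = {(False, False): 0, (False, True): 1,
                                         (True, False): 2, (True, True): 3}[(insulin, oad)]

        pbill = bill_g.get(pid)
        for ind in ("gp_cat", "genspec_cat", "specspec_cat"):
            if pbill is None:
                row[ind] = 0
                continue
            sub = pbill[(pbill["specialty_group"] == specialty_cols[ind])
                        & pbill["qi"].isin(wset)]
            row[ind] = quarter_count_category(int(sub["qi"].nunique()))
        for ind, codeset in exam_sets.items():
            if pbill is None:
                row[ind] = 0
                continue
            sub = pbill[pbill["billing_code"].isin(codeset) & pbill["qi"].isin(wset)]
            row[ind] = quarter_count_category(int(sub["qi"].nunique()))
        rows.append(row)

    matrix = pd.DataFrame(rows).set_index("patient_id")[list(INDICATOR_COLUMNS)]
    matrix = matrix.astype("Int64")
    for col in INDICATOR_COLUMNS:
        bad = matrix[col].dropna()
        if not bad.isin(CATEGORY_CODES[col]).all():
            raise AssertionError(f"indicator {col} outside its category set")
    return matrix


def charlson_table(
    cohort: pd.DataFrame, tables: ClaimsTables, codes: CodeConfig = DEFAULT_CODES
) -> pd.DataFrame:
    """Charlson score and band per cohort member over the 1-year lookback.

    Uses validated outpatient diagnoses in the same 4-quarter window as
    the other indicators.
    """
    members = cohort.set_index("patient_id")
    diag = tables.outpatient_diagnoses
    diag = diag[diag["patient_id"].isin(members.index)
                & diag["qualifier"].isin(QUALIFIER_VALID)].copy()
    if len(diag):
        diag["qi"] = q_index_series(diag["quarter"])
        diag = diag.merge(members["index_quarter"], left_on="patient_id", right_index=True)
        diag = diag[(diag["qi"] >= diag["index_quarter"] - 4)
                    & (diag["qi"] < diag["index_quarter"])]
    scores = charlson_scores_by_patient(diag)
    out = pd.DataFrame(index=members.index)
    out["cci_score"] = scores.reindex(out.index).fillna(0).astype(int)
    out["cci_cat"] = out["cci_score"].map(cci_category)
    return out
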