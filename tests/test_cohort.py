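import numpy as np
import pandas as pd
import pytest

from claimseg import synthetic as S
from claimseg.cohort import (allocate_dm_type, build_cohort,
                             collect_dm_evidence, index_visits, validate_dm)
from claimseg.config import DEFAULT_CODES


def _tables(patients=None, diagnoses=None, billing=None, rx=None,
            visits=None, dmp=None):
    """Minimal hand-built claims tables for single-patient scenarios."""
    return S.ClaimsTables(
        patients=pd.DataFrame(patients or [
            {"patient_id": 1, "sex": 1, "birth_year": 1950, "region_id": 2,
             "insurance_status": "member", "rx_data_available": True}]),
        outpatient_diagnoses=pd.DataFrame(
            diagnoses or [], columns=["patient_id", "quarter", "icd_code", "qualifier"]),
        billing_events=pd.DataFrame(
            billing or [], columns=["patient_id", "quarter", "billing_code",
                                    "specialty_group"]),
        prescriptions=pd.DataFrame(rx or [], columns=["patient_id", "quarter", "atc_code"]),
        ed_visits=pd.DataFrame(visits or [
            {"visit_id": "V1_1", "patient_id": 1, "visit_date": "2016-08-10",
             "site_id": 1, "ed_icd_codes": "I10", "admitted": 0,
             "main_hospital_icd": ""}]),
        dmp=pd.DataFrame(dmp or [], columns=["patient_id", "programme", "quarter"]),
    )


def _diag(q, code, qualifier="confirmed", pid=1):
    return {"patient_id": pid, "quarter": q, "icd_code": code, "qualifier": qualifier}


class TestCandidateScreen:
    def test_suspected_code_does_not_qualify(self):
        tables = _tables(diagnoses=[_diag("2016Q1", "E11.9", "suspected")])
        ev = collect_dm_evidence(tables)
        assert ev.loc[1, "n_dm_quarters"] == 0

    def test_main_hospital_diagnosis_qualifies(self):
        tables = _tables(visits=[{
            "visit_id": "V1_1", "patient_id": 1, "visit_date": "2016-08-10",
            "site_id": 1, "ed_icd_codes": "R07", "admitted": 1,
            "main_hospital_icd": "E11.5"}])
        ev = collect_dm_evidence(tables)
        assert bool(ev.loc[1, "has_mhd_dm"])
        assert validate_dm(ev.loc[1]) == 4

    def test_code_nine_quarters_back_is_outside_window(self):
        # index 2016Q3 -> lookback 2014Q3..2016Q2; 2014Q2 is quarter 9 back
        tables = _tables(diagnoses=[_diag("2014Q2", "E11.9")])
        ev = collect_dm_evidence(tables)
        assert ev.loc[1, "n_dm_quarters"] == 0

    def test_visit_outside_2016_is_an_input_error(self):
        tables = _tables(visits=[{
            "visit_id": "V1_1", "patient_id": 1, "visit_date": "2015-08-10",
            "site_id": 1, "ed_icd_codes": "I10", "admitted": 0,
            "main_hospital_icd": ""}])
        with pytest.raises(ValueError, match="2016"):
            collect_dm_evidence(tables)


class TestValidation:
    def test_two_lookback_quarters_is_condition_one(self):
        tables = _tables(diagnoses=[_diag("2015Q2", "E11.9"), _diag("2016Q1", "E11.9")])
        ev = collect_dm_evidence(tables)
        assert validate_dm(ev.loc[1]) == 1

    def test_condition_order_prefers_one_over_three(self):
        tables = _tables(
            diagnoses=[_diag("2015Q2", "E11.9"), _diag("2016Q1", "E11.9")],
            rx=[{"patient_id": 1, "quarter": "2015Q3", "atc_code": "A10BA02"}])
        ev = collect_dm_evidence(tables)
        assert validate_dm(ev.loc[1]) == 1

    def test_single_quarter_plus_prescription_is_condition_three(self):
        tables = _tables(
            diagnoses=[_diag("2015Q2", "E11.9")],
            rx=[{"patient_id": 1, "quarter": "2015Q4", "atc_code": "A10BA02"}])
        ev = collect_dm_evidence(tables)
        assert validate_dm(ev.loc[1]) == 3

    def test_single_quarter_plus_ed_code_is_condition_two(self):
        tables = _tables(
            diagnoses=[_diag("2015Q2", "E11.9")],
            visits=[{"visit_id": "V1_1", "patient_id": 1,
                     "visit_date": "2016-08-10", "site_id": 1,
                     "ed_icd_codes": "E11;R07", "admitted": 0,
                     "main_hospital_icd": ""}])
        ev = collect_dm_evidence(tables)
        assert validate_dm(ev.loc[1]) == 2

    def test_single_quarter_alone_fails(self):
        tables = _tables(diagnoses=[_diag("2015Q2", "E11.9")])
        ev = collect_dm_evidence(tables)
        assert validate_dm(ev.loc[1]) is None


class TestTypeAllocation:
    @staticmethod
    def _row(**kw):
        base = dict(has_e10=False, has_e11=False, has_e12_14=False,
                    has_ed_e10=False, has_ed_e11=False,
                    has_mhd_e10=False, has_mhd_e11=False,
                    has_insulin=False, has_oad=False, t1dmp=False, t2dmp=False)
        base.update(kw)
        return pd.Series(base)

    def test_e11_with_oad_is_t2dm(self):
        assert allocate_dm_type(self._row(has_e11=True, has_oad=True)) == "T2DM"

    def test_e10_insulin_t1dmp_is_t1dm(self):
        row = self._row(has_e10=True, has_insulin=True, t1dmp=True)
        assert allocate_dm_type(row) == "T1DM"

    def test_mixed_coding_with_oad_and_t2dmp_is_t2dm(self):
        row = self._row(has_e10=True, has_e11=True, has_oad=True, t2dmp=True)
        assert allocate_dm_type(row) == "T2DM"

    def test_e13_only_with_insulin_is_other(self):
        row = self._row(has_e12_14=True, has_insulin=True)
        assert allocate_dm_type(row) == "other"

    def test_no_evidence_is_unclear(self):
        assert allocate_dm_type(self._row()) == "unclear"

    def test_rule_is_total_over_all_evidence_combinations(self):
        """Every evidence combination maps to exactly one type."""
        from itertools import product
        for combo in product([False, True], repeat=6):
            e10, e11, e12, ins, oad, t1 = combo
            row = self._row(has_e10=e10, has_e11=e11, has_e12_14=e12,
                            has_insulin=ins, has_oad=oad, t1dmp=t1)
            assert allocate_dm_type(row) in {"T1DM", "T2DM", "other", "unclear"}


class TestBuildCohort:
    def test_planted_fixture_recovered_exactly(self, small_sim):
        members, report = build_cohort(small_sim.tables)
        got = set(members["patient_id"])
        want = set(small_sim.truth.loc[small_sim.truth.is_cohort, "patient_id"])
        assert got == want  # precision = recall = 1

    def test_attrition_funnel_stages(self, small_sim):
        _, report = build_cohort(small_sim.tables)
        d = report.as_dict()
        assert d["eligible"] == 360
        # 20 patients per distractor archetype fail at each dedicated stage
        assert d["any_dm_code"] == 340
        assert d["validated_dm"] == 320
        assert d["t2dm"] == 300 == d["outpatient_case"]
        funnel = list(d.values())
        assert all(a >= b for a, b in zip(funnel, funnel[1:]))

    def test_t1dm_only_population_yields_empty_cohort(self):
        rows, rx, visits = [], [], []
        for pid in range(1, 6):
            rows += [_diag("2015Q1", "E10.9", pid=pid), _diag("2015Q3", "E10.9", pid=pid)]
            rx.append({"patient_id": pid, "quarter": "2015Q4", "atc_code": "A10AB01"})
            visits.append({"visit_id": f"V{pid}_1", "patient_id": pid,
                           "visit_date": "2016-06-01", "site_id": 1,
                           "ed_icd_codes": "R07", "admitted": 0,
                           "main_hospital_icd": ""})
        patients = [{"patient_id": p, "sex": 1, "birth_year": 1940, "region_id": 1,
                     "insurance_status": "member", "rx_data_available": True}
                    for p in range(1, 6)]
        tables = _tables(patients=patients, diagnoses=rows, rx=rx, visits=visits)
        members, report = build_cohort(tables)
        assert len(members) == 0
        assert report.validated_dm == 5

    def test_index_visit_is_earliest(self):
        tables = _tables(visits=[
            {"visit_id": "V1_2", "patient_id": 1, "visit_date": "2016-09-01",
             "site_id": 1, "ed_icd_codes": "I10", "admitted": 0, "main_hospital_icd": ""},
            {"visit_id": "V1_1", "patient_id": 1, "visit_date": "2016-02-15",
             "site_id": 1, "ed_icd_codes": "I10", "admitted": 0, "main_hospital_icd": ""},
        ])
        idx = index_visits(tables.ed_visits)
        assert idx.loc[0, "visit_id"] == "V1_1"
        assert idx.loc[0, "index_quarter"] == 2016 * 4  # 2016Q1

    def test_empty_tables_give_empty_cohort(self):
        tables = _tables()
        tables.ed_visits = tables.ed_visits.iloc[0:0]
        members, report = build_cohort(tables)
        assert len(members) == 0
        assert report.eligible == 0

    def test_window_shift_never_adds_members(self, small_sim):
        """Moving a lookback-quarter-8 code to quarter 9 cannot grow the cohort."""
        members, _ = build_cohort(small_sim.tables)
        tables = small_sim.tables.copy()
        diag = tables.outpatient_diagnoses.copy()
        idx = index_visits(tables.ed_visits).set_index("patient_id")["index_quarter"]
        from claimseg.quarters import q_index, q_label
        qi = diag["quarter"].map(q_index)
        at_eight = qi == diag["patient_id"].map(idx) - 8
        diag.loc[at_eight, "quarter"] = (qi[at_eight] - 1).map(q_label)
        # guard against leaving the calendar range
        diag = diag[diag["quarter"].map(q_index) >= q_index("2014Q1")]
        tables.outpatient_diagnoses = diag.reset_index(drop=True)
        shifted, _ = build_cohort(tables)
        assert set(shifted["patient_id"]) <= set(members["patient_id"])
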