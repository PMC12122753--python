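"""Synthetic claims generator with planted latent classes.

The real study data (linked emergency-department and statutory-health-
insurance claims) are access-restricted, so this module generates claims
tables whose ground truth is known: patients are drawn from a finite
mixture of independent multinomials over the categorical care
indicators, raw claims events are then synthesised so that the
indicator-construction stage recovers the planted profiles exactly, and
dichotomous outcomes (recurrent ED visit, inpatient admission) are drawn
from class-specific logits.

Two generation layers are exposed:

* profile level (:func:`sample_indicator_profiles`) — fast, for testing
  the latent-class machinery directly;
* claims level (:func:`synthesize_claims`) — a constrained inverse of
  the indicator coding, for testing cohort extraction and indicator
  construction end to end. Distractor patients that must fail each
  cohort-validation path are planted alongside the cohort.

One region's prescription data can be removed wholesale
(:func:`inject_missing_prescriptions`), mimicking the situation where a
single association of SHI physicians transmits no drug data and the
medication indicator is missing — not zero — for its patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import CATEGORY_CODES, INDICATOR_COLUMNS, CodeConfig, DEFAULT_CODES
from .quarters import q_index, q_label, quarter_of_date, random_date_in_quarter

# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LatentClassSpec:
    """Ground-truth parameters of the planted mixture.

    ``item_response[col]`` is a (K, C_col) row-stochastic matrix: the
    category distribution of indicator ``col`` within each class.
    ``outcome_log_odds[name]`` is ``(intercept, offsets)`` with one
    log-odds offset per class (first class = reference, offset 0).
    ``dependent_copies`` plants a deliberate local-independence
    violation: the target indicator copies its source with the given
    probability and otherwise draws from its own class-conditional
    distribution.
    """

    n_classes: int
    class_weights: tuple[float, ...]
    item_response: dict[str, np.ndarray]
    outcome_log_odds: dict[str, tuple[float, tuple[float, ...]]]
    dependent_copies: dict[str, tuple[str, float]] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        w = np.asarray(self.class_weights, dtype=float)
        if len(w) != self.n_classes:
            raise ValueError("class_weights length != n_classes")
        if abs(w.sum() - 1.0) > 1e-12 or (w < 0).any() or (w > 1).any():
            raise ValueError("class_weights must be a probability vector")
        for col, theta in self.item_response.items():
            theta = np.asarray(theta, dtype=float)
            if theta.shape != (self.n_classes, len(CATEGORY_CODES[col])):
                raise ValueError(f"item_response[{col!r}] has wrong shape")
            if (theta < 0).any() or (theta > 1).any():
                raise ValueError(f"item_response[{col!r}] outside [0,1]")
            if not np.allclose(theta.sum(axis=1), 1.0, atol=1e-12):
                raise ValueError(f"item_response[{col!r}] rows must sum to 1")
        for name, (_, offs) in self.outcome_log_odds.items():
            if len(offs) != self.n_classes:
                raise ValueError(f"outcome {name!r}: one offset per class required")
        for tgt, (src, p) in self.dependent_copies.items():
            if len(CATEGORY_CODES[tgt]) != len(CATEGORY_CODES[src]):
                raise ValueError("dependent copy requires matching category sets")
            if not 0.0 <= p <= 1.0:
                raise ValueError("copy probability outside [0,1]")


def default_latent_class_spec() -> LatentClassSpec:
    """Three well-separated classes patterned on the published cohort.

    Class 1: early disease stage, high utilisation. Class 2: progressing
    disease, low utilisation (low specialist contact, infrequent
    guideline examinations). Class 3: progressed disease, high
    utilisation. Class weights follow the published class shares
    (36.5% / 26.1% / 37.4%). The creatinine indicator copies the HbA1c
    indicator half of the time, planting the known collinearity that the
    local-independence screen must detect and resolve. Admission
    log-odds offsets target class-2 and class-3 odds ratios of 1.27 and
    1.38 versus class 1; recurrent-visit offsets target 1.03 and 1.17.
    """
    theta = {
        "sex": [[0.33, 0.67], [0.50, 0.50], [0.69, 0.31]],
        "age_cat": [
            [0.04, 0.15, 0.66, 0.15],
            [0.34, 0.35, 0.19, 0.12],
            [0.02, 0.283, 0.692, 0.005],
        ],
        "complication_cat": [
            [0.9675, 0.0300, 0.0025],
            [0.9525, 0.0400, 0.0075],
            [0.006, 0.824, 0.170],
        ],
        "medication_cat": [
            [0.7635, 0.233, 0.002, 0.0015],
            [0.02, 0.115, 0.525, 0.34],
            [0.06, 0.165, 0.305, 0.47],
        ],
        "gp_cat": [[0.004, 0.016, 0.98], [0.10, 0.26, 0.64], [0.003, 0.012, 0.985]],
        "genspec_cat": [[0.015, 0.185, 0.80], [0.88, 0.114, 0.006], [0.012, 0.138, 0.85]],
        "specspec_cat": [[0.18, 0.64, 0.18], [0.78, 0.19, 0.03], [0.24, 0.36, 0.40]],
        "hba1c_cat": [[0.07, 0.56, 0.37], [0.45, 0.40, 0.15], [0.006, 0.254, 0.74]],
        "microalb_cat": [[0.78, 0.205, 0.015], [0.96, 0.0375, 0.0025], [0.44, 0.41, 0.15]],
        "creatinine_cat": [[0.11, 0.50, 0.39], [0.33, 0.47, 0.20], [0.03, 0.27, 0.70]],
        "fundus_cat": [[0.44, 0.51, 0.05], [0.96, 0.0375, 0.0025], [0.32, 0.53, 0.15]],
    }
    return LatentClassSpec(
        n_classes=3,
        class_weights=(0.365, 0.261, 0.374),
        item_response={k: np.asarray(v, dtype=float) for k, v in theta.items()},
        outcome_log_odds={
            "admitted": (float(np.log(0.608 / 0.392)), (0.0, float(np.log(1.27)), float(np.log(1.38)))),
            "recurrent_ed": (float(np.log(0.227 / 0.773)), (0.0, float(np.log(1.03)), float(np.log(1.17)))),
        },
        dependent_copies={"creatinine_cat": ("hba1c_cat", 0.5)},
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Problem-size and plumbing parameters of a simulated dataset."""

    n_patients: int = 10_000
    n_distractors: int = 500
    missing_prescription_region_share: float = 0.204
    calendar_start: str = "2014Q1"
    calendar_end: str = "2016Q4"
    n_regions: int = 8
    n_sites: int = 13
    codes: CodeConfig = DEFAULT_CODES
    seed: int = 0

    def __post_init__(self):
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not 0.0 <= self.missing_prescription_region_share <= 1.0:
            raise ValueError("missing_prescription_region_share outside [0,1]")
        span = q_index(self.calendar_end) - q_index(self.calendar_start) + 1
        if span < 9:
            raise ValueError("calendar range must span >= 9 quarters")


# ---------------------------------------------------------------------------
# Claims tables container
# ---------------------------------------------------------------------------

_TABLE_NAMES = ("patients", "outpatient_diagnoses", "billing_events",
                "prescriptions", "ed_visits", "dmp")


@dataclass
class ClaimsTables:
    """Bundle of long-format claims tables keyed by patient and quarter."""

    patients: pd.DataFrame
    outpatient_diagnoses: pd.DataFrame
    billing_events: pd.DataFrame
    prescriptions: pd.DataFrame
    ed_visits: pd.DataFrame
    dmp: pd.DataFrame

    def validate(self, calendar_start: str = "2014Q1", calendar_end: str = "2016Q4") -> None:
        lo, hi = q_index(calendar_start), q_index(calendar_end)
        known = set(self.patients["patient_id"])
        for name in ("outpatient_diagnoses", "billing_events", "prescriptions", "dmp"):
            df = getattr(self, name)
            if len(df) == 0:
                continue
            if not set(df["patient_id"]).issubset(known):
                raise ValueError(f"{name}: unknown patient_id")
            qi = df["quarter"].map(q_index)
            if (qi < lo).any() or (qi > hi).any():
                raise ValueError(f"{name}: quarter outside calendar range")
        if len(self.ed_visits):
            if not set(self.ed_visits["patient_id"]).issubset(known):
                raise ValueError("ed_visits: unknown patient_id")
            years = pd.to_datetime(self.ed_visits["visit_date"]).dt.year
            if (years != 2016).any():
                raise ValueError("ed_visits: visit outside the 2016 index year")

    def copy(self) -> "ClaimsTables":
        return ClaimsTables(**{n: getattr(self, n).copy() for n in _TABLE_NAMES})

    def to_csv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in _TABLE_NAMES:
            getattr(self, name).to_csv(directory / f"{name}.csv", index=False)

    @classmethod
    def from_csv(cls, directory: str | Path) -> "ClaimsTables":
        directory = Path(directory)
        frames = {}
        for name in _TABLE_NAMES:
            df = pd.read_csv(directory / f"{name}.csv", keep_default_na=False,
                             na_values=[""], dtype={"quarter": str} if name != "patients" else None)
            frames[name] = df
        frames["ed_visits"]["visit_date"] = pd.to_datetime(frames["ed_visits"]["visit_date"])
        if "main_hospital_icd" in frames["ed_visits"]:
            frames["ed_visits"]["main_hospital_icd"] = (
                frames["ed_visits"]["main_hospital_icd"].fillna(""))
        return cls(**frames)


# ---------------------------------------------------------------------------
# Profile-level generation
# ---------------------------------------------------------------------------


def sample_indicator_profiles(
    spec: LatentClassSpec, n: int, seed: int
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw ``n`` indicator profiles from the planted mixture.

    Returns the profile matrix (category codes, one row per patient,
    indexed 1..n) and the true class labels (1-based).
    """
    spec.validate()
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    labels0 = rng.choice(spec.n_classes, size=n, p=np.asarray(spec.class_weights))
    data: dict[str, np.ndarray] = {}
    for col in INDICATOR_COLUMNS:
        if col not in spec.item_response:
            continue
        theta = np.asarray(spec.item_response[col])
        cum = np.cumsum(theta, axis=1)
        u = rng.random(n)
        idx = (u[:, None] > cum[labels0]).sum(axis=1)
        codes = np.asarray(CATEGORY_CODES[col])
        data[col] = codes[idx]
        if col in spec.dependent_copies:
            src, p_copy = spec.dependent_copies[col]
            copy_mask = rng.random(n) < p_copy
            data[col] = np.where(copy_mask, data[src], data[col])
    df = pd.DataFrame(data, index=pd.RangeIndex(1, n + 1, name="patient_id"))
    return df, labels0 + 1


def generate_outcomes(labels: np.ndarray, spec: LatentClassSpec, seed: int) -> pd.DataFrame:
    """Bernoulli outcomes from class-specific logits (1-based labels)."""
    rng = np.random.default_rng(seed)
    labels0 = np.asarray(labels) - 1
    out = {}
    for name, (intercept, offsets) in spec.outcome_log_odds.items():
        logits = intercept + np.asarray(offsets)[labels0]
        out[name] = (rng.random(len(labels0)) < expit(logits)).astype(int)
    return pd.DataFrame(out, index=pd.RangeIndex(1, len(labels0) + 1, name="patient_id"))


# ---------------------------------------------------------------------------
# Claims-level generation (constrained inverse of the indicator coding)
# ---------------------------------------------------------------------------

_AGE_BANDS = {1: (20, 55), 2: (56, 70), 3: (71, 85), 4: (86, 99)}
_GROUP_DIGITS = {"metabolic": ("0", "1"), "kidney": ("2",), "eye": ("3",),
                 "neuro_vascular": ("4", "5"), "multiple": ("7",)}
_ED_POOL = ["I10", "M54", "S00", "I63", "R10", "J18", "I50", "R07", "I48"]
_MHD_POOL = ["I63", "I50", "S06", "I21", "A41", "J18", "G45", "N17", "J44"]
# Extra comorbidity diagnoses feeding the Charlson index only (no E-codes,
# so they cannot disturb cohort validation or the complication indicator).
_CCI_POOL = ["I21.9", "I50.9", "I63.9", "J44.9", "N18.9", "C34.1", "G81.9", "F01.9", "K25.9"]
_CCI_RATE = {1: 2.0, 2: 1.4, 3: 3.6}  # mean comorbid diagnoses per class
_INSULIN_CODES = ["A10AB01", "A10AE04"]
_OAD_CODES = ["A10BA02", "A10BB01"]


def _n_quarters_for_category(cat: int, rng: np.random.Generator) -> int:
    """Uniform choice among quarter counts consistent with a category."""
    if cat == 0:
        return 0
    return int(rng.integers(1, 3)) if cat == 1 else int(rng.integers(3, 5))


def synthesize_claims(
    profiles: pd.DataFrame,
    labels: np.ndarray,
    config: SimulationConfig,
    outcomes: pd.DataFrame | None = None,
    seed: int | None = None,
) -> ClaimsTables:
    """Emit raw claims events realising the given indicator profiles.

    The construction is a constrained inverse of the indicator coding:
    for every quarter-count indicator the requested number of distinct
    lookback quarters (chosen uniformly among admissible placements)
    receives a matching billing event; complication-group diagnoses are
    planted via the 4th digit of E11 codes; prescriptions realise the
    medication category. Every cohort patient additionally carries
    confirmed E11 codes in two distinct quarters of the 8-quarter
    validation window. Laboratory and fundus billing rows are attributed
    to the "other" specialty group so that they cannot disturb the three
    physician-contact indicators.

    ``config.n_distractors`` patients are appended that must fail the
    cohort build, cycling through three archetypes: type-1-diabetes-only
    patients (validated but allocated away at the type-allocation step),
    single-quarter E11 coders without prescriptions (fail validation),
    and patients without any diabetes code (fail the code screen).
    """
    for col in profiles.columns:
        bad = ~profiles[col].isin(CATEGORY_CODES[col])
        if bad.any():
            raise ValueError(f"profile column {col!r} contains invalid category codes")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = len(profiles)
    labels = np.asarray(labels)
    if outcomes is None:
        outcomes = pd.DataFrame(
            {"recurrent_ed": np.zeros(n, dtype=int), "admitted": np.zeros(n, dtype=int)},
            index=profiles.index,
        )

    patients, diagnoses, billing, rx, visits, dmp = [], [], [], [], [], []
    visit_counts: dict[int, int] = {}

    # region 1 is sized to the configured non-transmitting share
    share = config.missing_prescription_region_share
    other = np.arange(2, config.n_regions + 1)
    region_p = np.r_[share, np.full(len(other), (1 - share) / len(other))]

    def emit_visit(pid: int, date, cls: int | None, admitted: bool, dm_free: bool):
        pool = list(_ED_POOL)
        mpool = list(_MHD_POOL)
        if cls in (2, 3) and not dm_free:
            pool += ["E11", "E11", "E11"]
            mpool += ["E11", "E11"]
        n_codes = int(rng.integers(1, 5))
        codes = [pool[i] for i in rng.integers(0, len(pool), n_codes)]
        mhd = mpool[int(rng.integers(0, len(mpool)))] if admitted else ""
        visit_counts[pid] = visit_counts.get(pid, 0) + 1
        visits.append({
            "visit_id": f"V{pid}_{visit_counts[pid]}",
            "patient_id": pid,
            "visit_date": date,
            "site_id": int(rng.integers(1, config.n_sites + 1)),
            "ed_icd_codes": ";".join(codes),
            "admitted": int(admitted),
            "main_hospital_icd": mhd,
        })

    def emit_quarter_events(pid: int, cat_col: str, cat: int, lb4: list[int]):
        k = _n_quarters_for_category(int(cat), rng)
        if k == 0:
            return
        quarters = rng.choice(lb4, size=k, replace=False)
        if cat_col == "gp_cat":
            code, grp = "CONS", "GP"
        elif cat_col == "genspec_cat":
            code, grp = "CONS", "general_specialist"
        elif cat_col == "specspec_cat":
            code, grp = "CONS", "specialised_specialist"
        else:
            codeset = sorted(config.codes.exam_code_sets[cat_col])
            code, grp = codeset[int(rng.integers(0, len(codeset)))], "other"
        for q in quarters:
            billing.append({"patient_id": pid, "quarter": q_label(int(q)),
                            "billing_code": code, "specialty_group": grp})

    year_end = pd.Timestamp("2016-12-31")
    for i, (pid, row) in enumerate(profiles.iterrows()):
        cls = int(labels[i])
        index_q = 2016 * 4 + int(rng.integers(0, 4))
        lb4 = list(range(index_q - 4, index_q))
        lb8 = list(range(index_q - 8, index_q))
        age = int(rng.integers(*_AGE_BANDS[int(row["age_cat"])])) if "age_cat" in row else 70
        patients.append({
            "patient_id": pid,
            "sex": int(row.get("sex", 1)),
            "birth_year": 2016 - age,
            "region_id": int(rng.choice(np.r_[1, other], p=region_p)),
            "insurance_status": ["member", "family", "retiree"][int(rng.integers(0, 3))],
            "rx_data_available": True,
        })
        # diagnosis-validation anchor: confirmed E11 in two distinct quarters
        for q in rng.choice(lb8, size=2, replace=False):
            diagnoses.append({"patient_id": pid, "quarter": q_label(int(q)),
                              "icd_code": "E11.9", "qualifier": "confirmed"})
        # complication groups via the 4th digit, inside the 1-year window
        comp_cat = int(row["complication_cat"])
        if comp_cat > 0:
            n_groups = int(rng.integers(1, 3)) if comp_cat == 1 else int(rng.integers(3, 6))
            groups = rng.choice(sorted(_GROUP_DIGITS), size=n_groups, replace=False)
            for g in groups:
                digits = _GROUP_DIGITS[g]
                digit = digits[int(rng.integers(0, len(digits)))]
                diagnoses.append({"patient_id": pid,
                                  "quarter": q_label(int(rng.choice(lb4))),
                                  "icd_code": f"E11.{digit}", "qualifier": "confirmed"})
        # medication in the 1-year window
        med = int(row["medication_cat"])
        if med in (2, 3):
            for _ in range(int(rng.integers(1, 3))):
                rx.append({"patient_id": pid, "quarter": q_label(int(rng.choice(lb4))),
                           "atc_code": _INSULIN_CODES[int(rng.integers(0, 2))]})
        if med in (1, 3):
            for _ in range(int(rng.integers(1, 3))):
                rx.append({"patient_id": pid, "quarter": q_label(int(rng.choice(lb4))),
                           "atc_code": _OAD_CODES[int(rng.integers(0, 2))]})
        # physician contacts and guideline examinations
        for cat_col in ("gp_cat", "genspec_cat", "specspec_cat", "hba1c_cat",
                        "microalb_cat", "creatinine_cat", "fundus_cat"):
            emit_quarter_events(pid, cat_col, int(row[cat_col]), lb4)
        # comorbidity diagnoses for the Charlson index
        for _ in range(rng.poisson(_CCI_RATE.get(cls, 2.0))):
            diagnoses.append({"patient_id": pid, "quarter": q_label(int(rng.choice(lb4))),
                              "icd_code": _CCI_POOL[int(rng.integers(0, len(_CCI_POOL)))],
                              "qualifier": "confirmed"})
        if rng.random() < 0.3:
            dmp.append({"patient_id": pid, "programme": "T2DMP",
                        "quarter": q_label(int(rng.choice(lb8)))})
        # index ED visit, plus later visits for recurrent patients
        index_date = random_date_in_quarter(index_q, rng)
        admitted = bool(outcomes.loc[pid, "admitted"])
        emit_visit(pid, index_date, cls, admitted, dm_free=False)
        if bool(outcomes.loc[pid, "recurrent_ed"]):
            for _ in range(int(rng.integers(1, 3))):
                span = max((year_end - index_date).days, 1)
                extra = index_date + pd.Timedelta(days=int(rng.integers(0, span + 1)))
                emit_visit(pid, min(extra, year_end), cls, False, dm_free=False)

    # --- distractors: three archetypes cycling -----------------------------
    next_id = int(profiles.index.max()) + 1 if n else 1
    for d in range(config.n_distractors):
        pid = next_id + d
        archetype = d % 3
        index_q = 2016 * 4 + int(rng.integers(0, 4))
        lb4 = list(range(index_q - 4, index_q))
        lb8 = list(range(index_q - 8, index_q))
        age = int(rng.integers(20, 95))
        patients.append({
            "patient_id": pid, "sex": int(rng.integers(1, 3)), "birth_year": 2016 - age,
            "region_id": int(rng.choice(np.r_[1, other], p=region_p)),
            "insurance_status": "member", "rx_data_available": True,
        })
        # every distractor is present in the outpatient data
        billing.append({"patient_id": pid, "quarter": q_label(int(rng.choice(lb4))),
                        "billing_code": "CONS", "specialty_group": "GP"})
        if archetype == 0:  # type-1-only: validated, then allocated away
            for q in rng.choice(lb8, size=int(rng.integers(2, 4)), replace=False):
                diagnoses.append({"patient_id": pid, "quarter": q_label(int(q)),
                                  "icd_code": "E10.9", "qualifier": "confirmed"})
            rx.append({"patient_id": pid, "quarter": q_label(int(rng.choice(lb4))),
                       "atc_code": _INSULIN_CODES[0]})
            dmp.append({"patient_id": pid, "programme": "T1DMP",
                        "quarter": q_label(int(rng.choice(lb8)))})
        elif archetype == 1:  # single-quarter coder, no corroboration
            diagnoses.append({"patient_id": pid, "quarter": q_label(int(rng.choice(lb8))),
                              "icd_code": "E11.9", "qualifier": "confirmed"})
        else:  # no diabetes code at all
            diagnoses.append({"patient_id": pid, "quarter": q_label(int(rng.choice(lb8))),
                              "icd_code": "I10.0", "qualifier": "confirmed"})
        emit_visit(pid, random_date_in_quarter(index_q, rng), None, False, dm_free=True)

    tables = ClaimsTables(
        patients=pd.DataFrame(patients),
        outpatient_diagnoses=pd.DataFrame(
            diagnoses, columns=["patient_id", "quarter", "icd_code", "qualifier"]),
        billing_events=pd.DataFrame(
            billing, columns=["patient_id", "quarter", "billing_code", "specialty_group"]),
        prescriptions=pd.DataFrame(rx, columns=["patient_id", "quarter", "atc_code"]),
        ed_visits=pd.DataFrame(
            visits, columns=["visit_id", "patient_id", "visit_date", "site_id",
                             "ed_icd_codes", "admitted", "main_hospital_icd"]),
        dmp=pd.DataFrame(dmp, columns=["patient_id", "programme", "quarter"]),
    )
    return tables


def inject_missing_prescriptions(
    tables: ClaimsTables, share: float, seed: int = 0
) -> ClaimsTables:
    """Designate non-transmitting region(s) and drop their prescriptions.

    Regions are added greedily (largest first) while doing so brings the
    affected patient share closer to ``share``; with the default layout
    region 1 holds the requested share and is the single region chosen.
    Affected patients are flagged ``rx_data_available = False`` so the
    medication indicator becomes *missing* rather than "no medication".
    """
    if not 0.0 <= share <= 1.0:
        raise ValueError("share outside [0,1]")
    out = tables.copy()
    if share == 0 or len(out.patients) == 0:
        return out
    counts = out.patients["region_id"].value_counts()
    n = len(out.patients)
    chosen: list[int] = []
    acc = 0.0
    for region, cnt in counts.items():
        if abs(acc + cnt / n - share) <= abs(acc - share):
            chosen.append(region)
            acc += cnt / n
    affected = out.patients["region_id"].isin(chosen)
    out.patients.loc[affected, "rx_data_available"] = False
    bad_ids = set(out.patients.loc[affected, "patient_id"])
    out.prescriptions = out.prescriptions[
        ~out.prescriptions["patient_id"].isin(bad_ids)
    ].reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# End-to-end convenience
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    tables: ClaimsTables
    profiles: pd.DataFrame
    labels: np.ndarray
    outcomes: pd.DataFrame
    truth: pd.DataFrame


def simulate(
    config: SimulationConfig | None = None,
    spec: LatentClassSpec | None = None,
    seed: int = 0,
) -> SimulationResult:
    """Full simulation: profiles -> outcomes -> claims -> missing data."""
    config = config or SimulationConfig()
    spec = spec or default_latent_class_spec()
    profiles, labels = sample_indicator_profiles(spec, config.n_patients, seed)
    outcomes = generate_outcomes(labels, spec, seed + 1)
    tables = synthesize_claims(profiles, labels, config, outcomes, seed=seed + 2)
    tables = inject_missing_prescriptions(
        tables, config.missing_prescription_region_share, seed + 3)
    n_total = len(tables.patients)
    truth = pd.DataFrame({
        "patient_id": tables.patients["patient_id"],
        "is_cohort": [True] * config.n_patients + [False] * config.n_distractors,
        "true_class": list(labels) + [0] * config.n_distractors,
    })
    truth = truth.merge(outcomes.reset_index(), on="patient_id", how="left")
    return SimulationResult(tables, profiles, labels, outcomes, truth)
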