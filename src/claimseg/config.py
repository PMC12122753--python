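"""Code lists and category definitions.

Everything that identifies diabetes in claims — ICD-10-GM diagnosis
prefixes, ATC drug prefixes, billing-code sets for guideline
examinations, the complication-group map and disease-management-
programme labels — lives in :class:`CodeConfig` so a user can swap in
regionally valid code sets. The defaults use the standard diabetes code
families (E10–E14, A10A/A10B) and synthetic placeholder billing codes:
real German outpatient billing (EBM) numbers are regionally versioned
and carry no scientific content here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

# ---------------------------------------------------------------------------
# Indicator matrix column definitions (the segmentation variables)
# ---------------------------------------------------------------------------

#: Column order of the per-patient indicator matrix.
INDICATOR_COLUMNS = (
    "sex",
    "age_cat",
    "complication_cat",
    "medication_cat",
    "gp_cat",
    "genspec_cat",
    "specspec_cat",
    "hba1c_cat",
    "microalb_cat",
    "creatinine_cat",
    "fundus_cat",
)

#: Valid category codes per indicator. Sex: male 1 / female 2. Age bands:
#: 0–55 (1), 56–70 (2), 71–85 (3), >=86 (4). Complication groups: 0 / 1–2 /
#: >=3. Medication: none (0), OAD only (1), insulin only (2), both (3).
#: All quarter-count indicators: 0 quarters (0), 1–2 (1), 3–4 (2).
CATEGORY_CODES: dict[str, tuple[int, ...]] = {
    "sex": (1, 2),
    "age_cat": (1, 2, 3, 4),
    "complication_cat": (0, 1, 2),
    "medication_cat": (0, 1, 2, 3),
    "gp_cat": (0, 1, 2),
    "genspec_cat": (0, 1, 2),
    "specspec_cat": (0, 1, 2),
    "hba1c_cat": (0, 1, 2),
    "microalb_cat": (0, 1, 2),
    "creatinine_cat": (0, 1, 2),
    "fundus_cat": (0, 1, 2),
}

#: Indicators counting quarters with a billing event, mapped to the
#: billing-code-set / specialty selector that defines the event.
QUARTER_COUNT_INDICATORS = (
    "gp_cat",
    "genspec_cat",
    "specspec_cat",
    "hba1c_cat",
    "microalb_cat",
    "creatinine_cat",
    "fundus_cat",
)


def quarter_count_category(count: int) -> int:
    """Collapse a 0–4 quarter count to the 0 / 1–2 / 3–4 categories."""
    if count < 0 or count > 4:
        raise ValueError(f"quarter count {count} outside 0–4")
    if count == 0:
        return 0
    return 1 if count <= 2 else 2


def complication_category(n_groups: int) -> int:
    """Collapse a complication-group count to 0 / 1–2 / >=3."""
    if n_groups < 0:
        raise ValueError("negative group count")
    if n_groups == 0:
        return 0
    return 1 if n_groups <= 2 else 2


def age_category(age: float) -> int:
    """Age band of a (rounded) age in years."""
    if age < 0:
        raise ValueError("negative age")
    if age <= 55:
        return 1
    if age <= 70:
        return 2
    if age <= 85:
        return 3
    return 4


def cci_category(score: int) -> str:
    """Charlson score band used in the descriptive tables."""
    if score == 0:
        return "0"
    if score <= 2:
        return "1-2"
    if score <= 4:
        return "3-4"
    return ">=5"


# ---------------------------------------------------------------------------
# Claims code configuration
# ---------------------------------------------------------------------------

QUALIFIER_VALID = ("confirmed", "condition_after")
SPECIALTY_GROUPS = ("GP", "general_specialist", "specialised_specialist", "other")


@dataclass(frozen=True)
class CodeConfig:
    """Code sets driving cohort extraction and indicator construction."""

    dm_icd_prefixes: tuple[str, ...] = ("E10", "E11", "E12", "E13", "E14")
    t2dm_prefix: str = "E11"
    t1dm_prefix: str = "E10"
    insulin_atc_prefix: str = "A10A"
    oad_atc_prefix: str = "A10B"
    # Placeholder billing codes for the guideline examinations; override
    # with regionally valid EBM numbers on real data.
    hba1c_codes: frozenset[str] = frozenset({"LAB_HBA1C"})
    microalbuminuria_codes: frozenset[str] = frozenset({"LAB_MALB"})
    creatinine_codes: frozenset[str] = frozenset({"LAB_CREA"})
    fundus_codes: frozenset[str] = frozenset({"EYE_FUNDUS", "EYE_FLUORO"})
    #: 4th digit of an E10–E14 code -> diabetes complication group.
    #: Digits .6/.8/.9 ("other"/"unspecified"/"without complications")
    #: name no specific organ complication and map to no group.
    complication_group_map: tuple[tuple[str, str], ...] = (
        ("0", "metabolic"),
        ("1", "metabolic"),
        ("2", "kidney"),
        ("3", "eye"),
        ("4", "neuro_vascular"),
        ("5", "neuro_vascular"),
        ("7", "multiple"),
    )
    specialty_map: tuple[tuple[str, str], ...] = (
        ("GP", "gp_cat"),
        ("general_specialist", "genspec_cat"),
        ("specialised_specialist", "specspec_cat"),
    )

    def __post_init__(self):
        if not self.dm_icd_prefixes:
            raise ValueError("dm_icd_prefixes must be non-empty")
        if self.t2dm_prefix not in self.dm_icd_prefixes:
            raise ValueError("t2dm_prefix must be a DM prefix")
        if self.t1dm_prefix not in self.dm_icd_prefixes:
            raise ValueError("t1dm_prefix must be a DM prefix")
        sets = [self.hba1c_codes, self.microalbuminuria_codes,
                self.creatinine_codes, self.fundus_codes]
        for i, a in enumerate(sets):
            for b in sets[i + 1:]:
                if a & b:
                    raise ValueError("billing-code sets must be pairwise disjoint")

    @property
    def group_map(self) -> dict[str, str]:
        return dict(self.complication_group_map)

    @property
    def exam_code_sets(self) -> dict[str, frozenset[str]]:
        return {
            "hba1c_cat": self.hba1c_codes,
            "microalb_cat": self.microalbuminuria_codes,
            "creatinine_cat": self.creatinine_codes,
            "fundus_cat": self.fundus_codes,
        }

    def with_(self, **kwargs) -> "CodeConfig":
        return replace(self, **kwargs)


DEFAULT_CODES = CodeConfig()


def strip_icd(code: str) -> str:
    """Normalise an ICD code: upper-case, dots removed (``E11.2`` -> ``E112``)."""
    return str(code).replace(".", "").strip().upper()


def icd_matches(code: str, prefix: str) -> bool:
    """Prefix match on the dot-stripped code (``E11`` matches ``E11.2``)."""
    return strip_icd(code).startswith(strip_icd(prefix))
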