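"""Published aggregate counts used in the worked examples.

These are the class-level and cohort-level summary counts reported by
the motivating observational study of 40,561 type 2 diabetes patients
attending 13 German emergency departments in 2016 (the individual-level
data are access-restricted). They serve as fixed inputs for the
worked-example analyses: re-deriving the published odds ratios and
shares from the published counts through the package's own regression
and profiling code.
"""

#: Patients per latent class (classes 1..3).
CLASS_SIZES = {1: 14_797, 2: 10_579, 3: 15_185}

#: Total validated cohort size.
COHORT_SIZE = 40_561

#: Inpatient admission (>=1 admission) by class: yes / no counts.
ADMISSION_BY_CLASS = {
    "yes": (9_002, 7_023, 10_365),
    "no": (5_795, 3_556, 4_820),
}

#: Recurrent ED visits (>1 visit in the index year) by class.
RECURRENT_BY_CLASS = {
    "yes": (3_362, 2_463, 3_892),
    "no": (11_435, 8_116, 11_293),
}

#: Patients with at least one inpatient admission (whole cohort).
PATIENTS_ADMITTED = 26_390

#: Patients with no HbA1c measurement billed in the year before the visit.
HBA1C_ZERO_QUARTERS = 7_231
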