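"""Category sets shared by the survey, donor and matching stages.

Labour-force/condition *groups* are the analysis axis (who is compared with
whom); *labour force status* is the coarser 4-way classification carried by
donor records, which have no chronic-condition information.
"""

from __future__ import annotations

# Analysis groups (five reported groups plus the two no-condition groups that
# complete the labour-force denominator for the counterfactual stage).
FT_NO_CONDITION = "ft_no_condition"
PT_NO_CONDITION = "pt_no_condition"
FT_DIABETES = "ft_diabetes"
PT_DIABETES = "pt_diabetes"
NILF_DIABETES = "nilf_diabetes"
UNEMPLOYED = "unemployed"
NILF_OTHER = "nilf_other"

#: Printed reporting order for the five headline groups.
REPORTED_GROUPS = (
    FT_NO_CONDITION,
    PT_NO_CONDITION,
    FT_DIABETES,
    PT_DIABETES,
    NILF_DIABETES,
)

#: All generated groups, reported ones first.
GROUPS = REPORTED_GROUPS + (UNEMPLOYED, NILF_OTHER)

#: Groups with no chronic health condition (the counterfactual reference
#: population for employment structure).
NO_CONDITION_GROUPS = (FT_NO_CONDITION, PT_NO_CONDITION, UNEMPLOYED, NILF_OTHER)

# 4-way labour force status, one of the ten matching variables.
LF_FULL_TIME = "ft"
LF_PART_TIME = "pt"
LF_UNEMPLOYED = "unemployed"
LF_NILF = "nilf"

GROUP_TO_LF_STATUS = {
    FT_NO_CONDITION: LF_FULL_TIME,
    PT_NO_CONDITION: LF_PART_TIME,
    FT_DIABETES: LF_FULL_TIME,
    PT_DIABETES: LF_PART_TIME,
    NILF_DIABETES: LF_NILF,
    UNEMPLOYED: LF_UNEMPLOYED,
    NILF_OTHER: LF_NILF,
}

AGE_GROUPS = ("45-49", "50-54", "55-59", "60-64")
SEXES = ("male", "female")
EDUCATION_LEVELS = ("non_university", "university")
INCOME_UNITS = ("couple_dependents", "couple_only", "lone_parent", "lone_person")
HOURS_BANDS = ("1-15", "16-24", "25-34", "35-40", "41+")
#: Sentinel hours value carried by records that are not employed.
HOURS_NONE = "none"
INCOME_QUINTILES = (1, 2, 3, 4, 5)
FLAGS = (0, 1)
LF_STATUSES = (LF_FULL_TIME, LF_PART_TIME, LF_UNEMPLOYED, LF_NILF)

#: The ten matching variables, in the order they are conventionally listed
#: (strongest income predictors first). This order is the default matching
#: priority: variables are relaxed from the *end* of this tuple.
MATCH_VARIABLES = (
    "lf_status",
    "income_unit",
    "income_quintile",
    "age_pension",
    "dsp",
    "sex",
    "age_group",
    "hours_band",
    "education",
    "home_owner",
)

#: Admissible categories per matching variable (hours additionally allows the
#: "none" sentinel for non-employed records).
MATCH_CATEGORIES = {
    "lf_status": LF_STATUSES,
    "income_unit": INCOME_UNITS,
    "income_quintile": INCOME_QUINTILES,
    "age_pension": FLAGS,
    "dsp": FLAGS,
    "sex": SEXES,
    "age_group": AGE_GROUPS,
    "hours_band": HOURS_BANDS,
    "education": EDUCATION_LEVELS,
    "home_owner": FLAGS,
}

#: Categorical survey variables usable as benchmark strata.
STRATUM_VARIABLES = (
    "age_group",
    "sex",
    "education",
    "income_unit",
    "lf_status",
    "hours_band",
    "age_pension",
    "dsp",
    "home_owner",
)
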