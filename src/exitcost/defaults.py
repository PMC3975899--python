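"""Default study conditions for the synthetic-data generator.

The numbers here encode the published 2010 Australian estimates for persons
aged 45-64 by labour-force/diabetes group: sampled and weighted group sizes,
annual income mean/median anchors (AU$/yr), adjusted group contrasts in log
income, zero-inflated welfare-payment anchors, and a 2010-era piecewise-linear
income-tax schedule (Medicare levy and the low-income offset folded into the
marginal rates, giving an effective tax-free threshold of $16,000).

The two no-condition groups that the published tables omit (unemployed, not in
the labour force for reasons other than a chronic condition) carry realistic
2010 values so that the counterfactual stage has a complete labour-force
denominator: the no-condition reference population works out to roughly 58%
full time, 19% part time and 23% non-employed (~77% participation).
"""

from __future__ import annotations

import math

from .categories import (
    FT_DIABETES,
    FT_NO_CONDITION,
    NILF_DIABETES,
    NILF_OTHER,
    PT_DIABETES,
    PT_NO_CONDITION,
    UNEMPLOYED,
)

#: Weighted population totals by group (persons, 2010).
GROUP_SIZES = {
    FT_NO_CONDITION: 1_413_511,
    PT_NO_CONDITION: 467_796,
    FT_DIABETES: 88_889,
    PT_DIABETES: 25_329,
    NILF_DIABETES: 11_310,
    UNEMPLOYED: 60_000,
    NILF_OTHER: 500_000,
}

#: Unweighted survey record counts by group.
SAMPLE_SIZES = {
    FT_NO_CONDITION: 6_606,
    PT_NO_CONDITION: 2_373,
    FT_DIABETES: 345,
    PT_DIABETES: 105,
    NILF_DIABETES: 46,
    UNEMPLOYED: 300,
    NILF_OTHER: 2_500,
}

#: Annual income (mean, median) anchors in AU$/yr for the five reported
#: groups; the invented groups get plausible low-income anchors.
INCOME_ANCHORS = {
    FT_NO_CONDITION: (63_190.0, 54_795.0),
    PT_NO_CONDITION: (29_068.0, 21_257.0),
    FT_DIABETES: (60_389.0, 52_655.0),
    PT_DIABETES: (30_857.0, 26_032.0),
    NILF_DIABETES: (13_900.0, 11_784.0),
    UNEMPLOYED: (15_500.0, 12_200.0),
    NILF_OTHER: (11_000.0, 8_200.0),
}

#: Adjusted (age/sex/education) group contrasts in log annual income relative
#: to full-time employed persons with no chronic condition. The reported
#: percent differences are -56.3, -6.5, -52.4 and -88.3; effects for the two
#: unreported groups are plausible low-income contrasts.
INCOME_EFFECTS = {
    FT_NO_CONDITION: 0.0,
    PT_NO_CONDITION: math.log(1 - 0.563),
    FT_DIABETES: math.log(1 - 0.065),
    PT_DIABETES: math.log(1 - 0.524),
    NILF_DIABETES: math.log(1 - 0.883),
    UNEMPLOYED: -1.5,
    NILF_OTHER: -1.9,
}

#: Log-income covariate effects used both to generate incomes and as the
#: signal the regression stage must adjust away. Reference categories
#: (45-49, male, non-university) carry 0.
COVARIATE_EFFECTS = {
    "age_group": {"45-49": 0.0, "50-54": 0.05, "55-59": 0.0, "60-64": -0.20},
    "sex": {"male": 0.0, "female": -0.25},
    "education": {"non_university": 0.0, "university": 0.35},
}

#: Welfare-payment anchors: probability of receiving any payment, and the
#: (mean, median) of annual payments in AU$/yr. Employed groups have median 0
#: (receipt probability < 0.5); the group out of the labour force due to
#: diabetes has median $986 and mean $6,048.
WELFARE_ANCHORS = {
    FT_NO_CONDITION: {"p_positive": 0.10, "mean": 593.0, "median": None},
    PT_NO_CONDITION: {"p_positive": 0.20, "mean": 1_960.0, "median": None},
    FT_DIABETES: {"p_positive": 0.06, "mean": 305.0, "median": None},
    PT_DIABETES: {"p_positive": 0.22, "mean": 2_377.0, "median": None},
    NILF_DIABETES: {"p_positive": 0.80, "mean": 6_048.0, "median": 986.0},
    UNEMPLOYED: {"p_positive": 0.90, "mean": 12_000.0, "median": 11_000.0},
    NILF_OTHER: {"p_positive": 0.70, "mean": 8_000.0, "median": 5_500.0},
}

#: Piecewise-linear marginal tax schedule, (lower threshold AU$, marginal
#: rate). 2010-era Australian brackets with the Medicare levy (1.5%) folded in
#: above $20,000 and the low-income tax offset absorbed into an effective
#: tax-free threshold of $16,000.
TAX_SCHEDULE = (
    (0.0, 0.0),
    (16_000.0, 0.15),
    (20_000.0, 0.165),
    (37_000.0, 0.315),
    (80_000.0, 0.395),
    (180_000.0, 0.465),
)

#: Income quintile band edges (AU$/yr) used to band both survey and donor
#: incomes. The source surveys' band boundaries are unpublished; these are
#: round 2010-era quintile cut points for the 45-64 population.
QUINTILE_EDGES = (16_000.0, 30_000.0, 45_000.0, 65_000.0)

# Covariate mixes. _BASE holds the default mix; per-group overrides follow.
_BASE_MIX = {
    "age_group": {"45-49": 0.30, "50-54": 0.28, "55-59": 0.24, "60-64": 0.18},
    "sex": {"male": 0.50, "female": 0.50},
    "education": {"non_university": 0.72, "university": 0.28},
    "income_unit": {
        "couple_dependents": 0.35,
        "couple_only": 0.35,
        "lone_parent": 0.08,
        "lone_person": 0.22,
    },
    "hours_band": {"none": 1.0},
    "age_pension": {0: 0.99, 1: 0.01},
    "dsp": {0: 0.995, 1: 0.005},
    "home_owner": {0: 0.20, 1: 0.80},
    "n_conditions": {0: 1.0},
}

_FT_HOURS = {"35-40": 0.55, "41+": 0.45}
_PT_HOURS = {"1-15": 0.35, "16-24": 0.35, "25-34": 0.30}

_GROUP_OVERRIDES = {
    FT_NO_CONDITION: {
        "sex": {"male": 0.62, "female": 0.38},
        "education": {"non_university": 0.68, "university": 0.32},
        "hours_band": _FT_HOURS,
    },
    PT_NO_CONDITION: {
        "sex": {"male": 0.25, "female": 0.75},
        "hours_band": _PT_HOURS,
    },
    FT_DIABETES: {
        "sex": {"male": 0.65, "female": 0.35},
        "education": {"non_university": 0.78, "university": 0.22},
        "hours_band": _FT_HOURS,
        "dsp": {0: 0.99, 1: 0.01},
        "n_conditions": {1: 0.50, 2: 0.25, 3: 0.15, 4: 0.10},
    },
    PT_DIABETES: {
        "sex": {"male": 0.35, "female": 0.65},
        "education": {"non_university": 0.82, "university": 0.18},
        "hours_band": _PT_HOURS,
        "dsp": {0: 0.95, 1: 0.05},
        "n_conditions": {1: 0.45, 2: 0.25, 3: 0.18, 4: 0.12},
    },
    NILF_DIABETES: {
        # Older, less educated, high DSP receipt; chronic-condition counts
        # follow the reported mix (13% one, 11% two, 26% three, 50% four+).
        "age_group": {"45-49": 0.10, "50-54": 0.20, "55-59": 0.30, "60-64": 0.40},
        "sex": {"male": 0.55, "female": 0.45},
        "education": {"non_university": 0.90, "university": 0.10},
        "age_pension": {0: 0.90, 1: 0.10},
        "dsp": {0: 0.45, 1: 0.55},
        "home_owner": {0: 0.35, 1: 0.65},
        "n_conditions": {1: 0.13, 2: 0.11, 3: 0.26, 4: 0.50},
    },
    UNEMPLOYED: {
        "age_group": {"45-49": 0.28, "50-54": 0.27, "55-59": 0.25, "60-64": 0.20},
        "education": {"non_university": 0.85, "university": 0.15},
        "dsp": {0: 0.98, 1: 0.02},
        "home_owner": {0: 0.40, 1: 0.60},
        "n_conditions": {0: 0.60, 1: 0.25, 2: 0.15},
    },
    NILF_OTHER: {
        "age_group": {"45-49": 0.12, "50-54": 0.20, "55-59": 0.28, "60-64": 0.40},
        "sex": {"male": 0.40, "female": 0.60},
        "education": {"non_university": 0.80, "university": 0.20},
        "age_pension": {0: 0.85, 1: 0.15},
        "dsp": {0: 0.80, 1: 0.20},
        "home_owner": {0: 0.30, 1: 0.70},
        "n_conditions": {0: 0.50, 1: 0.30, 2: 0.20},
    },
}


def covariate_mixes() -> dict:
    """Per-group covariate category distributions (each summing to 1)."""
    mixes = {}
    for group, overrides in _GROUP_OVERRIDES.items():
        mix = {var: dict(dist) for var, dist in _BASE_MIX.items()}
        for var, dist in overrides.items():
            mix[var] = dict(dist)
        mixes[group] = mix
    return mixes
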