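"""Reference estimates from a 37-patient moderated-drinking cohort.

These constants package the published calibration of the drinking-desire
model to a 12-week daily-diary study of patients with mild-to-moderate
alcohol use disorder who aimed to moderate (not quit) drinking.  The raw
diaries are not redistributable, so downstream stages (synthetic cohorts,
sensitivity baselines, per-patient sweep examples) use these summaries as
fixtures rather than re-deriving them.
"""

from __future__ import annotations

from .model import InitialConditions, ModelParameters

# Population-level (fixed-effect) estimates.  a1 and d1 were fixed before
# calibration at the medians of preliminary per-patient fits because the full
# six-parameter set was practically non-identifiable.
POPULATION_PARAMS = ModelParameters(
    a1=0.2829, a2=0.9944, a3=-0.4539, d1=0.8144, d2=0.4110, d3=-0.0561
)

FIXED_PARAMS = ("a1", "d1")
VARYING_PARAMS = ("a2", "a3", "d2", "d3")

# Spread of the per-patient effective parameters (min/max/mean/median/sd).
INDIVIDUAL_SPREAD = {
    "a1": {"min": 0.2829, "max": 0.2829, "mean": 0.2829, "median": 0.2829, "sd": 0.0},
    "a2": {"min": 0.9688, "max": 1.0052, "mean": 0.9944, "median": 0.9988, "sd": 0.0088},
    "a3": {"min": -1.1274, "max": 0.3316, "mean": -0.4541, "median": -0.4974, "sd": 0.4475},
    "d1": {"min": 0.8144, "max": 0.8144, "mean": 0.8144, "median": 0.8144, "sd": 0.0},
    "d2": {"min": 0.0069, "max": 0.7530, "mean": 0.4111, "median": 0.4552, "sd": 0.2168},
    "d3": {"min": -0.7469, "max": 0.7719, "mean": -0.0561, "median": -0.1165, "sd": 0.3426},
}

# Initial-condition statistics across the 37 patients.  A0 is the 30-day
# Timeline Followback average; A1 and D1 are the first diary observations.
IC_STATS = {
    "A0": {"min": 3.5, "max": 32.0, "mean": 9.4622, "median": 8.4, "sd": 5.9181},
    "A1": {"min": 0.0, "max": 16.0, "mean": 4.7297, "median": 4.0, "sd": 4.0665},
    "D1": {"min": 0.0, "max": 12.0, "mean": 6.2162, "median": 7.0, "sd": 3.5444},
}

MEDIAN_ICS = InitialConditions(A0=8.4, A1=4.0, D1=7.0)

# Effective parameter sets for three illustrative subjects.
SUBJECT_PARAMS = {
    "1274": ModelParameters(
        a1=0.2829, a2=0.9989, a3=-0.1489, d1=0.8144, d2=0.5095, d3=-0.1173
    ),
    "1677": ModelParameters(
        a1=0.2829, a2=1.0013, a3=-0.0484, d1=0.8144, d2=0.7055, d3=-0.4816
    ),
    "1848": ModelParameters(
        a1=0.2829, a2=0.9994, a3=-0.9963, d1=0.8144, d2=0.3024, d3=0.4477
    ),
}

# Winsorization cap for nightly drink counts (mean + 2 sd over the pooled
# study sample, rounded): 98% of observations fell at or below this value.
WINSOR_CAP = 17

# Desire composite range (three 0-4 Likert items, first reverse-coded).
DESIRE_MAX = 12

# Global-sensitivity sampling bounds chosen so that solutions with all other
# inputs at baseline never exceed the winsorization cap on any day.
LHS_A1_MAX = 1.0015
LHS_D1_MAX = 2.2742
LHS_FLOOR = 0.001

STUDY_DAYS = 84
COHORT_SIZE = 37
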