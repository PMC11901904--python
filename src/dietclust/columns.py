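"""Column vocabulary for the long-format cohort table.

The cohort table is a plain :class:`pandas.DataFrame`, one row per
subject-visit, with the column groups declared here: 31 dietary fatty-acid
intakes (g/day), fat-spread intakes (g/day) plus a no-spread indicator,
outcome panels (six seated blood-pressure readings, serum lipids, fasting
glucose and insulin), and the lifestyle / anthropometric covariates used for
adjustment.  Helper modules import these lists rather than hard-coding names.
"""

from __future__ import annotations

ID_COLUMNS = ["subject_id", "visit"]
VISITS = ["age20", "age22"]

# Fatty acids by common name and shorthand chain designation, ordered from
# short-chain saturates to long-chain omega-3 polyunsaturates.
FATTY_ACIDS = [
    "butyric_4_0",
    "caproic_6_0",
    "caprylic_8_0",
    "capric_10_0",
    "lauric_12_0",
    "myristic_14_0",
    "pentadecanoic_15_0",
    "palmitic_16_0",
    "margaric_17_0",
    "stearic_18_0",
    "arachidic_20_0",
    "behenic_22_0",
    "lignoceric_24_0",
    "myristoleic_14_1n7",
    "pentadecenoic_15_1",
    "palmitoleic_16_1n7",
    "civetic_17_1n9",
    "oleic_18_1n9",
    "elaidic_18_1n9t",
    "gondoic_20_1n9",
    "erucic_22_1n9",
    "linoleic_18_2n6",
    "linoelaidic_18_2n6t",
    "alpha_linolenic_18_3n3",
    "dihomolinoleic_20_2n6",
    "mead_20_3n6",
    "arachidonic_20_4n6",
    "eicosapentaenoic_20_5n3",
    "docosatetraenoic_22_4n6",
    "docosapentaenoic_22_5n3",
    "docosahexaenoic_22_6n3",
]

SATURATED_FAS = [c for c in FATTY_ACIDS if c.split("_")[-1] == "0"]
N3_FAS = [c for c in FATTY_ACIDS if c.endswith("n3")]

# Typical habitual intake levels (g/day) used as log-scale baselines by the
# synthetic generator; order matches FATTY_ACIDS.  Major fats (palmitic,
# oleic, linoleic, stearic) dominate; very-long-chain and n-3 fats are trace.
FATTY_ACID_BASELINES_G_DAY = [
    1.2, 0.8, 0.6, 1.0, 1.5, 3.0, 0.35, 20.0, 0.25, 10.0,
    0.2, 0.1, 0.06, 0.25, 0.05, 1.5, 0.1, 30.0, 0.9, 0.2,
    0.05, 10.0, 0.25, 1.3, 0.08, 0.05, 0.15, 0.15, 0.03, 0.1,
    0.25,
]

# Fat-spread variables, labelled as on the survey instrument.  "None" is a
# 0/1 indicator of using no spread at all; the rest are intakes in g/day.
SPREAD_NONE = "None"
SPREAD_TYPES = [
    "Marg",
    "Polyunsaturated_marg",
    "Monounsaturated_marg",
    "Marg_butter_blends",
    "Butter",
]
SPREADS = [SPREAD_NONE] + SPREAD_TYPES

# Outcome panel: six seated BP readings taken two minutes apart, plus serum
# biochemistry.  All outcomes are complete by design (the analysis population
# is restricted to complete-outcome subjects).
SBP_READINGS = [f"sbp_{i}" for i in range(1, 7)]
DBP_READINGS = [f"dbp_{i}" for i in range(1, 7)]
BIOCHEMISTRY = ["triglycerides", "total_cholesterol", "hdl_cholesterol", "glucose", "insulin"]
OUTCOMES = SBP_READINGS + DBP_READINGS + BIOCHEMISTRY

# Covariates.  Subject-level ones are constant across the two visits; age and
# waist-hip ratio are measured at each visit.
VISIT_COVARIATES = ["age", "waist_hip_ratio"]
SUBJECT_COVARIATES = [
    "sex",
    "family_history_hbp",
    "healthy_diet_score",
    "western_diet_score",
    "fruit_category",
    "vegetable_category",
    "alcohol_g_day",
    "sodium_mg_day",
    "smoking",
    "mets_per_week",
    "pa_category",
]
COVARIATES = ["sex"] + VISIT_COVARIATES + SUBJECT_COVARIATES[1:]

# Covariates that take a small set of discrete codes; imputation treats these
# with predictive mean matching so imputed values stay in the observed codes.
CATEGORICAL_COVARIATES = ["family_history_hbp", "smoking", "pa_category"]

TRUTH_COLUMNS = ["true_fa_cluster", "true_spread_cluster"]

DERIVED_PREFIX = "derived_"
DERIVED_COLUMNS = [
    "derived_sbp",
    "derived_dbp",
    "derived_pp",
    "derived_homa_ir",
    "derived_non_hdl",
    "derived_htn_stage",
]

ALL_COLUMNS = (
    ID_COLUMNS + FATTY_ACIDS + SPREADS + OUTCOMES
    + ["sex"] + VISIT_COVARIATES + SUBJECT_COVARIATES[1:] + TRUTH_COLUMNS
)


def column_dictionary() -> dict:
    """Machine-readable data dictionary for the cohort CSV sidecar."""
    d = {}
    for c in ID_COLUMNS:
        d[c] = {"group": "id"}
    for c in FATTY_ACIDS:
        d[c] = {"group": "fatty_acid", "unit": "g/day"}
    d[SPREAD_NONE] = {"group": "spread", "unit": "indicator"}
    for c in SPREAD_TYPES:
        d[c] = {"group": "spread", "unit": "g/day"}
    for c in SBP_READINGS + DBP_READINGS:
        d[c] = {"group": "outcome", "unit": "mmHg"}
    for c, u in zip(BIOCHEMISTRY, ["mmol/L", "mmol/L", "mmol/L", "mmol/L", "mU/L"]):
        d[c] = {"group": "outcome", "unit": u}
    for c in ["sex"] + VISIT_COVARIATES + SUBJECT_COVARIATES[1:]:
        d[c] = {"group": "covariate"}
    for c in TRUTH_COLUMNS:
        d[c] = {"group": "truth"}
    return d
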