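"""Shipped clinical defaults: statin intensity map and CVD exclusion codes.

Both are editable configuration, not ground truth.  The intensity map follows
the 2013 ACC/AHA cholesterol guideline's categorization of statin agent + daily
dose into low / moderate / high intensity by expected LDL-C lowering
(<30%, 30-50%, >=50%).  The cardiovascular-disease exclusion list is a
prefix-matched set of ICD-9-CM / ICD-10-CM code families covering ischemic
heart disease, cerebrovascular disease and peripheral arterial disease, i.e.
the conditions that disqualify a patient from primary-prevention risk scoring.
"""

from __future__ import annotations

ARMS = ("none", "low", "moderate", "high")
#: ranking used for tie-breaks: prefer the least intense therapy
INTENSITY_ORDER = {arm: i for i, arm in enumerate(ARMS)}

#: agent -> list of (min_dose_mg, max_dose_mg, intensity); doses are daily
DEFAULT_STATIN_INTENSITY_MAP: dict[str, list[tuple[float, float, str]]] = {
    "atorvastatin": [(10, 20, "moderate"), (40, 80, "high")],
    "rosuvastatin": [(5, 10, "moderate"), (20, 40, "high")],
    "simvastatin": [(5, 10, "low"), (20, 40, "moderate")],
    "pravastatin": [(10, 20, "low"), (40, 80, "moderate")],
    "lovastatin": [(20, 20, "low"), (40, 80, "moderate")],
    "fluvastatin": [(20, 40, "low"), (80, 80, "moderate")],
    "pitavastatin": [(1, 1, "low"), (2, 4, "moderate")],
}

#: agents recognized as statins even when absent from a user-edited map,
#: so that an unmapped statin raises instead of silently passing as "none"
KNOWN_STATIN_AGENTS = frozenset(DEFAULT_STATIN_INTENSITY_MAP)

ANTIHYPERTENSIVE_AGENTS = frozenset(
    {"lisinopril", "amlodipine", "losartan", "hydrochlorothiazide", "metoprolol"}
)

DIABETES_AGENTS = frozenset({"metformin", "glipizide", "insulin glargine"})

# Trailing "*" marks a prefix match (ICD families), otherwise exact.
DEFAULT_CVD_EXCLUSION_CODES = tuple(
    [f"{c}*" for c in range(410, 415)]      # ICD-9 ischemic heart disease
    + [f"{c}*" for c in range(430, 439)]    # ICD-9 cerebrovascular disease
    + [f"{c}*" for c in range(440, 445)]    # ICD-9 peripheral arterial disease
    + [f"I{c}*" for c in range(20, 26)]     # ICD-10 ischemic heart disease
    + [f"I{c}*" for c in range(60, 70)]     # ICD-10 cerebrovascular disease
    + [f"I{c}*" for c in range(70, 74)]     # ICD-10 arterial disease
)
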