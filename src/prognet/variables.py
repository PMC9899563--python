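"""Canonical variable schema for the 32 baseline predictors and the outcome.

The predictor set mirrors a primary-care depression cohort assessed with a
21-item depressive-symptom questionnaire (items scored 0-3, total 0-63),
eight anxiety-domain subscale totals from a structured clinical interview,
and three auxiliary psychosocial totals (social support, life events,
alcohol use). The follow-up outcome is the depressive total at 3-4 months;
remission is defined as a follow-up total of 10 or less.
"""

from __future__ import annotations

BDI_ITEMS: list[str] = [f"bdi_{i:02d}" for i in range(1, 22)]

ANX_SUBSCALES: list[str] = [
    "anx_generalised",
    "anx_worry",
    "anx_compulsions",
    "anx_obsessions",
    "anx_phobic",
    "anx_health",
    "anx_somatic",
    "anx_panic",
]

AUX_TOTALS: list[str] = ["social_support", "life_events", "alcohol"]

#: The 32 baseline variables, in the fixed order used everywhere downstream.
BASELINE_VARS: list[str] = BDI_ITEMS + ANX_SUBSCALES + AUX_TOTALS

OUTCOME = "outcome_bdi"
REMISSION = "remission"
STUDY_ID = "study_id"
PATIENT_ID = "patient_id"

#: Remission threshold on the follow-up depressive total (<= is remitted).
REMISSION_THRESHOLD = 10

#: Inclusive integer value ranges per variable.
VALUE_RANGES: dict[str, tuple[int, int]] = {
    **{v: (0, 3) for v in BDI_ITEMS},
    **{v: (0, 4) for v in ANX_SUBSCALES},
    "social_support": (0, 21),
    "life_events": (0, 12),
    "alcohol": (0, 20),
    OUTCOME: (0, 63),
}

#: Instrument blocks used for block-wise min-max rescaling of weights.
BLOCKS: dict[str, list[str]] = {
    "bdi": BDI_ITEMS,
    "anxiety": ANX_SUBSCALES,
    "auxiliary": AUX_TOTALS,
}

#: Severity categories on (predicted) depressive totals, inclusive bounds.
SEVERITY_CATEGORIES: list[tuple[str, int, int]] = [
    ("minimal", 0, 13),
    ("mild", 14, 19),
    ("moderate", 20, 28),
    ("severe", 29, 63),
]


def block_of(label: str) -> str:
    """Return the instrument block a baseline variable belongs to."""
    for name, members in BLOCKS.items():
        if label in members:
            return name
    raise KeyError(f"unknown baseline variable: {label!r}")
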