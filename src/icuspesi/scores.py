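"""PESI, sPESI and ICU-sPESI scoring.

PESI sums the patient's age in years with fixed weights for ten further
items; its points map onto five risk classes.  sPESI counts six equally
weighted binary items; 0 is conventionally "low risk".  ICU-sPESI extends
sPESI with three binary acuity-of-presentation items — Intubation, Confusion
(altered mental status), and Use of vasoactive infusions — giving a 0-9
score mapped onto four risk classes.

Threshold edge semantics follow the source scores exactly: heart rate >=110
and respiratory rate >=30 are inclusive; systolic blood pressure <100,
temperature <36 C, SpO2 <90 % and age >80 are exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import PatientRecord
from .features import DerivedFeatures, FeatureConfig, derive_features

#: Fixed PESI weights for the non-age items.
PESI_WEIGHTS = {
    "male_sex": 10,
    "cancer": 30,
    "heart_failure": 10,
    "chronic_lung_disease": 10,
    "hr_ge_110": 20,
    "sbp_lt_100": 30,
    "rr_ge_30": 20,
    "temp_lt_36": 20,
    "ams": 60,
    "spo2_lt_90": 20,
}

PESI_CLASS_BOUNDS = ((65, "I"), (85, "II"), (105, "III"), (125, "IV"))

ICU_SPESI_CLASS_LABELS = ("I", "II", "III", "IV")


@dataclass
class ScorePanel:
    """All three scores, their classes, and the per-item contribution map."""

    patient_id: str
    pesi_points: int
    pesi_class: str
    spesi_points: int
    icu_spesi_points: int
    icu_spesi_class: str
    apache_iv: int | None
    breakdown: dict[str, int]


def _vital_items(f: DerivedFeatures) -> dict[str, bool]:
    return {
        "hr_ge_110": f.extreme_hr >= 110,
        "sbp_lt_100": f.extreme_sbp < 100,
        "rr_ge_30": f.extreme_rr >= 30,
        "temp_lt_36": f.extreme_temp < 36,
        "spo2_lt_90": f.extreme_spo2 < 90,
    }


def compute_pesi(features: DerivedFeatures, record: PatientRecord) -> tuple[int, dict[str, int]]:
    """PESI points (age + fired weights) with the per-item breakdown."""
    v = _vital_items(features)
    fired = {
        "age": record.age_years,
        "male_sex": record.sex == "male",
        "cancer": record.comorbidities.get("cancer", False),
        "heart_failure": record.comorbidities.get("heart_failure", False),
        "chronic_lung_disease": features.chronic_lung_disease,
        "hr_ge_110": v["hr_ge_110"],
        "sbp_lt_100": v["sbp_lt_100"],
        "rr_ge_30": v["rr_ge_30"],
        "temp_lt_36": v["temp_lt_36"],
        "ams": features.ams,
        "spo2_lt_90": v["spo2_lt_90"],
    }
    breakdown = {"age": record.age_years}
    for item, weight in PESI_WEIGHTS.items():
        if fired[item]:
            breakdown[item] = weight
    return sum(breakdown.values()), breakdown


def pesi_class(points: int) -> str:
    """Class I (<=65), II (66-85), III (86-105), IV (106-125), V (>125)."""
    for bound, label in PESI_CLASS_BOUNDS:
        if points <= bound:
            return label
    return "V"


def spesi_items(features: DerivedFeatures, record: PatientRecord) -> dict[str, bool]:
    """The six equally weighted sPESI items."""
    v = _vital_items(features)
    return {
        "age_gt_80": record.age_years > 80,
        "cancer": record.comorbidities.get("cancer", False),
        "chronic_cardiopulmonary_disease": features.chronic_cardiopulmonary_disease,
        "hr_ge_110": v["hr_ge_110"],
        "sbp_lt_100": v["sbp_lt_100"],
        "spo2_lt_90": v["spo2_lt_90"],
    }


def compute_spesi(features: DerivedFeatures, record: PatientRecord) -> int:
    return sum(spesi_items(features, record).values())


def icu_spesi_items(
    features: DerivedFeatures, record: PatientRecord, ventilation_mode: str = "invasive_only"
) -> dict[str, bool]:
    """sPESI items plus Intubation, Confusion (AMS) and vasoactive Use.

    With ``ventilation_mode='any'`` the intubation item also accepts
    noninvasive ventilation.
    """
    items = spesi_items(features, record)
    items["intubation"] = (
        features.ventilation_any_flag if ventilation_mode == "any" else features.intubation_flag
    )
    items["ams"] = features.ams
    items["vasoactive"] = features.vasoactive_flag
    return items


def compute_icu_spesi(
    features: DerivedFeatures, record: PatientRecord, ventilation_mode: str = "invasive_only"
) -> int:
    return sum(icu_spesi_items(features, record, ventilation_mode).values())


def icu_spesi_class(points: int) -> str:
    """Class I (<=2), II (3-4), III (5-6), IV (>=7)."""
    if not 0 <= points <= 9:
        raise ValueError(f"ICU-sPESI points must be in 0..9, got {points}")
    if points <= 2:
        return "I"
    if points <= 4:
        return "II"
    if points <= 6:
        return "III"
    return "IV"


def score_panel(record: PatientRecord, config: FeatureConfig | None = None) -> ScorePanel:
    """Compute all three scores from a single feature derivation."""
    cfg = config or FeatureConfig()
    features = derive_features(record, cfg)
    pesi_pts, breakdown = compute_pesi(features, record)
    spesi_pts = compute_spesi(features, record)
    icu_pts = compute_icu_spesi(features, record, cfg.ventilation_mode)
    for item, flag in icu_spesi_items(features, record, cfg.ventilation_mode).items():
        breakdown[f"spesi:{item}"] = int(flag)
    return ScorePanel(
        patient_id=record.patient_id,
        pesi_points=pesi_pts,
        pesi_class=pesi_class(pesi_pts),
        spesi_points=spesi_pts,
        icu_spesi_points=icu_pts,
        icu_spesi_class=icu_spesi_class(icu_pts),
        apache_iv=record.apache_iv,
        breakdown=breakdown,
    )
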