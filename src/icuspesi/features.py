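"""Derive score components from raw vitals, GCS and acuity events.

Vitals are reduced to 30-minute bin medians aligned at ICU admission, and the
score-relevant extreme of the bin medians is kept per vital kind: the maximum
for heart rate and respiratory rate, the minimum for systolic blood pressure,
temperature and SpO2 (only the low tail of each of those scores points).
Vital kinds with no observations inside the window are imputed with a
normal-range sentinel so that no abnormal-vital criterion can fire, and the
imputation is recorded.  Acuity events (intubation, noninvasive ventilation,
vasoactive support) count only when their onset falls inside the observation
window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import VITAL_KINDS, PatientRecord, VitalSample

WINDOW_CHOICES = (2, 3, 6, 12, 24)

#: Direction of the score-relevant extreme per vital kind.
EXTREME_DIRECTION = {
    "heart_rate": "max",
    "respiratory_rate": "max",
    "systolic_bp": "min",
    "temperature_c": "min",
    "spo2": "min",
}

#: Normal-side sentinels substituted for missing vitals; each sits strictly
#: inside the normal range so an imputed kind can never score points.
IMPUTATION_SENTINELS = {
    "heart_rate": 80.0,
    "systolic_bp": 120.0,
    "respiratory_rate": 16.0,
    "temperature_c": 37.0,
    "spo2": 98.0,
}

LUNG_FLAGS = ("asthma", "copd", "restrictive_lung_disease", "home_oxygen", "lung_transplant")
CARDIAC_FLAGS = ("heart_failure", "myocardial_infarction", "cabg", "pacemaker_or_icd")


@dataclass(frozen=True)
class FeatureConfig:
    """Observation-window and policy knobs for feature derivation.

    ventilation_mode: ``invasive_only`` restricts the intubation component to
    invasive mechanical ventilation; ``any`` also accepts noninvasive
    ventilation.  ams_untestable_policy: how an untestable GCS verbal
    response (``None``) maps to the altered-mental-status flag; the default
    ``present`` treats it as AMS because "verbally responsive and oriented"
    cannot be established.
    """

    window_hours: int = 24
    ventilation_mode: str = "invasive_only"
    ams_untestable_policy: str = "present"
    sentinels: dict = field(default_factory=lambda: dict(IMPUTATION_SENTINELS))

    def __post_init__(self) -> None:
        if self.window_hours not in WINDOW_CHOICES:
            raise ValueError(f"window_hours must be one of {WINDOW_CHOICES}")
        if self.ventilation_mode not in ("invasive_only", "any"):
            raise ValueError("ventilation_mode must be 'invasive_only' or 'any'")
        if self.ams_untestable_policy not in ("present", "absent"):
            raise ValueError("ams_untestable_policy must be 'present' or 'absent'")


@dataclass
class DerivedFeatures:
    """Window-restricted extremes, AMS flag and composite comorbidity flags."""

    window_hours: int
    extreme_hr: float
    extreme_sbp: float
    extreme_rr: float
    extreme_temp: float
    extreme_spo2: float
    ams: bool
    intubation_flag: bool
    ventilation_any_flag: bool
    vasoactive_flag: bool
    chronic_lung_disease: bool
    chronic_cardiopulmonary_disease: bool
    missing_vitals: frozenset = frozenset()


def bin_median_vitals(
    samples: list[VitalSample], kind: str, window_hours: int = 24
) -> list[float]:
    """Median per half-open 30-minute bin [30k, 30(k+1)) inside the window.

    Bins are aligned at ICU admission (offset 0); bins with no samples are
    absent from the output.  The median of an even number of samples is the
    midpoint of the two central values.
    """
    if kind not in VITAL_KINDS:
        raise ValueError(f"unknown vital kind {kind!r}")
    horizon_min = window_hours * 60
    by_bin: dict[int, list[float]] = {}
    for s in samples:
        if s.kind != kind or not 0 <= s.offset_min < horizon_min:
            continue
        by_bin.setdefault(s.offset_min // 30, []).append(s.value)
    return [float(np.median(by_bin[k])) for k in sorted(by_bin)]


def extract_extremes(binned: dict[str, list[float]]) -> tuple[dict[str, float], set[str]]:
    """Score-relevant extreme of the bin medians per kind.

    Returns (extremes, missing): kinds with no bins appear in ``missing`` and
    are absent from ``extremes``.
    """
    extremes: dict[str, float] = {}
    missing: set[str] = set()
    for kind in VITAL_KINDS:
        medians = binned.get(kind, [])
        if not medians:
            missing.add(kind)
        elif EXTREME_DIRECTION[kind] == "max":
            extremes[kind] = max(medians)
        else:
            extremes[kind] = min(medians)
    return extremes, missing


def ams_from_gcs(gcs_verbal: int | None, untestable_policy: str = "present") -> bool:
    """Altered mental status: GCS verbal response below 5.

    A verbal score of 5 means verbally responsive and oriented; anything less
    counts as AMS.  An untestable verbal response (``None``, e.g. an intubated
    patient charted "T") maps to AMS under the default policy since a verbal
    score of 5 cannot be demonstrated; set ``untestable_policy='absent'`` to
    treat it as not-AMS instead.
    """
    if gcs_verbal is None:
        return untestable_policy == "present"
    if not 1 <= gcs_verbal <= 5:
        raise ValueError(f"gcs_verbal must be in 1..5, got {gcs_verbal}")
    return gcs_verbal < 5


def composite_flags(record: PatientRecord) -> tuple[bool, bool]:
    """(chronic lung disease, chronic cardiopulmonary disease) composites.

    Chronic lung disease is any of asthma, COPD, restrictive lung disease,
    home oxygen requirement or lung transplant; chronic cardiopulmonary
    disease additionally accepts heart failure, myocardial infarction,
    coronary artery bypass, or a pacemaker/ICD.
    """
    c = record.comorbidities
    lung = any(c.get(f, False) for f in LUNG_FLAGS)
    cardio = lung or any(c.get(f, False) for f in CARDIAC_FLAGS)
    return lung, cardio


def _event_in_window(flag: bool, onset_min: float | None, window_hours: int) -> bool:
    if not flag:
        return False
    onset = 0.0 if onset_min is None else onset_min
    return onset < window_hours * 60


def derive_features(record: PatientRecord, config: FeatureConfig | None = None) -> DerivedFeatures:
    """Compose binning, extremes, imputation, AMS and event flags."""
    cfg = config or FeatureConfig()
    binned = {k: bin_median_vitals(record.vitals, k, cfg.window_hours) for k in VITAL_KINDS}
    extremes, missing = extract_extremes(binned)
    for kind in missing:
        extremes[kind] = cfg.sentinels[kind]
    intub = _event_in_window(record.intubated_invasive, record.intubation_offset_min, cfg.window_hours)
    niv = _event_in_window(record.noninvasive_ventilation, record.niv_offset_min, cfg.window_hours)
    vaso = _event_in_window(record.vasoactive_use, record.vasoactive_offset_min, cfg.window_hours)
    lung, cardio = composite_flags(record)
    return DerivedFeatures(
        window_hours=cfg.window_hours,
        extreme_hr=extremes["heart_rate"],
        extreme_sbp=extremes["systolic_bp"],
        extreme_rr=extremes["respiratory_rate"],
        extreme_temp=extremes["temperature_c"],
        extreme_spo2=extremes["spo2"],
        ams=ams_from_gcs(record.gcs_verbal, cfg.ams_untestable_policy),
        intubation_flag=intub,
        ventilation_any_flag=intub or niv,
        vasoactive_flag=vaso,
        chronic_lung_disease=lung,
        chronic_cardiopulmonary_disease=cardio,
        missing_vitals=frozenset(missing),
    )
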