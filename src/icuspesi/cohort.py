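"""Cohort ingestion, validation, exclusions and count-based fixture expansion.

The patient-level container is a list of :class:`PatientRecord` wrapped in a
:class:`Cohort`.  Records arrive as two CSV files: one row per ICU admission
plus a long-format vitals table keyed by patient id.  A separate path expands
published score-level survivor/nonsurvivor counts into a patient-level
DataFrame so that count-based statistics (AUROC, NPV, per-level mortality)
can be recomputed without access to the raw ICU database.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

VITAL_KINDS = ("heart_rate", "systolic_bp", "respiratory_rate", "temperature_c", "spo2")

COMORBIDITY_FLAGS = (
    "cancer",
    "heart_failure",
    "asthma",
    "copd",
    "restrictive_lung_disease",
    "home_oxygen",
    "lung_transplant",
    "myocardial_infarction",
    "cabg",
    "pacemaker_or_icd",
)

#: Fields without which a record cannot be analysed (outcome, mental status,
#: and the externally supplied severity-of-illness score).
DEFAULT_KEY_FIELDS = frozenset({"died_in_hospital", "gcs_verbal", "apache_iv"})

RECORD_COLUMNS = (
    ["patient_id", "age_years", "sex", "bmi"]
    + list(COMORBIDITY_FLAGS)
    + [
        "gcs_verbal",
        "intubated_invasive",
        "intubation_offset_min",
        "noninvasive_ventilation",
        "niv_offset_min",
        "vasoactive_use",
        "vasoactive_offset_min",
        "apache_iv",
        "died_in_hospital",
        "time_to_event_days",
    ]
)

VITALS_COLUMNS = ("patient_id", "offset_min", "kind", "value")


class SchemaError(ValueError):
    """A required column is absent from an input CSV."""


class CohortValidationError(ValueError):
    """Record-level contract violation (duplicate ids, inconsistent counts...)."""


@dataclass(frozen=True)
class VitalSample:
    """One vital-sign measurement at a minute offset from ICU admission."""

    patient_id: str
    offset_min: int
    kind: str
    value: float

    def __post_init__(self) -> None:
        if self.kind not in VITAL_KINDS:
            raise CohortValidationError(f"unknown vital kind {self.kind!r}")
        if self.offset_min < 0:
            raise CohortValidationError("offset_min must be >= 0")
        if not np.isfinite(self.value):
            raise CohortValidationError("vital value must be finite")
        if self.kind == "spo2" and not 0 <= self.value <= 100:
            raise CohortValidationError(f"spo2 out of range: {self.value}")
        if self.kind == "temperature_c" and not 20 <= self.value <= 45:
            raise CohortValidationError(f"temperature out of range: {self.value}")


@dataclass
class PatientRecord:
    """One ICU admission: demographics, comorbidities, vitals, events, outcome.

    ``gcs_verbal`` is the verbal component of the Glasgow Coma Scale (1-5);
    ``None`` marks an untestable verbal response (for example an intubated
    patient charted as "T").  ``apache_iv`` is an externally computed
    APACHE-IV score carried through unchanged.  ``time_to_event_days`` is the
    time to in-hospital death for nonsurvivors and the time to discharge for
    survivors.
    """

    patient_id: str
    age_years: int
    sex: str
    died_in_hospital: bool
    time_to_event_days: float
    bmi: float | None = None
    comorbidities: dict[str, bool] = field(default_factory=dict)
    gcs_verbal: int | None = None
    vitals: list[VitalSample] = field(default_factory=list)
    intubated_invasive: bool = False
    intubation_offset_min: float | None = None
    noninvasive_ventilation: bool = False
    niv_offset_min: float | None = None
    vasoactive_use: bool = False
    vasoactive_offset_min: float | None = None
    apache_iv: int | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise CohortValidationError(f"sex must be male/female, got {self.sex!r}")
        if self.time_to_event_days < 0:
            raise CohortValidationError("time_to_event_days must be >= 0")
        if self.gcs_verbal is not None and not 1 <= self.gcs_verbal <= 5:
            raise CohortValidationError(f"gcs_verbal out of range: {self.gcs_verbal}")
        for flag in COMORBIDITY_FLAGS:
            self.comorbidities.setdefault(flag, False)


@dataclass
class Cohort:
    """Ordered collection of patient records with unique ids."""

    records: list[PatientRecord]
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate patient_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class ScoreLevelCounts:
    """Survivor/nonsurvivor counts per ordered score level.

    ``score_name`` is one of ``pesi_class``, ``spesi``, ``icu_spesi``.  Levels
    are ordered labels ("0".."5", "I".."V", ">=7"...).  Counts must satisfy
    survivor_n + nonsurvivor_n = total_n at every level.
    """

    score_name: str
    levels: list[str]
    total_n: list[int]
    survivor_n: list[int]
    nonsurvivor_n: list[int]

    def validate(self) -> None:
        n = len(self.levels)
        if not (len(self.total_n) == len(self.survivor_n) == len(self.nonsurvivor_n) == n):
            raise CohortValidationError("count arrays must have one entry per level")
        for i, lvl in enumerate(self.levels):
            if min(self.total_n[i], self.survivor_n[i], self.nonsurvivor_n[i]) < 0:
                raise CohortValidationError(f"negative count at level {lvl!r}")
            if self.survivor_n[i] + self.nonsurvivor_n[i] != self.total_n[i]:
                raise CohortValidationError(
                    f"inconsistent counts at level {lvl!r}: survivors "
                    f"{self.survivor_n[i]} + nonsurvivors {self.nonsurvivor_n[i]} != "
                    f"total {self.total_n[i]}; reconcile with "
                    f"nonsurvivor_n := total_n - survivor_n"
                )

    @property
    def numeric_levels(self) -> list[float]:
        """Ordinal value per level: integers, roman classes, and '>=k' floors."""
        return [_level_value(lbl) for lbl in self.levels]


_ROMAN = {"I": 1, "II": 2, "III": 3, "IV": 4, "V": 5}


def _level_value(label: str) -> float:
    lbl = str(label).strip()
    if lbl in _ROMAN:
        return float(_ROMAN[lbl])
    for prefix in (">=", "≥"):
        if lbl.startswith(prefix):
            return float(lbl[len(prefix):])
    return float(lbl)


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    if isinstance(x, (int, float, np.integer, np.floating)):
        if pd.isna(x):
            raise ValueError("missing boolean")
        return bool(int(x))
    s = str(x).strip().lower()
    if s in ("1", "true", "t", "yes"):
        return True
    if s in ("0", "false", "f", "no"):
        return False
    raise ValueError(f"unparseable boolean {x!r}")


def _opt_float(x) -> float | None:
    try:
        v = float(x)
    except (TypeError, ValueError):
        return None
    return None if np.isnan(v) else v


def read_cohort(records_path, vitals_path, provenance: str = "csv") -> tuple[Cohort, list[str]]:
    """Read a cohort from the records CSV plus the long-format vitals CSV.

    Returns the cohort and a list of per-row rejection reasons for rows that
    could not be turned into a valid record (missing outcome, bad age...).
    Unparseable optional fields (bmi, apache_iv, offsets) simply become
    missing.  A missing required column raises :class:`SchemaError`.
    """
    records = pd.read_csv(records_path)
    vitals = pd.read_csv(vitals_path)
    for col in ("patient_id", "age_years", "sex", "died_in_hospital", "time_to_event_days"):
        if col not in records.columns:
            raise SchemaError(f"records file is missing required column {col!r}")
    for col in VITALS_COLUMNS:
        if col not in vitals.columns:
            raise SchemaError(f"vitals file is missing required column {col!r}")

    vitals_by_id: dict[str, list[VitalSample]] = {}
    for row in vitals.itertuples(index=False):
        pid = str(row.patient_id)
        vitals_by_id.setdefault(pid, []).append(
            VitalSample(pid, int(row.offset_min), str(row.kind), float(row.value))
        )

    out: list[PatientRecord] = []
    rejections: list[str] = []
    for _, row in records.iterrows():
        pid = str(row["patient_id"])
        try:
            age = int(row["age_years"])
        except (TypeError, ValueError):
            rejections.append(f"{pid}: unparseable age_years")
            continue
        if age < 18:
            rejections.append(f"{pid}: age<18")
            continue
        try:
            died = _parse_bool(row["died_in_hospital"])
        except ValueError:
            rejections.append(f"{pid}: missing key data (died_in_hospital)")
            continue
        try:
            tte = float(row["time_to_event_days"])
            if np.isnan(tte):
                raise ValueError
        except (TypeError, ValueError):
            rejections.append(f"{pid}: missing time_to_event_days")
            continue
        comorb = {}
        for flag in COMORBIDITY_FLAGS:
            try:
                comorb[flag] = _parse_bool(row[flag]) if flag in row else False
            except ValueError:
                comorb[flag] = False
        gcs = row.get("gcs_verbal")
        gcs_val = None if pd.isna(gcs) else int(gcs)
        try:
            rec = PatientRecord(
                patient_id=pid,
                age_years=age,
                sex=str(row["sex"]).strip().lower(),
                died_in_hospital=died,
                time_to_event_days=tte,
                bmi=_opt_float(row.get("bmi")),
                comorbidities=comorb,
                gcs_verbal=gcs_val,
                vitals=sorted(vitals_by_id.get(pid, []), key=lambda v: v.offset_min),
                intubated_invasive=_safe_flag(row, "intubated_invasive"),
                intubation_offset_min=_opt_float(row.get("intubation_offset_min")),
                noninvasive_ventilation=_safe_flag(row, "noninvasive_ventilation"),
                niv_offset_min=_opt_float(row.get("niv_offset_min")),
                vasoactive_use=_safe_flag(row, "vasoactive_use"),
                vasoactive_offset_min=_opt_float(row.get("vasoactive_offset_min")),
                apache_iv=(lambda v: None if v is None else int(v))(_opt_float(row.get("apache_iv"))),
            )
        except CohortValidationError as exc:
            rejections.append(f"{pid}: {exc}")
            continue
        out.append(rec)
    return Cohort(out, provenance=provenance), rejections


def _safe_flag(row, name: str) -> bool:
    if name not in row:
        return False
    try:
        return _parse_bool(row[name])
    except ValueError:
        return False


def write_cohort(cohort: Cohort, records_path, vitals_path) -> None:
    """Write a cohort back to the two-CSV on-disk layout."""
    rec_rows = []
    vit_rows = []
    for r in cohort:
        row = {
            "patient_id": r.patient_id,
            "age_years": r.age_years,
            "sex": r.sex,
            "bmi": r.bmi,
            "gcs_verbal": r.gcs_verbal,
            "intubated_invasive": int(r.intubated_invasive),
            "intubation_offset_min": r.intubation_offset_min,
            "noninvasive_ventilation": int(r.noninvasive_ventilation),
            "niv_offset_min": r.niv_offset_min,
            "vasoactive_use": int(r.vasoactive_use),
            "vasoactive_offset_min": r.vasoactive_offset_min,
            "apache_iv": r.apache_iv,
            "died_in_hospital": int(r.died_in_hospital),
            "time_to_event_days": r.time_to_event_days,
        }
        for flag in COMORBIDITY_FLAGS:
            row[flag] = int(r.comorbidities.get(flag, False))
        rec_rows.append(row)
        for v in r.vitals:
            vit_rows.append(
                {"patient_id": v.patient_id, "offset_min": v.offset_min, "kind": v.kind, "value": v.value}
            )
    pd.DataFrame(rec_rows, columns=RECORD_COLUMNS).to_csv(records_path, index=False)
    pd.DataFrame(vit_rows, columns=list(VITALS_COLUMNS)).to_csv(vitals_path, index=False)


def apply_exclusions(
    cohort: Cohort, require: frozenset[str] | set[str] = DEFAULT_KEY_FIELDS
) -> tuple[Cohort, dict[str, int]]:
    """Split a cohort into retained records and an exclusion tally.

    A record failing several checks is counted once, under the first matching
    reason: the age criterion is checked before missing key data, so the tally
    is deterministic.  |retained| + sum(tally) == |input|.
    """
    tally = {"age<18": 0, "missing_key_data": 0}
    kept: list[PatientRecord] = []
    for r in cohort:
        if r.age_years < 18:
            tally["age<18"] += 1
            continue
        missing = False
        for key in require:
            if getattr(r, key, None) is None:
                missing = True
                break
        if missing:
            tally["missing_key_data"] += 1
            continue
        kept.append(r)
    return Cohort(kept, provenance=cohort.provenance), tally


def expand_score_level_counts(counts: ScoreLevelCounts, seed: int = 0) -> pd.DataFrame:
    """Expand score-level outcome counts into a patient-level DataFrame.

    Each row carries the score level (label and ordinal value), the death
    outcome, and a synthesized event time: deaths at day 3.7 (the cohort's
    median time to death), survivors censored at the 40-day horizon.  The
    synthesized time axis supports running the survival code on the fixture
    but is not a reconstruction of individual event times; count-based
    statistics (AUROC, NPV, per-level mortality) are exact.

    Level-wise tabulation of the output reproduces the input counts exactly.
    """
    counts.validate()
    rng = np.random.default_rng(seed)
    levels, values, died = [], [], []
    for lbl, val, surv, dead in zip(
        counts.levels, counts.numeric_levels, counts.survivor_n, counts.nonsurvivor_n
    ):
        n = surv + dead
        levels += [lbl] * n
        values += [val] * n
        died += [False] * surv + [True] * dead
    df = pd.DataFrame(
        {
            "patient_id": [f"{counts.score_name}-{i:04d}" for i in range(len(levels))],
            "score_name": counts.score_name,
            "level": levels,
            "score": values,
            "died": died,
        }
    )
    df["time_to_event_days"] = np.where(df["died"], 3.7, 40.0)
    # stable shuffle so expanded order carries no outcome information
    df = df.sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(drop=True)
    return df


def tabulate_levels(expanded: pd.DataFrame) -> ScoreLevelCounts:
    """Re-tabulate an expanded patient-level frame back into level counts."""
    name = expanded["score_name"].iloc[0] if len(expanded) else "empty"
    grouped = expanded.groupby("level", sort=False)
    order = (
        expanded.drop_duplicates("level").sort_values("score")["level"].tolist()
    )
    levels, total, surv, dead = [], [], [], []
    for lbl in order:
        g = grouped.get_group(lbl)
        levels.append(lbl)
        total.append(len(g))
        dead.append(int(g["died"].sum()))
        surv.append(len(g) - int(g["died"].sum()))
    return ScoreLevelCounts(name, levels, total, surv, dead)


def load_reference_counts(score_name: str) -> ScoreLevelCounts:
    """Load the packaged score-level count fixture for one score.

    ``score_name`` is ``pesi_class``, ``spesi`` or ``icu_spesi``.  Nonsurvivor
    counts are derived as total - survivors (reconciliation by totals).
    """
    ref = importlib.resources.files("icuspesi").joinpath("data/reference_counts.yaml")
    raw = yaml.safe_load(ref.read_text())
    if score_name not in raw:
        raise KeyError(f"no packaged counts for score {score_name!r}")
    block = raw[score_name]
    total = [int(x) for x in block["total_n"]]
    surv = [int(x) for x in block["survivor_n"]]
    counts = ScoreLevelCounts(
        score_name=score_name,
        levels=[str(x) for x in block["levels"]],
        total_n=total,
        survivor_n=surv,
        nonsurvivor_n=[t - s for t, s in zip(total, surv)],
    )
    counts.validate()
    return counts
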