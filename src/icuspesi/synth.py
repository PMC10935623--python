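"""Synthetic ICU pulmonary-embolism cohorts with known generating law.

Each patient carries a latent standard-normal severity factor.  Comorbidities
are independent Bernoulli draws at cohort-level prevalences; vital-sign time
series are noisy samples around a patient-level centre that loads on
severity; acuity events (intubation, noninvasive ventilation, vasoactive
support) and altered mental status are Bernoulli with logistic-in-severity
probabilities and uniformly distributed onset offsets inside the first 24 h.

The generator computes a ground-truth ICU-sPESI for every patient by its own
vectorised tabulation of the raw data it generated (30-minute bin medians,
directional extremes, score thresholds) — an independent code path from the
feature-extraction module, so extraction bugs show up as lost discrimination
in end-to-end tests.  In-hospital death is Bernoulli with
logit(p) = mortality_intercept + mortality_slope * true ICU-sPESI; death
times are exponential (median matching the study cohort's 3.7 days),
survivor discharge times lognormal, and survivors are assumed alive after
discharge up to the 40-day censoring horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, PatientRecord, VitalSample

#: Per-kind vitals law: (baseline mean, between-patient SD, severity loading,
#: within-patient sample SD).
DEFAULT_VITALS_MODEL = {
    "heart_rate": (92.0, 14.0, 10.0, 4.0),
    "systolic_bp": (118.0, 16.0, -10.0, 5.0),
    "respiratory_rate": (22.0, 4.5, 3.0, 1.5),
    "temperature_c": (36.8, 0.45, -0.15, 0.15),
    "spo2": (94.5, 2.5, -1.8, 1.0),
}

#: Comorbidity prevalences for the all-patients column of the study cohort
#: (calibration constants for the generator, not assertions about any
#: database); flags without a printed prevalence get a nominal small value.
DEFAULT_PREVALENCES = {
    "cancer": 0.173,
    "heart_failure": 0.081,
    "asthma": 0.030,
    "copd": 0.168,
    "restrictive_lung_disease": 0.009,
    "home_oxygen": 0.025,
    "lung_transplant": 0.001,
    "myocardial_infarction": 0.148,
    "cabg": 0.020,
    "pacemaker_or_icd": 0.018,
}

#: Age-band mixture (band bounds inclusive, weight).
DEFAULT_AGE_BANDS = (
    ((18, 60), 0.433),
    ((61, 70), 0.237),
    ((71, 80), 0.184),
    ((81, 95), 0.145),
)


@dataclass
class SyntheticConfig:
    """Generating law for a synthetic ICU-PE cohort.

    ``mortality_intercept``/``mortality_slope`` define the logistic law of
    in-hospital death on the true ICU-sPESI; the defaults use the slope of
    the univariate logistic fit to the study's score-level outcome counts
    with the intercept calibrated so the generator's own score distribution
    yields the study's ~6.3% in-hospital mortality.  ``severity loadings``
    live inside ``vitals_model`` and the acuity slopes.
    """

    n: int = 1424
    seed: int = 0
    prevalences: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCES))
    age_bands: tuple = DEFAULT_AGE_BANDS
    p_male: float = 0.499
    vitals_model: dict = field(default_factory=lambda: {k: v for k, v in DEFAULT_VITALS_MODEL.items()})
    samples_per_kind: float = 12.0
    # acuity logistic intercept/slope on severity
    intubation_coefs: tuple = (-2.4, 1.3)
    niv_coefs: tuple = (-2.6, 0.8)
    vasoactive_coefs: tuple = (-2.2, 1.3)
    ams_coefs: tuple = (-2.0, 1.1)
    mortality_intercept: float = -5.13
    mortality_slope: float = 0.88
    death_time_median_days: float = 3.7
    discharge_median_days: float = 5.7
    discharge_log_sd: float = 0.6
    horizon_days: float = 40.0

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        probs = list(self.prevalences.values()) + [self.p_male]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        # printed band percentages may round to slightly off 100%
        if abs(sum(w for _, w in self.age_bands) - 1) > 5e-3:
            raise ValueError("age band weights must sum to 1")


def _expit(x):
    return 1 / (1 + np.exp(-x))


def _generate_arrays(config: SyntheticConfig, rng: np.random.Generator) -> dict:
    """Draw all per-patient quantities as arrays; the ground-truth layer."""
    n = config.n
    severity = rng.standard_normal(n)
    weights = np.array([w for _, w in config.age_bands], dtype=float)
    band_idx = rng.choice(len(config.age_bands), size=n, p=weights / weights.sum())
    age = np.array(
        [rng.integers(config.age_bands[b][0][0], config.age_bands[b][0][1] + 1) for b in band_idx]
    )
    male = rng.random(n) < config.p_male
    comorb = {flag: rng.random(n) < p for flag, p in config.prevalences.items()}

    # long-format vitals samples
    frames = []
    for kind, (mean, bsd, load, ssd) in config.vitals_model.items():
        centre = mean + load * severity + bsd * rng.standard_normal(n)
        counts = rng.poisson(config.samples_per_kind, size=n)
        counts = np.maximum(counts, 1)
        pid_idx = np.repeat(np.arange(n), counts)
        values = centre[pid_idx] + ssd * rng.standard_normal(len(pid_idx))
        if kind == "spo2":
            values = np.clip(values, 50.0, 100.0)
        elif kind == "temperature_c":
            values = np.clip(values, 30.0, 43.0)
        else:
            values = np.maximum(values, 1.0)
        offsets = rng.integers(0, 24 * 60, size=len(pid_idx))
        frames.append(
            pd.DataFrame({"idx": pid_idx, "kind": kind, "offset_min": offsets, "value": values})
        )
    vitals = pd.concat(frames, ignore_index=True)

    # ground-truth extremes: 30-min bin medians, then directional extreme
    vitals["bin"] = vitals["offset_min"] // 30
    medians = vitals.groupby(["idx", "kind", "bin"])["value"].median().reset_index()
    agg = medians.groupby(["idx", "kind"])["value"].agg(["max", "min"]).unstack("kind")
    ext = {}
    for kind, direction in (
        ("heart_rate", "max"),
        ("respiratory_rate", "max"),
        ("systolic_bp", "min"),
        ("temperature_c", "min"),
        ("spo2", "min"),
    ):
        col = agg[(direction, kind)].reindex(range(n))
        ext[kind] = col.to_numpy(dtype=float)

    intubated = rng.random(n) < _expit(config.intubation_coefs[0] + config.intubation_coefs[1] * severity)
    niv = rng.random(n) < _expit(config.niv_coefs[0] + config.niv_coefs[1] * severity)
    vaso = rng.random(n) < _expit(config.vasoactive_coefs[0] + config.vasoactive_coefs[1] * severity)
    ams = rng.random(n) < _expit(config.ams_coefs[0] + config.ams_coefs[1] * severity)
    gcs_verbal = np.where(ams, rng.integers(1, 5, size=n), 5)
    onset = {k: rng.integers(0, 24 * 60, size=n) for k in ("intubation", "niv", "vaso")}

    lung = (
        comorb["asthma"]
        | comorb["copd"]
        | comorb["restrictive_lung_disease"]
        | comorb["home_oxygen"]
        | comorb["lung_transplant"]
    )
    cardio = (
        lung
        | comorb["heart_failure"]
        | comorb["myocardial_infarction"]
        | comorb["cabg"]
        | comorb["pacemaker_or_icd"]
    )
    spesi = (
        (age > 80).astype(int)
        + comorb["cancer"].astype(int)
        + cardio.astype(int)
        + (ext["heart_rate"] >= 110).astype(int)
        + (ext["systolic_bp"] < 100).astype(int)
        + (ext["spo2"] < 90).astype(int)
    )
    true_icu_spesi = spesi + intubated.astype(int) + ams.astype(int) + vaso.astype(int)

    p_death = _expit(config.mortality_intercept + config.mortality_slope * true_icu_spesi)
    died = rng.random(n) < p_death
    death_scale = config.death_time_median_days / np.log(2)
    death_time = rng.exponential(death_scale, size=n)
    discharge = np.exp(
        np.log(config.discharge_median_days) + config.discharge_log_sd * rng.standard_normal(n)
    )
    time_to_event = np.where(died, death_time, discharge)

    # APACHE-IV stand-in: severity-driven integer on a plausible 0-220 scale
    apache = np.clip(np.round(45 + 22 * severity + 8 * rng.standard_normal(n)), 0, 220).astype(int)

    return {
        "severity": severity,
        "age": age,
        "male": male,
        "comorb": comorb,
        "vitals": vitals,
        "extremes": ext,
        "intubated": intubated,
        "niv": niv,
        "vaso": vaso,
        "ams": ams,
        "gcs_verbal": gcs_verbal,
        "onset": onset,
        "true_spesi": spesi,
        "true_icu_spesi": true_icu_spesi,
        "p_death": p_death,
        "died": died,
        "time_to_event": time_to_event,
        "apache": apache,
    }


def generate_cohort(config: SyntheticConfig) -> tuple[Cohort, pd.DataFrame]:
    """Generate a patient-level cohort plus its ground-truth table.

    Returns (cohort, truth) where ``truth`` has one row per patient with the
    latent severity, the true sPESI / ICU-sPESI, the death probability and
    the outcome — everything a recovery test needs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    arr = _generate_arrays(config, rng)
    n = config.n
    ids = [f"synth-{config.seed}-{i:05d}" for i in range(n)]

    vit_lists: list[list[VitalSample]] = [[] for _ in range(n)]
    v = arr["vitals"]
    for idx, kind, off, val in zip(
        v["idx"].to_numpy(), v["kind"].to_numpy(), v["offset_min"].to_numpy(), v["value"].to_numpy()
    ):
        vit_lists[idx].append(VitalSample(ids[idx], int(off), kind, float(val)))

    records = []
    for i in range(n):
        records.append(
            PatientRecord(
                patient_id=ids[i],
                age_years=int(arr["age"][i]),
                sex="male" if arr["male"][i] else "female",
                died_in_hospital=bool(arr["died"][i]),
                time_to_event_days=float(arr["time_to_event"][i]),
                comorbidities={k: bool(vals[i]) for k, vals in arr["comorb"].items()},
                gcs_verbal=int(arr["gcs_verbal"][i]),
                vitals=sorted(vit_lists[i], key=lambda s: (s.offset_min, s.kind)),
                intubated_invasive=bool(arr["intubated"][i]),
                intubation_offset_min=float(arr["onset"]["intubation"][i]) if arr["intubated"][i] else None,
                noninvasive_ventilation=bool(arr["niv"][i]),
                niv_offset_min=float(arr["onset"]["niv"][i]) if arr["niv"][i] else None,
                vasoactive_use=bool(arr["vaso"][i]),
                vasoactive_offset_min=float(arr["onset"]["vaso"][i]) if arr["vaso"][i] else None,
                apache_iv=int(arr["apache"][i]),
            )
        )
    truth = pd.DataFrame(
        {
            "patient_id": ids,
            "severity": arr["severity"],
            "true_spesi": arr["true_spesi"],
            "true_icu_spesi": arr["true_icu_spesi"],
            "p_death": arr["p_death"],
            "died": arr["died"],
            "time_to_event_days": arr["time_to_event"],
        }
    )
    return Cohort(records, provenance=f"synthetic(seed={config.seed})"), truth


def generate_grouped_survival(
    levels: list, hazards: list, n_per_level: int, horizon: float = 40.0, seed: int = 0
) -> dict:
    """Exponential survival per score level, censored at the horizon.

    Returns {level: (times, events)} with event times drawn from
    Exp(hazard) and administrative censoring at ``horizon``.
    """
    if len(levels) != len(hazards):
        raise ValueError("levels and hazards must align")
    if any(h <= 0 for h in hazards):
        raise ValueError("hazards must be > 0")
    rng = np.random.default_rng(seed)
    out = {}
    for lvl, hz in zip(levels, hazards):
        raw = rng.exponential(1.0 / hz, size=n_per_level)
        events = raw <= horizon
        out[lvl] = (np.minimum(raw, horizon), events)
    return out
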