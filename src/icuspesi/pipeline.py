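"""End-to-end pipelines: score a cohort, evaluate it, reproduce the
published-count analysis, and run the observation-window sensitivity sweep.

All numeric results are computed at full precision and rounded only at the
reporting layer (three decimals for AUROC, one for percentages).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import discrimination as disc
from . import survival as surv
from .cohort import Cohort, expand_score_level_counts, load_reference_counts
from .features import WINDOW_CHOICES, FeatureConfig
from .scores import score_panel

ICU_SPESI_CLASS_MAP = {
    0.0: "I", 1.0: "I", 2.0: "I",
    3.0: "II", 4.0: "II",
    5.0: "III", 6.0: "III",
    7.0: "IV", 8.0: "IV", 9.0: "IV",
}


@dataclass
class RunConfig:
    """Configuration echo for a pipeline run."""

    window_hours: int = 24
    ventilation_mode: str = "invasive_only"
    alpha: float = 0.05
    npv_target: float = 0.99
    horizon_days: float = 40.0
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.window_hours not in WINDOW_CHOICES:
            raise ValueError(f"window_hours must be one of {WINDOW_CHOICES}")
        if not 0 < self.npv_target < 1:
            raise ValueError("npv_target must lie in (0, 1)")

    def feature_config(self) -> FeatureConfig:
        return FeatureConfig(window_hours=self.window_hours, ventilation_mode=self.ventilation_mode)


def score_cohort(cohort: Cohort, config: FeatureConfig | None = None) -> pd.DataFrame:
    """Per-patient score panel as a flat DataFrame."""
    cfg = config or FeatureConfig()
    rows = []
    for record in cohort:
        panel = score_panel(record, cfg)
        rows.append(
            {
                "patient_id": panel.patient_id,
                "pesi_points": panel.pesi_points,
                "pesi_class": panel.pesi_class,
                "spesi_points": panel.spesi_points,
                "icu_spesi_points": panel.icu_spesi_points,
                "icu_spesi_class": panel.icu_spesi_class,
                "apache_iv": panel.apache_iv,
                "died_in_hospital": record.died_in_hospital,
                "time_to_event_days": record.time_to_event_days,
            }
        )
    return pd.DataFrame(rows)


def breakdown_table(cohort: Cohort, config: FeatureConfig | None = None) -> pd.DataFrame:
    """Per-patient per-item score contributions (long format)."""
    cfg = config or FeatureConfig()
    rows = []
    for record in cohort:
        panel = score_panel(record, cfg)
        for item, points in panel.breakdown.items():
            rows.append({"patient_id": panel.patient_id, "item": item, "points": points})
    return pd.DataFrame(rows)


def follow_up(died, time_to_event_days, horizon: float = 40.0) -> tuple[np.ndarray, np.ndarray]:
    """(times, events) for survival analysis: survivors are assumed alive
    after discharge, so their follow-up extends to the censoring horizon."""
    died = np.asarray(died, dtype=bool)
    t = np.asarray(time_to_event_days, dtype=float)
    return surv.apply_horizon(np.where(died, t, horizon), died, horizon)


def run_fixture_pipeline(output_dir: str | Path | None = None, seed: int = 0) -> dict:
    """Reproduce the count-based analysis from the packaged score-level counts.

    Expands the published survivor/nonsurvivor counts per score level to
    patient level, then recomputes overall mortality, AUROCs, NPV>99%
    thresholds, per-level mortalities and the four-class ICU-sPESI mortality
    summary.  Returns the report as a dict; with ``output_dir`` also writes
    report.json plus the per-analysis CSV tables.
    """
    report: dict = {"seed": seed}
    expanded = {
        name: expand_score_level_counts(load_reference_counts(name), seed)
        for name in ("pesi_class", "spesi", "icu_spesi")
    }
    icu = expanded["icu_spesi"]
    report["overall"] = {
        "n": int(len(icu)),
        "deaths": int(icu["died"].sum()),
        "mortality_pct": round(100 * icu["died"].mean(), 1),
    }
    report["auroc"] = {
        name: round(disc.auroc(df["score"], df["died"]), 3) for name, df in expanded.items()
    }
    report["npv_threshold"] = {}
    report["npv_profile"] = {}
    for name in ("spesi", "icu_spesi"):
        df = expanded[name]
        threshold, profile = disc.npv_threshold_search(df["score"], df["died"])
        report["npv_threshold"][name] = threshold
        report["npv_profile"][name] = profile.to_dict(orient="records")
    report["mortality_by_level"] = {}
    for name, df in expanded.items():
        tab = disc.mortality_by_level(df["score"], df["died"])
        report["mortality_by_level"][name] = [
            {"level": row.level, "n": row.n, "deaths": row.deaths,
             "mortality_pct": round(100 * row.mortality, 1)}
            for row in tab.itertuples()
        ]
    cls = disc.mortality_by_level(icu["score"], icu["died"], grouping=ICU_SPESI_CLASS_MAP)
    report["icu_spesi_class_mortality"] = [
        {"class": row.level, "n": row.n, "deaths": row.deaths,
         "mortality_pct": round(100 * row.mortality, 1),
         "ci_pct": [round(100 * row.ci_low, 1), round(100 * row.ci_high, 1)]}
        for row in cls.itertuples()
    ]
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2))
        for name, df in expanded.items():
            df.to_csv(out / f"expanded_{name}.csv", index=False)
    return report


def evaluate_scores(
    scored: pd.DataFrame,
    score_columns: list[str] | None = None,
    npv_target: float = 0.99,
) -> dict:
    """Discrimination/calibration/NPV report for a scored cohort DataFrame.

    ``scored`` needs a boolean ``died_in_hospital`` column plus one numeric
    column per score.  Returns per-score ROC/AUROC, all paired AUROC
    comparisons (DeLong and Hanley–McNeil), calibration tables and NPV
    profiles.
    """
    cols = score_columns or [
        c for c in ("apache_iv", "pesi_points", "spesi_points", "icu_spesi_points")
        if c in scored.columns and scored[c].notna().all()
    ]
    y = scored["died_in_hospital"].to_numpy(dtype=bool)
    out: dict = {"roc": {}, "comparison": {}, "calibration": {}, "npv": {}}
    for c in cols:
        s = scored[c].to_numpy(dtype=float)
        rr = disc.roc_result(s, y, score_name=c)
        out["roc"][c] = {"auroc": rr.auroc, "se": rr.se_auroc, "n_pos": rr.n_pos, "n_neg": rr.n_neg}
        cal = disc.calibration_table(s, y)
        out["calibration"][c] = {
            "binning": cal.binning,
            "intercept": cal.intercept,
            "slope": cal.slope,
            "table": cal.table,
        }
        threshold, profile = disc.npv_threshold_search(s, y, npv_target)
        out["npv"][c] = {"threshold": threshold, "profile": profile}
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            sa, sb = scored[a].to_numpy(float), scored[b].to_numpy(float)
            out["comparison"][f"{a}_vs_{b}"] = {
                method: disc.compare_auroc_paired(sa, sb, y, method)
                for method in ("delong", "hanley_mcneil")
            }
    return out


def survival_report(
    scored: pd.DataFrame,
    score_column: str = "icu_spesi_points",
    alpha: float = 0.05,
    min_group_n: int = 5,
    horizon: float = 40.0,
) -> dict:
    """KM curves per score level, log-rank tests and the risk-class partition."""
    times, events = follow_up(
        scored["died_in_hospital"], scored["time_to_event_days"], horizon
    )
    s = scored[score_column].to_numpy(dtype=float)
    level_groups = {
        lvl: (times[s == lvl], events[s == lvl]) for lvl in np.unique(s)
    }
    chi2, dof, p = surv.logrank(list(level_groups.values()), horizon)
    partition = surv.build_risk_classes(level_groups, alpha, min_group_n, horizon)
    curves = {lvl: surv.km_estimate(t, e, horizon) for lvl, (t, e) in level_groups.items()}
    return {
        "logrank": {"chi2": chi2, "dof": dof, "p": p},
        "pairwise_bonferroni": surv.pairwise_logrank(
            list(level_groups.values()), "bonferroni", horizon
        ),
        "partition": partition,
        "km_curves": curves,
    }


def run_sensitivity(
    cohort: Cohort,
    windows: tuple[int, ...] = (2, 3, 6, 12, 24),
    ventilation_mode: str = "invasive_only",
) -> pd.DataFrame:
    """AUROC per observation window per score (the shorter-window sweep)."""
    rows = []
    for w in windows:
        scored = score_cohort(cohort, FeatureConfig(window_hours=w, ventilation_mode=ventilation_mode))
        y = scored["died_in_hospital"].to_numpy(dtype=bool)
        for c in ("pesi_points", "spesi_points", "icu_spesi_points"):
            rows.append(
                {"window_hours": w, "score": c, "auroc": disc.auroc(scored[c].to_numpy(float), y)}
            )
    return pd.DataFrame(rows)


def config_echo(config: RunConfig) -> str:
    """JSON echo of a run configuration, for reproducibility logs."""
    return json.dumps(asdict(config), indent=2, sort_keys=True)
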