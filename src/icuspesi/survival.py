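"""Kaplan–Meier estimation, log-rank testing and risk-class construction.

Survivors are assumed alive after hospital discharge and all follow-up is
administratively censored at a 40-day horizon.  The product-limit estimate
and the log-rank statistics are computed by lifelines; the confidence band
is the plain (untransformed) Greenwood interval, S(t) +/- 1.96 sqrt(Var),
whose symmetric bounds match the printed point-estimate +/- CI style of the
risk-class summaries (a log-log interval cannot produce a bound like 99.8%).

Risk classes group adjacent score levels whose survival curves do not differ:
a greedy left-to-right agglomeration merges the next level into the current
group while the unadjusted pairwise log-rank p-value is at or above alpha,
and starts a new group otherwise.  Levels with too few patients are pooled
with their neighbour before testing, mirroring the pooling of sparse top
scores.  The full pairwise p-value matrix is returned so alternative
groupings can be audited.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

DEFAULT_HORIZON_DAYS = 40.0


@dataclass
class KmCurve:
    times: np.ndarray          # distinct event times (days)
    at_risk: np.ndarray
    survival: np.ndarray       # S(t) at each event time
    variance: np.ndarray       # Greenwood variance at each event time
    ci_low: np.ndarray
    ci_high: np.ndarray
    censor_times: np.ndarray
    horizon: float

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class RiskClassPartition:
    labels: list[str]                 # one label per group, in score order
    member_levels: list[list[float]]  # score levels per group
    summary: pd.DataFrame             # label, n, deaths, mortality, ci_low, ci_high
    pairwise_p: pd.DataFrame          # unadjusted level-by-level log-rank p matrix


def apply_horizon(times, events, horizon: float = DEFAULT_HORIZON_DAYS) -> tuple[np.ndarray, np.ndarray]:
    """Censor all follow-up at the horizon; later events become censorings."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if (t < 0).any():
        raise ValueError("event times must be >= 0")
    return np.minimum(t, horizon), e & (t <= horizon)


def km_estimate(times, events, horizon: float = DEFAULT_HORIZON_DAYS) -> KmCurve:
    """Product-limit survival estimate with plain Greenwood 95% CI."""
    t, e = apply_horizon(times, events, horizon)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    d = event_rows["observed"].to_numpy(dtype=float)
    n = event_rows["at_risk"].to_numpy(dtype=float)
    event_times = event_rows.index.to_numpy(dtype=float)
    surv = np.array([kmf.predict(x) for x in event_times], dtype=float)
    # Greenwood: Var[S(t)] = S(t)^2 * sum_{t_i <= t} d_i / (n_i (n_i - d_i))
    with np.errstate(divide="ignore"):
        increments = np.where(n > d, d / (n * (n - d)), np.inf)
    var = surv**2 * np.cumsum(increments)
    var = np.where(np.isfinite(var), var, 0.0)
    half = 1.959963984540054 * np.sqrt(var)
    return KmCurve(
        times=event_times,
        at_risk=n,
        survival=surv,
        variance=var,
        ci_low=np.clip(surv - half, 0.0, 1.0),
        ci_high=np.clip(surv + half, 0.0, 1.0),
        censor_times=np.sort(t[~e]),
        horizon=horizon,
    )


def logrank(groups: list[tuple[np.ndarray, np.ndarray]], horizon: float = DEFAULT_HORIZON_DAYS):
    """Multigroup log-rank test; returns (chi2, dof, p)."""
    if len(groups) < 2 or any(len(t) == 0 for t, _ in groups):
        raise ValueError("log-rank requires at least two nonempty groups")
    ts, es, gs = [], [], []
    for i, (t, e) in enumerate(groups):
        t, e = apply_horizon(t, e, horizon)
        ts.append(t)
        es.append(e)
        gs.append(np.full(len(t), i))
    t = np.concatenate(ts)
    e = np.concatenate(es)
    g = np.concatenate(gs)
    if not e.any():
        warnings.warn("no events in any group: log-rank p = 1", stacklevel=2)
        return 0.0, len(groups) - 1, 1.0
    res = multivariate_logrank_test(t, g, e)
    return float(res.test_statistic), len(groups) - 1, float(res.p_value)


def pairwise_logrank(
    groups: list[tuple[np.ndarray, np.ndarray]],
    adjust: str = "none",
    horizon: float = DEFAULT_HORIZON_DAYS,
) -> np.ndarray:
    """Symmetric matrix of pairwise log-rank p-values.

    ``adjust='bonferroni'`` multiplies each p by the number of unordered
    pairs, capped at 1.  The diagonal is 1.
    """
    if adjust not in ("none", "bonferroni"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    k = len(groups)
    n_pairs = k * (k - 1) // 2
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, _, pij = logrank([groups[i], groups[j]], horizon)
            if adjust == "bonferroni":
                pij = min(1.0, n_pairs * pij)
            p[i, j] = p[j, i] = pij
    return p


def build_risk_classes(
    level_groups: dict[float, tuple[np.ndarray, np.ndarray]],
    alpha: float = 0.05,
    min_group_n: int = 5,
    horizon: float = DEFAULT_HORIZON_DAYS,
) -> RiskClassPartition:
    """Partition ordered score levels into risk classes by survival similarity.

    ``level_groups`` maps score level -> (times, events).  Sparse levels
    (fewer than ``min_group_n`` patients) are first pooled with the adjacent
    higher level (the topmost sparse level pools downward).  Then, scanning
    from the lowest level, each level is merged into the current class when
    the unadjusted pairwise log-rank p against the class so far is >= alpha,
    and opens a new class otherwise.
    """
    levels = sorted(level_groups)
    if not levels:
        raise ValueError("no score levels supplied")
    pairwise = pd.DataFrame(
        pairwise_logrank([level_groups[l] for l in levels], "none", horizon)
        if len(levels) > 1
        else np.ones((1, 1)),
        index=levels,
        columns=levels,
    )

    # pool sparse levels with their neighbour (upward; last level pools down)
    units: list[tuple[list[float], np.ndarray, np.ndarray]] = []
    for lvl in levels:
        t, e = level_groups[lvl]
        units.append(([lvl], np.asarray(t, float), np.asarray(e, bool)))
    i = 0
    while len(units) > 1 and i < len(units):
        lvls, t, e = units[i]
        if len(t) < min_group_n:
            j = i + 1 if i + 1 < len(units) else i - 1
            nl, nt, ne = units[min(i, j)]
            ol, ot, oe = units[max(i, j)]
            merged = (nl + ol, np.concatenate([nt, ot]), np.concatenate([ne, oe]))
            units[min(i, j):max(i, j) + 1] = [merged]
            i = 0  # re-scan: the merge may have fixed or created sparse units
        else:
            i += 1

    # greedy left-to-right agglomeration on the pooled units
    classes: list[tuple[list[float], np.ndarray, np.ndarray]] = [units[0]]
    for lvls, t, e in units[1:]:
        cl, ct, ce = classes[-1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, _, p = logrank([(ct, ce), (t, e)], horizon)
        if p >= alpha:
            classes[-1] = (cl + lvls, np.concatenate([ct, t]), np.concatenate([ce, e]))
        else:
            classes.append((lvls, t, e))

    roman = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]
    rows = []
    labels, members = [], []
    for idx, (lvls, t, e) in enumerate(classes):
        t, e = apply_horizon(t, e, horizon)
        n = len(t)
        d = int(e.sum())
        p_hat = d / n
        half = 1.959963984540054 * np.sqrt(p_hat * (1 - p_hat) / n)
        label = roman[idx] if idx < len(roman) else str(idx + 1)
        labels.append(label)
        members.append(sorted(lvls))
        rows.append(
            {
                "label": label,
                "levels": "+".join(str(v) for v in sorted(lvls)),
                "n": n,
                "deaths": d,
                "mortality": p_hat,
                "ci_low": max(0.0, p_hat - half),
                "ci_high": min(1.0, p_hat + half),
            }
        )
    return RiskClassPartition(labels, members, pd.DataFrame(rows), pairwise)
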