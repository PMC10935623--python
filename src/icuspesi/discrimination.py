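"""Discrimination and calibration statistics for ordinal mortality scores.

AUROC is the tie-corrected rank statistic — the probability that a randomly
chosen nonsurvivor outscores a randomly chosen survivor, with half credit for
ties.  Paired AUROC comparison follows Hanley & McNeil's correlated-areas
test, with the between-area correlation estimated as the mean of the two
scores' Pearson correlations within nonsurvivors and within survivors; the
DeLong placement-value test is provided as the reference method and default
cross-check.  A univariate logistic model of death on the score supplies the
predicted-mortality curve, tabulated against deciles (continuous scores) or
direct score values (sPESI-style small-integer scores), and the
negative-predictive-value scan finds the highest cutoff whose at-or-below
group exceeds a target survival proportion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn import metrics as sk_metrics


@dataclass
class RocResult:
    score_name: str
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auroc: float
    se_auroc: float
    n_pos: int
    n_neg: int


@dataclass
class AurocComparison:
    auroc_1: float
    auroc_2: float
    se_1: float
    se_2: float
    r: float
    z: float
    p: float
    method: str


@dataclass
class CalibrationTable:
    binning: str
    table: pd.DataFrame  # columns: bin, n, deaths, observed, predicted
    intercept: float
    slope: float


def _validate_outcomes(outcomes: np.ndarray) -> np.ndarray:
    y = np.asarray(outcomes, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("undefined AUROC: outcomes contain a single class")
    return y


def auroc(scores, outcomes) -> float:
    """Tie-corrected rank AUROC: P(score_dead > score_alive) + 0.5 P(tie)."""
    y = _validate_outcomes(np.asarray(outcomes))
    s = np.asarray(scores, dtype=float)
    ranks = stats.rankdata(s)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_result(scores, outcomes, score_name: str = "score") -> RocResult:
    """ROC curve points plus AUROC and its Hanley–McNeil standard error."""
    y = _validate_outcomes(np.asarray(outcomes))
    s = np.asarray(scores, dtype=float)
    fpr, tpr, thr = sk_metrics.roc_curve(y, s)
    a = auroc(s, y)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    return RocResult(
        score_name=score_name,
        thresholds=thr,
        sensitivity=tpr,
        specificity=1 - fpr,
        auroc=a,
        se_auroc=hanley_mcneil_se(a, n_pos, n_neg),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def hanley_mcneil_se(auroc_value: float, n_pos: int, n_neg: int) -> float:
    """Standard error of an AUROC from the binormal-free moment formula.

    SE^2 = [A(1-A) + (n_pos-1)(Q1-A^2) + (n_neg-1)(Q2-A^2)] / (n_pos n_neg)
    with Q1 = A/(2-A) and Q2 = 2A^2/(1+A).
    """
    if min(n_pos, n_neg) < 1:
        raise ValueError("both outcome groups must be nonempty")
    a = float(auroc_value)
    if a in (0.0, 1.0):
        warnings.warn("degenerate AUROC of 0 or 1: standard error is 0", stacklevel=2)
        return 0.0
    if not 0 < a < 1:
        raise ValueError(f"auroc must lie in [0, 1], got {a}")
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)) / (n_pos * n_neg)
    return float(np.sqrt(var))


def _placements(s: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values: per-case and per-control mid-rank proportions."""
    pos, neg = s[y], s[~y]
    # V10[i] = P(neg < pos_i) + 0.5 P(neg == pos_i), V01 symmetric
    order = np.sort(neg)
    lo = np.searchsorted(order, pos, side="left")
    hi = np.searchsorted(order, pos, side="right")
    v10 = (lo + 0.5 * (hi - lo)) / len(neg)
    order = np.sort(pos)
    lo = np.searchsorted(order, neg, side="left")
    hi = np.searchsorted(order, neg, side="right")
    v01 = 1 - (lo + 0.5 * (hi - lo)) / len(pos)
    return v10, v01


def compare_auroc_paired(scores_a, scores_b, outcomes, method: str = "delong") -> AurocComparison:
    """Compare two scores' AUROCs measured on the same patients.

    ``method='hanley_mcneil'`` uses z = (A1-A2)/sqrt(SE1^2+SE2^2-2 r SE1 SE2)
    with r the mean of the within-nonsurvivor and within-survivor Pearson
    correlations of the two scores.  ``method='delong'`` builds the variance
    of the AUROC difference from placement values.  Two-sided normal p.
    """
    y = _validate_outcomes(np.asarray(outcomes))
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if sa.shape != sb.shape or sa.shape[0] != y.shape[0]:
        raise ValueError("paired comparison requires the same patients under both scores")
    a1, a2 = auroc(sa, y), auroc(sb, y)
    n_pos, n_neg = int(y.sum()), int((~y).sum())

    if method == "hanley_mcneil":
        se1 = hanley_mcneil_se(a1, n_pos, n_neg)
        se2 = hanley_mcneil_se(a2, n_pos, n_neg)
        r = _between_area_correlation(sa, sb, y)
        var = se1**2 + se2**2 - 2 * r * se1 * se2
    elif method == "delong":
        v10a, v01a = _placements(sa, y)
        v10b, v01b = _placements(sb, y)
        s10 = np.cov(np.vstack([v10a, v10b]))
        s01 = np.cov(np.vstack([v01a, v01b]))
        cov = s10 / n_pos + s01 / n_neg
        se1, se2 = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
        r = float(cov[0, 1] / (se1 * se2)) if se1 > 0 and se2 > 0 else 0.0
        var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    else:
        raise ValueError(f"unknown method {method!r}")

    diff = a1 - a2
    if var <= 0:
        if abs(diff) < 1e-12:
            z = 0.0
        else:
            raise ValueError("degenerate variance in paired AUROC comparison")
    else:
        z = float(diff / np.sqrt(var))
    p = float(2 * stats.norm.sf(abs(z)))
    return AurocComparison(a1, a2, se1, se2, float(r), z, max(p, np.finfo(float).tiny), method)


def _between_area_correlation(sa: np.ndarray, sb: np.ndarray, y: np.ndarray) -> float:
    rs = []
    for mask in (y, ~y):
        if np.std(sa[mask]) > 0 and np.std(sb[mask]) > 0:
            rs.append(stats.pearsonr(sa[mask], sb[mask])[0])
        else:
            rs.append(0.0)
    return float(np.mean(rs))


def fit_mortality_model(scores, outcomes) -> tuple[float, float, np.ndarray]:
    """Univariate logistic regression of in-hospital death on the score.

    Returns (intercept, slope, per-patient predicted risk).  Complete
    separation falls back to an L2-penalised fit with a warning.
    """
    y = _validate_outcomes(np.asarray(outcomes)).astype(float)
    s = np.asarray(scores, dtype=float)
    if np.ptp(s) == 0:
        # constant score: slope is unidentified, use the flat model
        intercept = float(np.log(y.mean() / (1 - y.mean())))
        return intercept, 0.0, np.full(len(s), y.mean())
    X = sm.add_constant(s)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
            fit = sm.Logit(y, X).fit(disp=0, tol=1e-8)
        params = fit.params
    except Exception:
        warnings.warn(
            "complete separation in logistic fit; falling back to penalised estimate",
            stacklevel=2,
        )
        fit = sm.Logit(y, X).fit_regularized(disp=0, alpha=1.0, L1_wt=0.0)
        params = fit.params
    intercept, slope = float(params[0]), float(params[1])
    predicted = 1 / (1 + np.exp(-(intercept + slope * s)))
    return intercept, slope, predicted


def calibration_table(scores, outcomes, binning: str = "auto") -> CalibrationTable:
    """Observed vs model-predicted mortality per score bin.

    ``binning='deciles'`` uses equal-count quantile bins with tied score
    values kept together in the lower bin (for continuous scores such as
    PESI or APACHE-IV); ``binning='values'`` makes one bin per distinct score
    value (for small-integer scores such as sPESI / ICU-sPESI).  ``'auto'``
    picks values when there are at most 12 distinct scores.
    """
    y = _validate_outcomes(np.asarray(outcomes))
    s = np.asarray(scores, dtype=float)
    intercept, slope, predicted = fit_mortality_model(s, y)
    if binning == "auto":
        binning = "values" if len(np.unique(s)) <= 12 else "deciles"
    if binning == "values":
        labels = s
    elif binning == "deciles":
        labels = pd.qcut(pd.Series(s).rank(method="first"), 10, labels=False)
        # keep tied score values together: assign each tie group its lowest bin
        df_tmp = pd.DataFrame({"s": s, "b": labels})
        labels = df_tmp.groupby("s")["b"].transform("min").to_numpy()
    else:
        raise ValueError(f"unknown binning {binning!r}")
    df = pd.DataFrame({"bin": labels, "score": s, "died": y, "predicted": predicted})
    rows = []
    for b, g in df.groupby("bin", sort=True):
        rows.append(
            {
                "bin": b,
                "score_min": g["score"].min(),
                "score_max": g["score"].max(),
                "n": len(g),
                "deaths": int(g["died"].sum()),
                "observed": g["died"].mean(),
                "predicted": g["predicted"].mean(),
            }
        )
    return CalibrationTable(binning, pd.DataFrame(rows), intercept, slope)


def npv_threshold_search(scores, outcomes, target: float = 0.99) -> tuple[float | None, pd.DataFrame]:
    """Largest cutoff whose at-or-below group has survival proportion > target.

    Returns (threshold, profile).  The profile lists, for every observed
    score value c, the size of the score<=c group and its negative predictive
    value; threshold is None when no cutoff qualifies.
    """
    y = np.asarray(outcomes, dtype=bool)
    s = np.asarray(scores, dtype=float)
    rows = []
    best = None
    for c in np.unique(s):
        mask = s <= c
        npv = float((~y[mask]).mean())
        rows.append({"cutoff": float(c), "n_at_or_below": int(mask.sum()), "npv": npv})
        if npv > target:
            best = float(c)
    return best, pd.DataFrame(rows)


def mortality_by_level(
    scores, outcomes, grouping: dict | None = None, ci: str = "wald"
) -> pd.DataFrame:
    """Per-level (or per-class) n, deaths, mortality and 95% binomial CI.

    ``grouping`` optionally maps score values to class labels; unmapped
    values keep their own level.  ``ci`` is ``'wald'`` (symmetric, matching
    the printed point-estimate +/- CI style) or ``'wilson'``.
    """
    y = np.asarray(outcomes, dtype=bool)
    s = np.asarray(scores, dtype=float)
    labels = np.array([grouping.get(v, v) if grouping else v for v in s], dtype=object)
    order = {}
    for v, lbl in zip(s, labels):
        order.setdefault(lbl, v)
    rows = []
    for lbl in sorted(order, key=lambda k: order[k]):
        mask = labels == lbl
        n = int(mask.sum())
        d = int(y[mask].sum())
        p = d / n
        if ci == "wald":
            half = 1.959963984540054 * np.sqrt(p * (1 - p) / n)
            lo, hi = max(0.0, p - half), min(1.0, p + half)
        elif ci == "wilson":
            lo, hi = sm.stats.proportion_confint(d, n, alpha=0.05, method="wilson")
        else:
            raise ValueError(f"unknown ci {ci!r}")
        rows.append(
            {"level": lbl, "n": n, "deaths": d, "mortality": p, "ci_low": float(lo), "ci_high": float(hi)}
        )
    return pd.DataFrame(rows)
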