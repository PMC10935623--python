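import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import icuspesi as ip

settings.register_profile(
    "ci",
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_frames():
    """Patient-level expansions of the packaged score-level counts."""
    return {
        name: ip.expand_score_level_counts(ip.load_reference_counts(name), seed=0)
        for name in ("pesi_class", "spesi", "icu_spesi")
    }


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-patient synthetic cohort with its ground-truth table."""
    cohort, truth = ip.generate_cohort(ip.SyntheticConfig(n=400, seed=7))
    return cohort, truth


def brute_force_auroc(scores, outcomes):
    """Pair-enumeration AUROC oracle: mean over (dead, alive) pairs of
    1{dead > alive} + 0.5 * 1{tie}."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    pos, neg = s[y][:, None], s[~y][None, :]
    return float(((pos > neg) + 0.5 * (pos == neg)).mean())


def reference_logrank_stat(times, events, labels):
    """Independent two-group log-rank chi-square (observed-minus-expected)."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    labels = np.asarray(labels)
    obs = exp = var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (labels == 1)).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & (labels == 1)).sum()
        obs += d1
        exp += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (obs - exp) ** 2 / var if var > 0 else 0.0
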