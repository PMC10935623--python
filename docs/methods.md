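# Methods

## Scores

PESI is the patient's age in years plus fixed weights for ten items; class
cut-points are ≤65 (I), 66–85 (II), 86–105 (III), 106–125 (IV), >125 (V).
sPESI counts six equally weighted binary items; ICU-sPESI adds Intubation,
Confusion (altered mental status) and Use of vasoactive infusions, each 0/1,
for a 0–9 range with classes ≤2 / 3–4 / 5–6 / ≥7. Threshold edges follow
the source definitions exactly: HR ≥110 and RR ≥30 inclusive; SBP <100,
temperature <36 °C, SpO₂ <90% and age >80 exclusive. By construction
ICU-sPESI restricted to the six sPESI items equals sPESI, and every score is
monotone in its items (both properties are enforced by exhaustive
enumeration in the test suite).

## Feature derivation

Vital signs arrive as a long-format series of (offset-minute, kind, value).
Each kind is reduced to medians over half-open 30-minute bins aligned at ICU
admission — bin *k* covers [30k, 30(k+1)) minutes — and the score-relevant
extreme of the bin medians is kept: maximum for heart rate and respiratory
rate, minimum for systolic pressure, temperature and SpO₂ (only the low tail
of each of those scores points; a high temperature never does). Bin
alignment at admission rather than a rolling window is a determinism choice;
it is configurable ground the source material does not fix.

Kinds with no observation inside the window are imputed with normal-side
sentinels (HR 80, SBP 120, RR 16, 37.0 °C, SpO₂ 98%) chosen strictly inside
the normal range so an imputed kind can never fire a criterion; imputed
kinds are recorded on the derived features. Acuity events count only when
their onset offset is strictly below `window_hours × 60` minutes. Altered
mental status is GCS verbal <5; an untestable verbal response (e.g. an
intubated patient) defaults to AMS-present — "verbally responsive and
oriented" cannot be demonstrated — and the policy is configurable. With
`ventilation_mode="any"`, noninvasive ventilation also satisfies the
intubation item.

## Discrimination and calibration

AUROC is the tie-corrected rank statistic, P(score_dead > score_alive) +
½·P(tie), computed from midranks; it equals brute-force pair enumeration
exactly and is invariant under strictly increasing transforms. Its standard
error uses the moment formula SE² = [A(1−A) + (n₊−1)(Q₁−A²) +
(n₋−1)(Q₂−A²)]/(n₊n₋) with Q₁ = A/(2−A), Q₂ = 2A²/(1+A).

Paired comparison of two scores on the same cohort offers two methods.
The correlated-areas z-test uses z = (A₁−A₂)/√(SE₁²+SE₂²−2r·SE₁·SE₂), with
the between-areas correlation r estimated as the mean of the two scores'
Pearson correlations within nonsurvivors and within survivors. This is a
reproducible approximation to the classical tabulated conversion; it is
exact-calibrated under the exponential ROC model (where the moment SE is
exact — the equivalence test in the suite uses that model and finds
agreement with DeLong within 0.011 in p at n=1400) but **conservative for
Gaussian score distributions at high AUROC**, where the moment SE
overestimates by ~10–15% and p-values can differ from DeLong by up to ~0.1.
DeLong's placement-value method is therefore the default and reference; it
was validated to 7 decimals against an independent R implementation (pROC)
on a frozen cohort.

Calibration fits a univariate maximum-likelihood logistic model of death on
the score (tolerance 1e-8; a constant score falls back to the flat model;
complete separation falls back to an L2-penalised fit with a warning) and
tabulates observed versus mean predicted mortality per bin: equal-count
deciles with tied score values kept together in the lower bin for
continuous scores, one bin per value for small-integer scores.

The NPV search scans every observed cutoff c and reports the largest with
survivor proportion among score ≤ c strictly above the target (default
0.99), plus the full profile for audit. Per-level mortality tables use Wald
95% intervals by default — matching the symmetric point-estimate ± CI
presentation convention (e.g. an upper bound of 99.8% on 10/13) — with
Wilson available by flag.

## Survival

Follow-up is administratively censored at 40 days after ICU admission;
hospital survivors are assumed alive post-discharge, so their follow-up
extends to the horizon. Kaplan–Meier estimation and the log-rank statistics
are delegated to lifelines; the confidence band is the plain Greenwood
interval S(t) ± 1.96·√Var with Var = S(t)²·Σ dᵢ/(nᵢ(nᵢ−dᵢ)), untransformed
for the same symmetric-interval reason, clipped to [0,1]. Deaths at a tie
time are processed before censorings at that time (standard convention).
Pairwise log-rank p-values are Bonferroni-adjusted by the number of
unordered pairs, capped at 1.

Risk classes are built greedily left to right over ordered score levels:
levels with fewer than `min_group_n` (default 5) patients are first pooled
with the adjacent higher level (the topmost sparse level pools downward);
then each level merges into the current class when the unadjusted pairwise
log-rank p against the class accumulated so far is ≥ α (default 0.05), and
opens a new class otherwise. The merge order and re-test rule are not
canonical; greedy adjacent merge-then-continue was chosen for determinism,
and the full unadjusted pairwise matrix is emitted so any alternative
grouping can be audited. Each merge decision carries the usual type-I risk,
so k same-law adjacent levels collapse to one class with probability
≈ (1−α)^(k−1).

## Synthetic cohorts

Each patient draws a latent severity ~ N(0,1). Ages come from a four-band
mixture (43.3% 18–60, 23.7% 61–70, 18.4% 71–80, 14.5% 81–95) and
comorbidities are independent Bernoulli draws at the packaged prevalences
(cancer 17.3%, heart failure 8.1%, obstructive lung disease 16.8%, ...);
both are calibration constants describing a plausible ICU PE cohort, not
estimates of any database. Vitals are sampled (Poisson mean 12 per kind
over 24 h, uniform offsets) around a patient-level centre = baseline +
severity·loading + between-patient noise; acuity events and AMS are
Bernoulli with logistic-in-severity probabilities and uniform onset offsets
in [0, 24 h).

The generator computes a ground-truth ICU-sPESI by its own vectorised
tabulation of the raw data it generated (pandas groupby medians → extremes
→ thresholds) — a code path independent of the feature-extraction module,
so extraction bugs surface as lost discrimination in end-to-end tests
rather than cancelling out. Death is Bernoulli with logit(p) = −5.13 +
0.88·(true ICU-sPESI): the slope is the univariate logistic fit to the
packaged count table, the intercept solved once so the generator's own
score distribution yields ≈6.3% in-hospital mortality (giving score
discrimination ≈0.84 at n=1424). Death times are exponential with median
3.7 days; survivor discharge times are lognormal (median 5.7 days,
log-SD 0.6) and survivors are then carried to the 40-day horizon.

What the generator does **not** emulate: inter-hospital heterogeneity,
treatment effects, correlated comorbidities, missing-not-at-random vitals,
charting lag on event times, or any dependence of event *times* on
severity beyond the death/discharge split. Passing tests therefore
demonstrate the pipeline's internal correctness and statistical behaviour
under a known law, not performance on real ICU data.

## Packaged count table and its expansion

The package ships the per-level survivor/nonsurvivor counts of a published
1424-patient ICU PE cohort (PESI classes, sPESI 0–5, ICU-sPESI 0–≥7).
Nonsurvivor counts are derived as total − survivors; the one printed cell
that conflicts with its row total (sPESI level 2: printed 11, implied 18 —
only 18 makes the nonsurvivor column sum to the cohort's 90 deaths) is
reconciled by totals, and the expander raises with that reconciliation rule
when handed inconsistent counts. Expansion synthesizes event times — deaths
at day 3.7 (the cohort's median time to death), survivors censored at day
40 — which keeps the survival code runnable on the expansion but makes its
time axis conventional: count-based statistics (AUROC, NPV, mortalities)
are exact, time-based ones are not reconstructions.

## Problem sizes in the test suite

The suite runs the count-table reproduction exactly (seconds); oracle
equivalence on cohorts ≤500 (AUROC), n≤8 toys with exhaustively enumerated
permutation nulls (log-rank), and 100 cohorts of n=1400 (paired-test
agreement); parameter recovery at n=5000 (logistic) and 100 seeds × 3
levels × 300 patients (risk classes); and the generator calibration over
200 seeds at n=1424. These sizes keep the full suite under a few minutes
while leaving Monte-Carlo error well inside the asserted tolerances.
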