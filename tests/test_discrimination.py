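"""AUROC machinery, paired comparisons, calibration, NPV search."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import icuspesi as ip
from icuspesi.synth import _expit

from conftest import brute_force_auroc


class TestAuroc:
    def test_matches_pair_enumeration_on_random_cohorts(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = rng.integers(20, 501)
            s = rng.integers(0, 10, n).astype(float)
            y = rng.random(n) < 0.2
            if y.all() or not y.any():
                continue
            assert ip.auroc(s, y) == pytest.approx(brute_force_auroc(s, y), abs=1e-12)

    def test_all_ties_is_half(self):
        assert ip.auroc([3, 3, 3, 3], [True, False, True, False]) == 0.5

    def test_perfect_separation(self):
        assert ip.auroc([1, 2, 9, 8], [False, False, True, True]) == 1.0

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="undefined AUROC"):
            ip.auroc([1, 2], [True, True])

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        s = rng.random(200)
        y = rng.random(200) < 0.3
        assert ip.auroc(np.exp(3 * s), y) == pytest.approx(ip.auroc(s, y))

    @given(st.integers(0, 1000))
    def test_complement_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        s = rng.integers(0, 6, n).astype(float)
        y = rng.random(n) < 0.3
        if y.all() or not y.any():
            return
        assert ip.auroc(s, y) + ip.auroc(-s, y) == pytest.approx(1.0)


class TestHanleyMcNeilSe:
    def test_symmetric_point_closed_form(self):
        # A=0.5: Q1=Q2=1/3, SE^2 = [0.25 + (m-1)/12 + (n-1)/12]/(m n)
        m, n = 10, 20
        expect = np.sqrt((0.25 + 9 / 12 + 19 / 12) / (m * n))
        assert ip.hanley_mcneil_se(0.5, m, n) == pytest.approx(expect)

    def test_against_bootstrap_on_expanded_counts(self, fixture_frames):
        df = fixture_frames["icu_spesi"]
        s = df["score"].to_numpy()
        y = df["died"].to_numpy()
        a = ip.auroc(s, y)
        se = ip.hanley_mcneil_se(a, int(y.sum()), int((~y).sum()))
        rng = np.random.default_rng(0)
        boots = []
        for _ in range(2000):
            idx = rng.integers(0, len(s), len(s))
            yy = y[idx]
            if yy.all() or not yy.any():
                continue
            boots.append(ip.auroc(s[idx], yy))
        assert se == pytest.approx(np.std(boots), rel=0.20)

    def test_sqrt_n_scaling(self):
        se1 = ip.hanley_mcneil_se(0.8, 50, 500)
        se2 = ip.hanley_mcneil_se(0.8, 100, 1000)
        assert se1 / se2 == pytest.approx(np.sqrt(2), rel=0.02)

    def test_degenerate_auroc_warns_zero(self):
        with pytest.warns(UserWarning):
            assert ip.hanley_mcneil_se(1.0, 5, 5) == 0.0


class TestComparePaired:
    def test_score_against_itself(self):
        rng = np.random.default_rng(1)
        s = rng.random(300)
        y = rng.random(300) < 0.2
        for method in ("delong", "hanley_mcneil"):
            res = ip.compare_auroc_paired(s, s, y, method)
            assert res.z == 0.0 and res.p == pytest.approx(1.0)

    def test_shift_invariance(self):
        rng = np.random.default_rng(2)
        s = rng.integers(0, 9, 400).astype(float)
        y = rng.random(400) < 0.15
        res = ip.compare_auroc_paired(s, s + 7.0, y, "delong")
        assert res.auroc_1 == res.auroc_2 and res.z == 0.0

    def test_delong_matches_r_proc_oracle(self):
        """Frozen reference values computed with R pROC's paired DeLong test
        (roc.test, method='delong') on this exact generated cohort."""
        rng = np.random.default_rng(42)
        n = 200
        sev = rng.standard_normal(n)
        a = np.round(2 + 1.5 * sev + rng.standard_normal(n), 3)
        b = np.round(2 + 1.2 * sev + 1.2 * rng.standard_normal(n), 3)
        y = (rng.random(n) < _expit(-2.2 + 1.2 * sev)).astype(int)
        res = ip.compare_auroc_paired(a, b, y, "delong")
        assert res.auroc_1 == pytest.approx(0.7305103, abs=1e-6)
        assert res.auroc_2 == pytest.approx(0.7069454, abs=1e-6)
        assert res.z == pytest.approx(0.4618669, abs=1e-6)
        assert res.p == pytest.approx(0.6441768, abs=1e-6)

    def test_hanley_mcneil_tracks_delong_on_simulated_cohorts(self):
        """Under exponential-model scores (where the moment-formula SE is
        exact) the two paired tests give near-identical p-values."""
        diffs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = 1400
            y = rng.random(n) < 0.065
            if y.sum() < 5:
                continue
            kap = 0.85 / 0.15
            a = np.where(y, rng.exponential(kap, n), rng.exponential(1, n))
            b = 0.7 * a + 0.3 * np.where(y, rng.exponential(kap, n), rng.exponential(1, n))
            ph = ip.compare_auroc_paired(a, b, y, "hanley_mcneil").p
            pd_ = ip.compare_auroc_paired(a, b, y, "delong").p
            diffs.append(abs(ph - pd_))
        assert len(diffs) >= 95
        assert max(diffs) <= 0.02


class TestMortalityModel:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(7)
        s = rng.integers(0, 10, 5000).astype(float)
        y = rng.random(5000) < _expit(-4.0 + 0.7 * s)
        b0, b1, pred = ip.fit_mortality_model(s, y)
        import statsmodels.api as sm
        se = sm.Logit(y.astype(float), sm.add_constant(s)).fit(disp=0).bse[1]
        assert abs(b1 - 0.7) <= 3 * se
        assert np.allclose(pred, _expit(b0 + b1 * s))

    def test_independent_outcome_gives_flat_slope(self):
        rng = np.random.default_rng(8)
        s = rng.integers(0, 10, 4000).astype(float)
        y = rng.random(4000) < 0.1
        _, b1, _ = ip.fit_mortality_model(s, y)
        assert abs(b1) < 0.05

    def test_duplication_invariance(self):
        rng = np.random.default_rng(9)
        s = rng.integers(0, 6, 300).astype(float)
        y = rng.random(300) < _expit(-3 + 0.8 * s)
        b0, b1, _ = ip.fit_mortality_model(s, y)
        b0d, b1d, _ = ip.fit_mortality_model(np.tile(s, 2), np.tile(y, 2))
        assert (b0, b1) == pytest.approx((b0d, b1d), abs=1e-6)

    def test_complete_separation_falls_back_with_warning(self):
        s = np.array([0, 1, 2, 3, 10, 11, 12, 13], float)
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1], bool)
        with pytest.warns(UserWarning, match="separation"):
            b0, b1, _ = ip.fit_mortality_model(s, y)
        assert np.isfinite(b0) and np.isfinite(b1)


class TestCalibration:
    def test_per_value_observed_matches_counts(self, fixture_frames):
        df = fixture_frames["icu_spesi"]
        cal = ip.calibration_table(df["score"], df["died"], binning="values")
        obs = dict(zip(cal.table["bin"], cal.table["observed"]))
        assert obs[5.0] == pytest.approx(21 / 72)   # 29.2%
        assert obs[7.0] == pytest.approx(10 / 13)   # 76.9%
        assert cal.table["n"].sum() == len(df)

    def test_well_calibrated_simulation(self):
        rng = np.random.default_rng(12)
        s = rng.normal(50, 15, 4000)
        y = rng.random(4000) < _expit(-6 + 0.08 * s)
        cal = ip.calibration_table(s, y, binning="deciles")
        for row in cal.table.itertuples():
            band = 1.96 * np.sqrt(max(row.predicted * (1 - row.predicted), 1e-6) / row.n)
            assert abs(row.observed - row.predicted) < band + 0.02
        assert len(cal.table) == 10

    def test_single_bin_degenerate(self):
        y = np.array([True] * 3 + [False] * 17)
        cal = ip.calibration_table(np.ones(20), y, binning="values")
        assert len(cal.table) == 1
        assert cal.table["observed"].iloc[0] == pytest.approx(0.15)


class TestNpvSearch:
    def test_fixture_threshold_and_profile(self, fixture_frames):
        df = fixture_frames["spesi"]
        threshold, profile = ip.npv_threshold_search(df["score"], df["died"])
        assert threshold == 0.0
        prof = dict(zip(profile["cutoff"], profile["npv"]))
        assert prof[0.0] == pytest.approx(176 / 177)
        assert prof[1.0] == pytest.approx(571 / 580)

    def test_zero_deaths_returns_max_score(self):
        t, _ = ip.npv_threshold_search([0, 1, 2, 3], [False] * 4)
        assert t == 3.0

    def test_unattainable_target_returns_none(self):
        t, _ = ip.npv_threshold_search([0, 0, 1, 1], [True, False, True, False], target=1.0)
        assert t is None

    def test_threshold_reproducible_by_exhaustive_scan(self):
        rng = np.random.default_rng(13)
        s = rng.integers(0, 8, 800).astype(float)
        y = rng.random(800) < _expit(-5 + 0.8 * s)
        t, _ = ip.npv_threshold_search(s, y, target=0.97)
        best = None
        for c in np.unique(s):
            if (~y[s <= c]).mean() > 0.97:
                best = c
        assert t == best


class TestMortalityByLevel:
    def test_fixture_class_mortalities_with_wald_ci(self, fixture_frames):
        from icuspesi.pipeline import ICU_SPESI_CLASS_MAP
        df = fixture_frames["icu_spesi"]
        tab = ip.mortality_by_level(df["score"], df["died"], grouping=ICU_SPESI_CLASS_MAP)
        rows = {r.level: r for r in tab.itertuples()}
        assert rows["II"].deaths == 37 and rows["II"].n == 381
        assert round(100 * rows["II"].mortality, 1) == 9.7
        assert (round(100 * rows["II"].ci_low, 1), round(100 * rows["II"].ci_high, 1)) == (6.7, 12.7)
        assert (round(100 * rows["IV"].ci_low, 1), round(100 * rows["IV"].ci_high, 1)) == (54.0, 99.8)

    def test_pesi_class_v(self, fixture_frames):
        df = fixture_frames["pesi_class"]
        tab = ip.mortality_by_level(df["score"], df["died"])
        row = tab[tab["level"] == 5.0].iloc[0]
        assert row["deaths"] == 81 and row["n"] == 662
        assert round(100 * row["mortality"], 1) == 12.2
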