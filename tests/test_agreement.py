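"""Agreement statistics vs independent brute-force oracles.

Each statistic is cross-checked against a second, independent route:
regression against the normal equations, ANOVA against both a manual
sum-of-squares decomposition and ``scipy.stats.f_oneway``, Welch tests
against ``scipy.stats.ttest_ind``, and Bland-Altman against hand-computed
values.
"""
import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import limbvol as lv
from limbvol.agreement import PairedMeasurements, compute_agreement
from limbvol.errors import DegenerateFitError, InsufficientDataError


class TestLinearFit:
    def test_perfect_line(self):
        tape = np.array([1.0, 2.0, 3.0, 4.0])
        slope, intercept, r2 = lv.linear_fit(PairedMeasurements(tape, 1.1 * tape))
        assert slope == pytest.approx(1.1, rel=1e-12)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(1.0, rel=1e-12)

    def test_flat_response(self):
        pairs = PairedMeasurements(np.array([1.0, 2.0, 3.0]), np.array([2.0, 2.0, 2.0]))
        slope, _, r2 = lv.linear_fit(pairs)
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        tape = np.array([1.0, 2.0, 3.0, 4.0])
        scan = np.array([1.1, 2.3, 2.9, 4.2])
        slope, intercept, r2 = lv.linear_fit(PairedMeasurements(tape, scan))
        design = np.column_stack((tape, np.ones_like(tape)))
        beta = np.linalg.solve(design.T @ design, design.T @ scan)
        residuals = scan - design @ beta
        r2_oracle = 1.0 - residuals @ residuals / np.sum((scan - scan.mean()) ** 2)
        assert slope == pytest.approx(beta[0], abs=1e-9)
        assert intercept == pytest.approx(beta[1], abs=1e-9)
        assert r2 == pytest.approx(r2_oracle, abs=1e-9)

    def test_degenerate_predictor_rejected(self):
        pairs = PairedMeasurements(np.array([2.0, 2.0, 2.0]), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(DegenerateFitError):
            lv.linear_fit(pairs)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            lv.linear_fit(PairedMeasurements(np.array([1.0, 2.0]), np.array([1.0, 2.0])))


class TestBlandAltman:
    def test_identical_pairs_zero_bias_zero_loa(self):
        vals = np.array([1800.0, 2100.0, 2500.0, 3000.0])
        ba = lv.bland_altman(PairedMeasurements(vals, vals.copy()))
        assert ba.bias_ml == 0.0
        assert ba.loa_low_ml == 0.0 and ba.loa_high_ml == 0.0

    def test_alternating_diffs_hand_oracle(self):
        # diffs exactly +1, -1 repeated: mean 0, sample SD sqrt(n/(n-1))
        tape = np.full(6, 2000.0)
        scan = tape + np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        ba = lv.bland_altman(PairedMeasurements(tape, scan))
        sd = math.sqrt(6 / 5)
        assert ba.bias_ml == pytest.approx(0.0, abs=1e-12)
        assert ba.loa_high_ml == pytest.approx(1.96 * sd, rel=1e-12)
        assert ba.loa_low_ml == pytest.approx(-1.96 * sd, rel=1e-12)

    def test_translation_equivariance(self):
        tape = np.array([1500.0, 2000.0, 2600.0, 3100.0])
        scan = tape * 1.02
        base = lv.bland_altman(PairedMeasurements(tape, scan))
        shifted = lv.bland_altman(PairedMeasurements(tape, scan + 50.0))
        assert shifted.bias_ml == pytest.approx(base.bias_ml + 50.0, rel=1e-12)
        width = base.loa_high_ml - base.loa_low_ml
        assert shifted.loa_high_ml - shifted.loa_low_ml == pytest.approx(
            width, rel=1e-12
        )

    def test_loa_brackets_bias(self, rng):
        tape = rng.uniform(1500, 3500, 20)
        scan = tape + rng.normal(30, 80, 20)
        ba = lv.bland_altman(PairedMeasurements(tape, scan))
        assert ba.loa_low_ml <= ba.bias_ml <= ba.loa_high_ml


class TestOnewayAnova:
    def test_identical_constant_groups(self):
        f, df1, df2, p = lv.oneway_anova([[5.0, 5.0, 5.0]] * 3)
        assert f == 0.0 and p == 1.0
        assert (df1, df2) == (2, 6)

    def test_matches_manual_sum_of_squares(self):
        groups = [[1.0, 2.0, 3.0], [2.0, 3.0, 4.0], [3.0, 4.0, 5.0]]
        f, df1, df2, p = lv.oneway_anova(groups)
        # manual decomposition
        all_obs = np.concatenate(groups)
        grand = all_obs.mean()
        ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
        ssw = sum(np.sum((np.asarray(g) - np.mean(g)) ** 2) for g in groups)
        f_oracle = (ssb / 2) / (ssw / 6)
        assert f == pytest.approx(f_oracle, abs=1e-9)
        assert p == pytest.approx(float(stats.f.sf(f_oracle, 2, 6)), abs=1e-9)

    def test_matches_scipy_f_oneway(self, rng):
        groups = [rng.normal(loc, 1.0, 8) for loc in (0.0, 0.4, 1.1)]
        f, _, _, p = lv.oneway_anova(groups)
        ref = stats.f_oneway(*groups)
        assert f == pytest.approx(float(ref.statistic), abs=1e-9)
        assert p == pytest.approx(float(ref.pvalue), abs=1e-9)

    @given(k=st.floats(0.1, 50.0))
    def test_scale_invariance_of_f(self, k):
        groups = [[1.0, 2.0, 3.0], [2.0, 3.0, 4.0], [3.0, 4.0, 5.0]]
        f_base, *_ = lv.oneway_anova(groups)
        f_scaled, *_ = lv.oneway_anova([[k * x for x in g] for g in groups])
        assert f_scaled == pytest.approx(f_base, rel=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            lv.oneway_anova([[1.0, 2.0], [3.0]])


class TestWelchPairwise:
    def test_identical_groups(self):
        table = lv.welch_pairwise([[1.0, 2.0, 3.0, 4.0]] * 2)
        (test,) = table
        assert test.welch_t == 0.0
        assert test.p_raw == 1.0 and test.p_bonferroni == 1.0
        assert not test.significant

    def test_matches_scipy_ttest_oracle(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = a + 10.0
        (test,) = lv.welch_pairwise([a, b])
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert test.welch_t == pytest.approx(float(ref.statistic), abs=1e-9)
        assert test.p_raw == pytest.approx(float(ref.pvalue), abs=1e-9)
        assert test.df == pytest.approx(float(ref.df), abs=1e-9)
        assert test.p_bonferroni == min(1.0, 1 * test.p_raw)

    def test_three_groups_three_comparisons(self, rng):
        groups = [rng.normal(mu, 1.0, 6) for mu in (0.0, 0.5, 2.0)]
        table = lv.welch_pairwise(groups, labels=["w2_3", "w4_6", "w7_12"])
        assert len(table) == 3
        for test in table:
            assert test.p_bonferroni == pytest.approx(
                min(1.0, 3 * test.p_raw), rel=1e-12
            )

    def test_constant_groups_with_unequal_means(self):
        (test,) = lv.welch_pairwise([[2.0, 2.0], [5.0, 5.0]])
        assert math.isinf(test.welch_t) and test.welch_t < 0
        assert test.p_raw == 0.0

    @given(seed=st.integers(0, 10_000))
    def test_bonferroni_never_decreases_p(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.normal(rng.uniform(-1, 1), 1.0, 5) for _ in range(3)]
        table = lv.welch_pairwise(groups)
        for test in table:
            assert test.p_bonferroni >= test.p_raw
            if test.significant:  # corrected significance implies raw significance
                assert test.p_raw < 0.05


class TestComputeAgreement:
    def test_perfect_agreement_report(self):
        vals = np.array([1600.0, 2000.0, 2400.0, 3000.0])
        report = compute_agreement(PairedMeasurements(vals, vals.copy()))
        assert report.slope == pytest.approx(1.0, rel=1e-12)
        assert report.r_squared == pytest.approx(1.0, rel=1e-12)
        assert report.bias_ml == 0.0
        assert report.loa_low_ml == 0.0 and report.loa_high_ml == 0.0

    def test_per_operator_stratification(self, rng):
        tape = rng.uniform(1500, 3500, 30)
        scan = tape * 1.01 + rng.normal(0, 20, 30)
        ops = tuple(["A"] * 10 + ["B"] * 10 + ["C"] * 10)
        report = compute_agreement(PairedMeasurements(tape, scan, operators=ops))
        assert set(report.per_operator_r_squared) == {"A", "B", "C"}
        for r2 in report.per_operator_r_squared.values():
            assert 0.0 <= r2 <= 1.0

    def test_time_bin_battery_included(self, rng):
        tape = rng.uniform(1500, 3500, 12)
        scan = tape * 1.02
        bins = {
            "w2_3": rng.normal(1.0, 0.5, 5),
            "w4_6": rng.normal(1.5, 0.5, 5),
            "w7_12": rng.normal(2.0, 0.5, 5),
        }
        report = compute_agreement(PairedMeasurements(tape, scan), groups_by_bin=bins)
        assert report.anova_p is not None and 0.0 <= report.anova_p <= 1.0
        assert len(report.pairwise) == len(list(itertools.combinations(bins, 2)))

    def test_synthetic_cohort_recovery_noiseless(self):
        """Small end-to-end study: slope ~ 1, R^2 high, scan bias negative."""
        from limbvol.cohort import simulate_paired_cohort

        pairs = simulate_paired_cohort(
            20, tape_sigma_cm=0.0, surface_sigma_cm=0.0, seed=77, points_per_view=2500
        )
        slope, _, r2 = lv.linear_fit(pairs)
        assert slope == pytest.approx(1.0, abs=0.02)
        assert r2 >= 0.99
        assert lv.bland_altman(pairs).bias_ml < 0.0  # inscribed-polygon direction
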