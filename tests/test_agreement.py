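"""Agreement battery: CCC, Pearson, MAE/RMSE, Bland-Altman, t-test, Fisher Z."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from fhoc import (
    GeneratorConfig,
    bland_altman,
    ccc,
    error_metrics,
    fisher_z,
    gen_cohort,
    gen_paired_measurements,
    paired_t,
    pearson_ci,
    stratified_agreement,
)

paired_arrays = hnp.arrays(
    np.float64, st.integers(5, 40),
    elements=st.floats(-50, 50, allow_nan=False, width=32),
)


def manual_ccc(x, y):
    """Direct evaluation of Lin's formula with 1/n moments."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sx2 = sum((v - mx) ** 2 for v in x) / n
    sy2 = sum((v - my) ** 2 for v in y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    return 2 * sxy / (sx2 + sy2 + (mx - my) ** 2)


class TestCCC:
    def test_identity_line(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert ccc(x, x).value == pytest.approx(1.0)

    def test_perfect_anticorrelation_zero_mean(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        assert ccc(x, -x).value == pytest.approx(-1.0)

    def test_matches_formula_oracle(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [1.1, 2.0, 3.2, 3.9]
        assert ccc(x, y).value == pytest.approx(manual_ccc(x, y), abs=1e-12)

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(0)
        x = rng.normal(25, 10, 200)
        y = x + rng.normal(0, 1, 200)
        est = ccc(x, y)
        assert est.ci_low <= est.value <= est.ci_high
        assert est.ci_high - est.ci_low < 0.05  # tight at n=200, near-identity

    def test_degenerate_equal_constants_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            ccc([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(paired_arrays, st.floats(-3, 3), st.floats(0.1, 3), st.floats(-5, 5))
    def test_ccc_never_exceeds_pearson(self, x, slope, scale, shift):
        """Lin's inequality |CCC| <= |r| <= 1 on randomized paired data."""
        y = slope * x * scale + shift + np.linspace(0, 1, len(x))
        if np.std(x) < 1e-6 or np.std(y) < 1e-6:
            return
        c = ccc(x, y).value
        r = np.corrcoef(x, y)[0, 1]
        assert abs(c) <= abs(r) + 1e-9
        assert abs(r) <= 1 + 1e-12

    def test_ccc_equals_r_when_moments_match(self):
        """CCC == r exactly when the two methods share mean and variance."""
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 3.0, 5.0, 4.0])  # same mean, same variance
        c = ccc(x, y).value
        r = np.corrcoef(x, y)[0, 1]
        assert c == pytest.approx(r, abs=1e-12)


class TestPearson:
    def test_bias_irrelevance(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        est = pearson_ci(x, 2 * x + 3)
        assert est.value == pytest.approx(1.0)

    def test_hand_computed_r(self):
        # r((1,2,3), (1,3,2)) = 0.5; pad pairs to meet the CI sample-size floor
        x = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        y = np.array([1.0, 3.0, 2.0, 1.0, 3.0, 2.0])
        assert pearson_ci(x, y).value == pytest.approx(0.5)

    def test_null_simulation_near_zero(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=10_000), rng.normal(size=10_000)
        est = pearson_ci(x, y)
        assert abs(est.value) < 0.05
        assert est.ci_low < est.value < est.ci_high

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_ci([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


class TestErrorMetrics:
    def test_zero_when_equal(self):
        x = np.array([1.0, 2.0, 3.0])
        mae, rmse = error_metrics(x, x, n_boot=200, seed=0)
        assert mae.value == 0.0 and rmse.value == 0.0

    @pytest.mark.parametrize(
        "diffs, mae_exp, rmse_exp",
        [((1.0, -1.0, 1.0, -1.0), 1.0, 1.0),
         ((0.0, 0.0, 3.0), 1.0, np.sqrt(3.0))],
    )
    def test_hand_computed(self, diffs, mae_exp, rmse_exp):
        y = np.zeros(len(diffs))
        mae, rmse = error_metrics(np.array(diffs), y, n_boot=200, seed=0)
        assert mae.value == pytest.approx(mae_exp)
        assert rmse.value == pytest.approx(rmse_exp)

    def test_mae_never_exceeds_rmse(self, rng):
        for _ in range(25):
            x = rng.normal(size=rng.integers(2, 30))
            mae, rmse = error_metrics(x, np.zeros_like(x), n_boot=150, seed=1)
            assert mae.value <= rmse.value + 1e-12

    def test_bootstrap_reproducible_bit_for_bit(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        a = error_metrics(x, y, n_boot=500, seed=11)
        b = error_metrics(x, y, n_boot=500, seed=11)
        assert a == b

    def test_small_n_boot_warns(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="fhoc.agreement"):
            error_metrics([1.0, 2.0], [0.0, 0.0], n_boot=50, seed=0)
        assert any("n_boot" in r.message for r in caplog.records)


class TestBlandAltman:
    def test_identical_measurements(self):
        x = np.array([1.0, 2.0, 3.0])
        ba = bland_altman(x, x)
        assert ba.bias_mm == 0.0
        assert ba.loa_low_mm == ba.loa_high_mm == 0.0
        assert ba.prop_bias_slope == 0.0

    def test_normal_null_coverage_near_95pct(self):
        rng = np.random.default_rng(5)
        y = rng.normal(25, 10, 10_000)
        x = y + rng.normal(0, 1, 10_000)
        ba = bland_altman(x, y)
        assert ba.pct_within_loa == pytest.approx(95.0, abs=1.0)
        assert ba.loa_low_mm <= ba.bias_mm <= ba.loa_high_mm

    def test_planted_proportional_bias_recovered(self):
        rng = np.random.default_rng(6)
        m = rng.uniform(10, 40, 500)
        x = m + 0.05 * m + rng.normal(0, 0.2, 500)
        y = m - 0.05 * m + rng.normal(0, 0.2, 500)
        ba = bland_altman(x, y)  # diff = 0.1 * mean + noise
        assert ba.prop_bias_slope == pytest.approx(0.1, abs=0.02)
        assert ba.prop_bias_p < 0.01


class TestPairedT:
    def test_symmetric_differences_give_t_zero(self):
        t, p = paired_t(np.array([1.0, -1.0]), np.zeros(2))
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_t(self):
        t, _ = paired_t(np.array([1.0, 2.0, 3.0]), np.zeros(3))
        assert t == pytest.approx(2 * np.sqrt(3.0))

    def test_large_planted_bias_detected(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=100)
        _, p = paired_t(y + 2.0, y + rng.normal(0, 0.5, 100))
        assert p < 0.001

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            paired_t(np.array([1.0, 1.0]), np.array([0.0, 0.0]))


class TestFisherZ:
    def test_equal_correlations(self):
        z, p = fisher_z(0.9, 100, 0.9, 50)
        assert z == 0.0
        assert p == 1.0

    def test_hand_computed_example(self):
        z, p = fisher_z(0.9, 103, 0.8, 103)
        assert z == pytest.approx((np.arctanh(0.9) - np.arctanh(0.8)) / np.sqrt(0.02))
        assert z == pytest.approx(2.642, abs=5e-4)
        assert p < 0.01

    def test_antisymmetry(self):
        z1, p1 = fisher_z(0.7, 60, 0.4, 80)
        z2, p2 = fisher_z(0.4, 80, 0.7, 60)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_r_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(1.0, 50, 0.5, 50)


@pytest.fixture(scope="module")
def paired_cohort():
    cohort = gen_cohort(GeneratorConfig(n_per_sex_per_agegroup=25, seed=21))
    return gen_paired_measurements(cohort, bias_mm=0.0, noise_sd_mm=0.8, seed=22)


class TestStratifiedAgreement:
    def test_overall_equals_single_stratum_pool(self, paired_cohort):
        overall = stratified_agreement(paired_cohort, by=None, n_boot=200, seed=3)
        assert len(overall) == 1
        females = paired_cohort[paired_cohort.sex == "female"]
        by_sex = stratified_agreement(females, by="sex", n_boot=200, seed=3)
        assert len(by_sex) == 1  # only present levels are reported
        pooled = stratified_agreement(females, by=None, n_boot=200, seed=3)
        assert by_sex[0].report == pooled[0].report

    def test_age_sex_grid_yields_24_reports(self, paired_cohort):
        res = stratified_agreement(paired_cohort, by=("age", "sex"), n_boot=150, seed=3)
        assert len(res) == 24
        assert not any(r.insufficient for r in res)

    def test_planted_sex_specific_bias_recovered(self):
        cohort = gen_cohort(GeneratorConfig(n_per_sex_per_agegroup=25, seed=31))
        males = cohort.sex == "male"
        ref = gen_paired_measurements(cohort, bias_mm=0.0, noise_sd_mm=0.3, seed=32)
        ref.loc[males, "reference_mm"] -= 0.5  # males: AI reads 0.5 mm high
        res = stratified_agreement(ref, by="sex", n_boot=150, seed=3)
        by_label = {r.label["sex"]: r.bland_altman for r in res}
        assert abs(by_label["male"].bias_mm) > 0.4
        assert abs(by_label["female"].bias_mm) < 0.1

    def test_insufficient_strata_reported_not_dropped(self, paired_cohort):
        tiny = paired_cohort[paired_cohort.sex == "female"].iloc[:2]
        both = pd.concat([paired_cohort[paired_cohort.sex == "male"], tiny])
        res = stratified_agreement(both, by="sex", n_boot=150, seed=3)
        flags = {r.label["sex"]: r.insufficient for r in res}
        assert flags == {"female": True, "male": False}

    def test_unknown_stratum_key_rejected(self, paired_cohort):
        with pytest.raises(ValueError, match="unknown stratum"):
            stratified_agreement(paired_cohort, by="height")

    def test_missing_reference_column_rejected(self):
        cohort = gen_cohort(GeneratorConfig(n_per_sex_per_agegroup=2, seed=1))
        with pytest.raises(ValueError, match="reference_mm"):
            stratified_agreement(cohort, by="sex")
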