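"""Outlier fences, descriptives, group tests, FP fits, unit conversion."""

import numpy as np
import pandas as pd
import pytest

from amhcut import (
    compare_groups,
    correlate,
    describe,
    filter_outliers,
    fit_fractional_polynomial,
    genII_to_picoAMH,
    tukey_fences,
)
from amhcut.preprocess import chi_square_test


class TestTukeyFences:
    def test_constant_input(self):
        f = tukey_fences([5, 5, 5, 5, 5])
        assert f.iqr == 0 and (f.lower, f.upper) == (5, 5) and f.n_excluded == 0

    def test_hand_computed_example(self):
        # linear-interpolation quartiles of 1..9 plus one outlier at 100
        f = tukey_fences([1, 2, 3, 4, 5, 6, 7, 8, 9, 100])
        assert f.q1 == pytest.approx(3.25)
        assert f.q3 == pytest.approx(7.75)
        assert f.iqr == pytest.approx(4.5)
        assert f.upper == pytest.approx(14.5)
        assert f.n_excluded == 1

    def test_sign_symmetry(self):
        vals = [-10, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 20]
        f = tukey_fences(vals)
        g = tukey_fences([-v for v in vals])
        assert g.lower == pytest.approx(-f.upper)
        assert g.upper == pytest.approx(-f.lower)
        assert g.n_excluded == f.n_excluded

    def test_too_few_or_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            tukey_fences([1, 2, 3])
        with pytest.raises(ValueError):
            tukey_fences([1, 2, 3, np.nan])


@pytest.fixture
def spiked_cohort():
    """Controls 1..8, cases 10..17 plus one extreme case value."""
    vals = list(range(1, 9)) + list(range(10, 18)) + [500.0]
    groups = ["control"] * 8 + ["case"] * 9
    return pd.DataFrame({"id": range(len(vals)), "amh": vals, "group": groups})


class TestFilterOutliers:
    def test_single_extreme_removed(self, spiked_cohort):
        res = filter_outliers(spiked_cohort)
        assert res.n_excluded == 1
        assert list(res.excluded.amh) == [500.0]
        # per-group fence verification
        assert res.fences["case"].n_excluded == 1
        assert res.fences["control"].n_excluded == 0

    def test_idempotent(self, spiked_cohort):
        once = filter_outliers(spiked_cohort)
        twice = filter_outliers(once.cohort)
        assert twice.n_excluded == 0
        pd.testing.assert_frame_equal(once.cohort, twice.cohort)

    def test_counts_reconcile_and_order_preserved(self, default_cohort):
        res = filter_outliers(default_cohort)
        assert len(res.cohort) + res.n_excluded == len(default_cohort)
        assert list(res.cohort.id) == sorted(res.cohort.id)
        # no survivor lies outside its own group's fences
        for g, f in res.fences.items():
            v = res.cohort.loc[res.cohort.group == g, "amh"]
            assert ((v >= f.lower) & (v <= f.upper)).all()

    def test_unknown_variable(self, spiked_cohort):
        with pytest.raises(KeyError):
            filter_outliers(spiked_cohort, "lh_fsh_ratio")


class TestDescribe:
    def test_small_examples(self):
        frame = pd.DataFrame({"v": [1, 2, 3], "group": ["a"] * 3})
        row = describe(frame, ["v"]).iloc[0]
        assert (row["mean"], row["median"], row.sd) == (2, 2, 1)
        frame2 = pd.DataFrame({"v": [2, 4], "group": ["a"] * 2})
        row2 = describe(frame2, ["v"]).iloc[0]
        assert row2.q1 == pytest.approx(2.5)
        assert row2.q3 == pytest.approx(3.5)

    def test_order_invariance(self, default_cohort):
        shuffled = default_cohort.sample(frac=1, random_state=0).reset_index(drop=True)
        a = describe(default_cohort, ["amh"]).round(12)
        b = describe(shuffled, ["amh"]).round(12)
        pd.testing.assert_frame_equal(a, b)

    def test_case_median_exceeds_control(self, default_cohort):
        d = describe(default_cohort, ["amh"]).set_index("group")
        assert d.loc["case", "median"] > d.loc["control", "median"]


class TestCompareGroups:
    def test_identical_groups_mann_whitney(self):
        frame = pd.DataFrame(
            {"v": list(range(20)) * 2, "group": ["a"] * 20 + ["b"] * 20}
        )
        res = compare_groups(frame, "v", "mann_whitney")
        assert res.p_value >= 0.99

    def test_synthetic_amh_difference_significant(self, default_cohort):
        res = compare_groups(default_cohort, "amh", "mann_whitney")
        assert res.p_value < 0.001
        res_t = compare_groups(default_cohort, "amh", "t")
        assert res_t.p_value < 0.001

    def test_balanced_contingency_table(self):
        res = chi_square_test([[10, 10], [10, 10]])
        assert res.statistic == 0 and res.p_value == 1

    @pytest.mark.parametrize("tf", ["exp", "cube", "affine"])
    def test_mann_whitney_monotone_invariance(self, default_cohort, tf):
        transform = {
            "exp": np.exp, "cube": lambda v: v**3, "affine": lambda v: 3 * v + 1,
        }[tf]
        sub = (
            default_cohort.groupby("group", group_keys=False)
            .head(200)
            .copy()
        )
        p0 = compare_groups(sub, "amh", "mann_whitney").p_value
        sub["amh"] = transform(sub["amh"] / sub["amh"].max())
        p1 = compare_groups(sub, "amh", "mann_whitney").p_value
        assert p1 == pytest.approx(p0, rel=1e-9)


class TestCorrelate:
    def test_perfect_linear(self):
        x = np.arange(1.0, 20.0)
        for method in ("pearson", "spearman"):
            r, _ = correlate(x, 2 * x, method)
            assert r == pytest.approx(1.0)

    def test_amh_age_negative(self, default_cohort):
        r, p = correlate(default_cohort.amh, default_cohort.age, "pearson")
        assert r < -0.4 and p < 0.001

    def test_amh_bmi_null(self, default_cohort):
        sub = default_cohort.head(1000)
        r, p = correlate(sub.amh, sub.bmi, "pearson")
        assert abs(r) < 0.05 and p > 0.05


class TestFractionalPolynomial:
    def test_reciprocal_signal(self):
        x = np.linspace(0.5, 5, 60)
        fit = fit_fractional_polynomial(x, 3.0 / x, degree=1)
        assert fit.powers == (-1.0,)
        assert fit.deviance == pytest.approx(0.0, abs=1e-12)

    def test_log_signal(self):
        x = np.linspace(0.5, 5, 60)
        fit = fit_fractional_polynomial(x, 1.5 + 2.0 * np.log(x), degree=1)
        assert fit.powers == (0.0,)
        assert fit.deviance == pytest.approx(0.0, abs=1e-12)

    def test_constant_response(self):
        x = np.linspace(1, 4, 30)
        fit = fit_fractional_polynomial(x, np.full_like(x, 7.0), degree=1)
        assert fit.deviance == pytest.approx(0.0, abs=1e-10)

    def test_degree_two_repeated_power(self):
        x = np.linspace(0.5, 5, 80)
        y = 1.0 + 2.0 * x + 0.5 * x * np.log(x)
        fit = fit_fractional_polynomial(x, y, degree=2)
        assert fit.powers == (1.0, 1.0)
        assert fit.deviance == pytest.approx(0.0, abs=1e-10)

    def test_nonpositive_x_rejected(self):
        with pytest.raises(ValueError):
            fit_fractional_polynomial([0.0, 1, 2, 3], [1, 2, 3, 4])


@pytest.mark.parametrize(
    "gen2,pico", [(0.0, 0.01), (1.0, 1.70), (4.7, 7.953)]
)
def test_genII_to_picoAMH(gen2, pico):
    assert genII_to_picoAMH(gen2) == pytest.approx(pico)


def test_genII_negative_rejected():
    with pytest.raises(ValueError):
        genII_to_picoAMH(-1.0)
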