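"""Reliability and validity statistics against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kneecdi import (
    RatingsMatrix,
    UndefinedStatisticError,
    ValidationError,
    group_summary,
    icc,
    linear_trend,
    percent_reduction,
    sample_with_moments,
    spearman,
    srm,
    two_sample_t,
)


def icc_oracle(x, model):
    """Brute-force two-way ANOVA sums of squares, written independently."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.sum() / (n * k)
    ss_rows = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if model == "3,1":
        return (msr - mse) / (msr + (k - 1) * mse)
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


class TestICC:
    def test_perfect_agreement(self):
        x = np.tile(np.array([[1.0], [2.0], [5.0], [9.0]]), (1, 3))
        m = RatingsMatrix(x)
        assert icc(m, "3,1") == pytest.approx(1.0)
        assert icc(m, "2,1") == pytest.approx(1.0)

    def test_constant_offset_penalized_only_by_model_2(self):
        base = np.array([1.0, 2.0, 5.0, 9.0, 4.0])
        x = np.stack([base, base + 3.0], axis=1)
        m = RatingsMatrix(x)
        assert icc(m, "3,1") == pytest.approx(1.0)
        assert icc(m, "2,1") < 1.0

    @pytest.mark.parametrize("model", ["2,1", "3,1"])
    def test_random_matrices_match_anova_oracle(self, model):
        rng = np.random.default_rng(42)
        for _ in range(50):
            x = rng.normal(size=(6, 3)) + rng.normal(size=(6, 1)) * 2
            assert icc(RatingsMatrix(x), model) == pytest.approx(
                icc_oracle(x, model), abs=1e-10
            )

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        x = rng.normal(size=(8, 3)) + rng.normal(size=(8, 1)) * 1.5
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(8), 3),
                "raters": np.tile(np.arange(3), 8),
                "score": x.ravel(),
            }
        )
        res = pingouin.intraclass_corr(
            df, targets="targets", raters="raters", ratings="score"
        ).set_index("Type")["ICC"]
        m = RatingsMatrix(x)
        # McGraw–Wong labels: (A,1) = agreement = ICC(2,1); (C,1) = ICC(3,1)
        assert icc(m, "2,1") == pytest.approx(res["ICC(A,1)"], abs=1e-8)
        assert icc(m, "3,1") == pytest.approx(res["ICC(C,1)"], abs=1e-8)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            icc(RatingsMatrix(np.ones((4, 2))), "3,1")

    def test_convergence_to_analytic_icc(self):
        # targets ~ N(0, s_t^2), errors ~ N(0, s_e^2):
        # ICC(3,1) -> s_t^2 / (s_t^2 + s_e^2); bias < 0.02 at n=200, k=2
        s_t, s_e = 2.0, 1.0
        analytic = s_t**2 / (s_t**2 + s_e**2)
        rng = np.random.default_rng(0)
        est = []
        for _ in range(100):
            t = rng.normal(0, s_t, size=(200, 1))
            x = t + rng.normal(0, s_e, size=(200, 2))
            est.append(icc(RatingsMatrix(x), "3,1"))
        assert abs(np.mean(est) - analytic) < 0.02

    def test_bad_shapes_rejected(self):
        with pytest.raises(ValidationError):
            RatingsMatrix(np.ones(5))
        with pytest.raises(ValidationError):
            RatingsMatrix(np.ones((1, 3)))
        with pytest.raises(ValidationError):
            RatingsMatrix(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestSRM:
    def test_reconstructed_moment_sample(self):
        changes = sample_with_moments(-35.73, 50.14, n=74, seed=1)
        assert np.mean(changes) == pytest.approx(-35.73, abs=1e-9)
        assert np.std(changes, ddof=1) == pytest.approx(50.14, abs=1e-9)
        assert round(srm(changes), 2) == -0.71

    def test_zero_sd_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            srm([3.0, 3.0, 3.0])

    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=40))
    @settings(derandomize=True, max_examples=60)
    def test_antisymmetry(self, changes):
        arr = np.asarray(changes)
        if arr.std(ddof=1) == 0:
            return
        assert srm(-arr) == pytest.approx(-srm(arr), rel=1e-9, abs=1e-12)


class TestSpearman:
    def test_monotone_limits(self):
        x = np.arange(10.0)
        assert spearman(x, x**3 + 2) == pytest.approx(1.0)
        assert spearman(x, -x - 5) == pytest.approx(-1.0)

    def test_ties_match_midrank_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0, 8.0])
        y = np.array([2.0, 1.0, 4.0, 4.0, 6.0, 7.0, 6.0, 9.0])

        def midranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j + 1 < len(v) and sv[j + 1] == sv[i]:
                    j += 1
                ranks[order[i : j + 1]] = (i + j) / 2 + 1
                i = j + 1
            return ranks

        rx, ry = midranks(x), midranks(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_constant_vector_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestLinearTrend:
    def test_recovers_planted_slope(self):
        rng = np.random.default_rng(8)
        grades = rng.integers(0, 4, size=40).astype(float)
        y = 1000.0 - 100.0 * grades + rng.normal(0, 30, size=40)
        res = linear_trend(y, grades)
        assert abs(res.slope - (-100.0)) < 3 * res.stderr
        assert res.p < 0.01

    def test_exact_linear_p_underflows(self):
        grades = np.array([0.0, 1, 2, 3, 0, 1, 2, 3])
        res = linear_trend(5.0 - 2.0 * grades, grades)
        assert res.slope == pytest.approx(-2.0)
        assert res.p < 1e-10

    def test_single_grade_rejected(self):
        with pytest.raises(ValidationError):
            linear_trend([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        g = rng.integers(0, 4, 30).astype(float)
        y = rng.normal(size=30)
        perm = rng.permutation(30)
        a = linear_trend(y, g)
        b = linear_trend(y[perm], g[perm])
        assert a.slope == pytest.approx(b.slope, rel=1e-12)
        assert a.p == pytest.approx(b.p, rel=1e-9)


class TestTwoSampleT:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0, 4.0]
        t, p = two_sample_t(g, g)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_swap_negates_t(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 20), rng.normal(1, 1, 20)
        t1, p1 = two_sample_t(a, b)
        t2, p2 = two_sample_t(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_power_at_one_sd_shift(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(200):
            a = rng.normal(0, 1, 30)
            b = rng.normal(1, 1, 30)
            _, p = two_sample_t(a, b)
            hits += p < 0.05
        assert hits >= 160  # >= 80 % power

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValidationError):
            two_sample_t([1.0], [1.0, 2.0])


class TestGroupSummaryAndPercent:
    def test_single_stratum_flags_trend(self):
        df = pd.DataFrame({"g": [1, 1, 1], "y": [2.0, 3.0, 4.0]})
        out = group_summary(df, "g", "y")
        assert out.attrs["trend"] is None
        assert out.attrs["trend_error"] is not None
        assert out.loc[0, "mean"] == pytest.approx(3.0)

    def test_equal_outcomes_zero_slope(self):
        df = pd.DataFrame({"g": [0, 0, 1, 1], "y": [5.0, 5.0, 5.0, 5.0]})
        out = group_summary(df, "g", "y")
        assert out.attrs["trend"].slope == pytest.approx(0.0)

    def test_recovers_planted_stratum_means(self):
        rng = np.random.default_rng(4)
        g = np.repeat([0, 1, 2, 3], 25)
        y = 1000 - 150 * g + rng.normal(0, 40, size=100)
        out = group_summary(pd.DataFrame({"g": g, "y": y}), "g", "y")
        for _, row in out.iterrows():
            planted = 1000 - 150 * row["g"]
            se = row["sd"] / np.sqrt(row["n"])
            assert abs(row["mean"] - planted) < 3 * se

    @pytest.mark.parametrize(
        "ref,cmp,expected",
        [(1177.40, 762.74, 35), (1177.40, 421.72, 64), (500.0, 500.0, 0)],
    )
    def test_percent_reduction(self, ref, cmp, expected):
        assert percent_reduction(ref, cmp) == expected

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValidationError):
            percent_reduction(0.0, 10.0)
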