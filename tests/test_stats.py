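import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msaccade.stats import (bonferroni_pairwise, gg_epsilon, linear_trend,
                            mauchly_test, rm_anova_two_way)


def _spherical_data(n=10, k=3, seed=0):
    """Data whose orthonormal-contrast sample covariance is exactly identity."""
    rng = np.random.default_rng(seed)
    z = rng.normal(size=(n, k - 1))
    z = z - z.mean(axis=0)
    # whiten so that cov(z) == I to machine precision
    z = z @ np.linalg.inv(np.linalg.cholesky(np.cov(z, rowvar=False, ddof=1))).T
    raw = np.zeros((k, k - 1))
    for j in range(k - 1):
        raw[: j + 1, j] = 1.0
        raw[j + 1, j] = -(j + 1)
    c = raw / np.linalg.norm(raw, axis=0)
    return z @ c.T + rng.normal(size=(n, 1)) + 5.0  # subject offsets + grand mean


#: 6 subjects x 3 visual-load x 3 mental-load cell means; expected values
#: frozen from an independent reference implementation of the GG-corrected
#: repeated-measures ANOVA run on this exact matrix
def _fixture_cube():
    rng = np.random.default_rng(12)
    return (rng.normal(0, 0.3, size=(6, 3, 3))
            + np.linspace(0, 0.8, 3)[None, :, None]
            + np.array([0.0, -0.1, 0.1])[None, None, :]
            + rng.normal(0, 0.2, size=(6, 1, 1)))


class TestMauchly:
    def test_spherical_data(self):
        res = mauchly_test(_spherical_data())
        assert res.W == pytest.approx(1.0, abs=1e-10)
        assert res.chi2 == pytest.approx(0.0, abs=1e-8)
        assert res.p == pytest.approx(1.0, abs=1e-8)

    def test_df_for_three_levels_is_two(self):
        res = mauchly_test(np.random.default_rng(1).normal(size=(8, 3)))
        assert res.df == 2

    def test_rank_one_covariance_maximally_violated(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=(8,))
        y = np.column_stack([z, z, np.zeros(8)])  # near-singular contrast cov
        res = mauchly_test(y)
        assert res.W < 1e-12
        assert res.p < 1e-20

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(8, 3)) + rng.normal(size=(8, 1))
        res = mauchly_test(x)
        # independent direct evaluation: explicit contrast scores,
        # determinant/trace ratio, chi-square approximation
        c = np.array([[1 / math.sqrt(2), 1 / math.sqrt(6)],
                      [-1 / math.sqrt(2), 1 / math.sqrt(6)],
                      [0.0, -2 / math.sqrt(6)]])
        scores = x @ c
        diff = scores - scores.mean(axis=0)
        s = diff.T @ diff / (len(x) - 1)
        W = np.linalg.det(s) / (np.trace(s) / 2) ** 2
        assert res.W == pytest.approx(W, abs=1e-10)
        f = (2 * 4 + 2 + 2) / (6.0 * 2 * 7)
        chi2 = -(1 - f) * 7 * math.log(W)
        assert res.chi2 == pytest.approx(chi2, abs=1e-10)

    def test_matches_independent_implementation(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        x = np.random.default_rng(3).normal(size=(8, 3))
        res = mauchly_test(x)
        ref = pg.sphericity(pd.DataFrame(x))
        assert res.W == pytest.approx(ref.W, abs=1e-10)
        assert res.chi2 == pytest.approx(ref.chi2, abs=1e-10)
        assert res.p == pytest.approx(ref.pval, abs=1e-10)

    def test_fixture_against_reference(self):
        view_means = _fixture_cube().mean(axis=2)
        res = mauchly_test(view_means)
        assert res.W == pytest.approx(0.8728332637, abs=1e-9)
        assert res.p == pytest.approx(0.761837906, abs=1e-7)


class TestGgEpsilon:
    def test_spherical_data_epsilon_one(self):
        assert gg_epsilon(_spherical_data()) == pytest.approx(1.0, abs=1e-12)

    def test_rank_one_contrast_covariance_hits_lower_bound(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=(10, 1))
        y = np.column_stack([z[:, 0], -z[:, 0], np.zeros(10)])
        assert gg_epsilon(y) == pytest.approx(0.5, abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounds_hold_for_any_input(self, seed):
        x = np.random.default_rng(seed).normal(size=(6, 3))
        eps = gg_epsilon(x)
        assert 0.5 - 1e-12 <= eps <= 1.0 + 1e-12


class TestRmAnova:
    def test_flat_data_gives_zero_f(self):
        y = np.ones((6, 3, 3)) * 2.5
        for res in rm_anova_two_way(y):
            assert res.F == 0.0
            assert res.p_gg == 1.0

    def test_raw_dfs_for_18_subjects(self):
        y = np.random.default_rng(0).normal(size=(18, 3, 3))
        view, count, inter = rm_anova_two_way(y)
        assert (view.df_num, view.df_den) == (2, 34)
        assert (count.df_num, count.df_den) == (2, 34)
        assert (inter.df_num, inter.df_den) == (4, 68)

    def test_fixture_matches_explicit_ss_decomposition(self):
        y = _fixture_cube()
        n, a, b = y.shape
        grand = y.mean()
        # independent oracle: nested-loop sums of squares
        ss = dict(A=0.0, B=0.0, AB=0.0, AS=0.0, BS=0.0, ABS=0.0)
        for i in range(a):
            ss["A"] += n * b * (y[:, i, :].mean() - grand) ** 2
        for j in range(b):
            ss["B"] += n * a * (y[:, :, j].mean() - grand) ** 2
        for i in range(a):
            for j in range(b):
                ss["AB"] += n * (y[:, i, j].mean() - y[:, i, :].mean()
                                 - y[:, :, j].mean() + grand) ** 2
        for s in range(n):
            for i in range(a):
                ss["AS"] += b * (y[s, i, :].mean() - y[s].mean()
                                 - y[:, i, :].mean() + grand) ** 2
            for j in range(b):
                ss["BS"] += a * (y[s, :, j].mean() - y[s].mean()
                                 - y[:, :, j].mean() + grand) ** 2
            for i in range(a):
                for j in range(b):
                    ss["ABS"] += (y[s, i, j] - y[s, i, :].mean() - y[s, :, j].mean()
                                  - y[:, i, j].mean() + y[s].mean()
                                  + y[:, i, :].mean() + y[:, :, j].mean() - grand) ** 2
        view, count, inter = rm_anova_two_way(y)
        assert view.F == pytest.approx((ss["A"] / 2) / (ss["AS"] / 10), abs=1e-8)
        assert count.F == pytest.approx((ss["B"] / 2) / (ss["BS"] / 10), abs=1e-8)
        assert inter.F == pytest.approx((ss["AB"] / 4) / (ss["ABS"] / 20), abs=1e-8)

    def test_fixture_against_reference_implementation(self):
        # frozen from an independent GG-corrected RM-ANOVA on this matrix
        view, count, inter = rm_anova_two_way(_fixture_cube())
        assert view.F == pytest.approx(24.29392, abs=1e-4)
        assert view.epsilon_gg == pytest.approx(0.887180190614, abs=1e-9)
        assert view.p_gg == pytest.approx(0.000309463962232, abs=1e-9)
        assert count.epsilon_gg == pytest.approx(0.991219448312, abs=1e-9)
        assert inter.F == pytest.approx(0.57031, abs=1e-4)
        assert inter.epsilon_gg == pytest.approx(0.558657448463, abs=1e-9)
        assert inter.p_gg == pytest.approx(0.599030664872196, abs=1e-9)

    def test_matches_pingouin_main_effects(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        y = np.random.default_rng(7).normal(size=(9, 3, 3))
        rows = [{"subj": s, "A": f"a{i}", "B": f"b{j}", "y": y[s, i, j]}
                for s in range(9) for i in range(3) for j in range(3)]
        ref = pg.rm_anova(dv="y", within=["A", "B"], subject="subj",
                          data=pd.DataFrame(rows), detailed=True)
        view, count, _ = rm_anova_two_way(y)
        assert view.F == pytest.approx(float(ref.loc[0, "F"]), rel=1e-9)
        assert count.F == pytest.approx(float(ref.loc[1, "F"]), rel=1e-9)
        assert view.p_raw == pytest.approx(float(ref.loc[0, "p_unc"]), abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_f_invariant_to_global_and_subject_shifts(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=(6, 3, 3))
        base = rm_anova_two_way(y)
        shifted = y + 3.7 + rng.normal(size=(6, 1, 1))
        for r0, r1 in zip(base, rm_anova_two_way(shifted)):
            assert r1.F == pytest.approx(r0.F, rel=1e-6)
            assert r1.epsilon_gg == pytest.approx(r0.epsilon_gg, rel=1e-6)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            rm_anova_two_way(np.zeros((1, 3, 3)))


class TestBonferroni:
    def test_identical_columns_give_p_one(self):
        x = np.tile(np.arange(5.0)[:, None], (1, 3))
        res = bonferroni_pairwise(x)
        assert all(r.t == 0.0 and r.p_bonferroni == 1.0 for r in res)

    def test_three_levels_three_comparisons(self):
        x = np.random.default_rng(0).normal(size=(6, 3))
        assert len(bonferroni_pairwise(x)) == 3

    def test_adjusted_p_is_three_times_raw_clipped(self):
        from scipy import stats as sps
        x = np.random.default_rng(1).normal(size=(8, 3))
        x[:, 2] += 2.0
        for r in bonferroni_pairwise(x, labels=["a", "b", "c"]):
            i, j = ["a", "b", "c"].index(r.pair[0]), ["a", "b", "c"].index(r.pair[1])
            t_ref, p_ref = sps.ttest_rel(x[:, i], x[:, j])
            assert r.p_raw == pytest.approx(p_ref, abs=1e-12)
            assert r.p_bonferroni == pytest.approx(min(1.0, 3 * p_ref), abs=1e-12)
            assert r.p_bonferroni >= r.p_raw


class TestLinearTrend:
    def test_flat_data_zero_f(self):
        F, df, p = linear_trend(np.ones((6, 3)))
        assert F == 0.0 and p == 1.0

    def test_df_is_one_and_n_minus_one(self):
        x = np.random.default_rng(0).normal(size=(18, 3))
        _, df, _ = linear_trend(x)
        assert df == (1, 17)

    def test_monotone_means_detected(self):
        rng = np.random.default_rng(6)
        x = np.array([0.5, 0.9, 1.1]) + rng.normal(0, 0.05, size=(18, 3))
        F, _, p = linear_trend(x)
        assert p < 0.001

    def test_equals_one_sample_t_on_contrast(self):
        from scipy import stats as sps
        x = np.random.default_rng(9).normal(size=(12, 3))
        F, _, p = linear_trend(x)
        t = sps.ttest_1samp(x[:, 2] - x[:, 0], 0.0)
        assert F == pytest.approx(t.statistic ** 2, rel=1e-12)
        assert p == pytest.approx(t.pvalue, abs=1e-12)
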