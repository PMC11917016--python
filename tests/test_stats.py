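import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from alpskit.errors import DataValidationError, InsufficientDesignError
from alpskit.stats import (
    ancova_group,
    classify_subjects,
    cohens_d,
    cohens_d_from_summary,
    dichotomize,
    linreg_standardized,
    log_transform_wmh,
    mann_whitney_u,
)


class TestClassify:
    def table(self, cdr, ratio):
        return pd.DataFrame({"cdr_global": [cdr], "abeta_ratio": [ratio]})

    def test_ad(self):
        assert classify_subjects(self.table(0.5, 0.04), cutoff=0.05).iloc[0] == "AD"

    def test_hc(self):
        assert classify_subjects(self.table(0.0, 0.09), cutoff=0.08).iloc[0] == "HC"

    def test_unclassified(self):
        assert pd.isna(classify_subjects(self.table(0.0, 0.04), cutoff=0.05).iloc[0])

    def test_boundary_inclusive_positive(self):
        # amyloid-positive boundary is inclusive: ratio == cutoff -> positive
        assert classify_subjects(self.table(1.0, 0.05), cutoff=0.05).iloc[0] == "AD"

    def test_ratio_fallback_from_components(self):
        t = pd.DataFrame(
            {"cdr_global": [0.5], "abeta_ratio": [np.nan], "abeta42": [4.0], "abeta40": [100.0]}
        )
        assert classify_subjects(t, cutoff=0.05).iloc[0] == "AD"

    def test_missing_everything_stays_unclassified(self):
        t = pd.DataFrame({"cdr_global": [0.5], "abeta_ratio": [np.nan]})
        assert pd.isna(classify_subjects(t, cutoff=0.05).iloc[0])


class TestCohensD:
    def test_identical_groups_zero(self):
        assert cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_hand_computed_oracle(self):
        # groups {0,1} vs {2,3}: pooled SD = sqrt(0.5), d = -2 / sqrt(0.5)
        assert cohens_d([0, 1], [2, 3]) == pytest.approx(-2.8284271247, abs=1e-9)

    def test_summary_matches_sample_route(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.4, 1.2, 25)
        via_summary = cohens_d_from_summary(
            x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y)
        )
        assert cohens_d(x, y) == pytest.approx(via_summary, rel=1e-12)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(DataValidationError):
            cohens_d([1.0, 1.0], [1.0, 1.0])

    def test_small_groups_rejected(self):
        with pytest.raises(InsufficientDesignError):
            cohens_d([1.0], [1.0, 2.0])


class TestAncova:
    def test_exact_group_gap_noise_free(self):
        n = 20
        g = np.array(["AD"] * n + ["HC"] * n)
        age = np.linspace(60, 80, 2 * n)
        sex = np.tile([0, 1], n)
        delta = 0.21
        y = 1.0 + delta * (g == "AD") + 0.01 * age + 0.05 * sex
        df = pd.DataFrame({"group": g, "age": age, "sex": sex, "alps": y})
        res = ancova_group(df, "alps")
        assert res.coef == pytest.approx(delta, abs=1e-12)

    def test_identical_groups(self):
        # same (outcome, covariate) profiles in both groups, outcome NOT a
        # linear function of the covariates -> group coefficient exactly 0
        vals = np.tile([1.0, 1.4, 1.1, 1.35, 1.2, 1.05, 1.3, 1.25, 1.15, 1.38], 2)
        df = pd.DataFrame(
            {"group": ["AD"] * 10 + ["HC"] * 10, "age": np.tile(np.arange(10), 2),
             "sex": [0, 1] * 10, "alps": vals}
        )
        res = ancova_group(df, "alps")
        assert res.cohens_d == 0.0
        assert abs(res.coef) < 1e-12
        assert res.p > 0.99

    def test_matches_statsmodels(self, rng):
        """Independent oracle: independent library oracle."""
        import statsmodels.api as sm

        n = 40
        df = pd.DataFrame(
            {
                "group": rng.permutation(["AD"] * 20 + ["HC"] * 20),
                "age": rng.normal(70, 5, n),
                "sex": rng.integers(0, 2, n),
                "alps": rng.normal(1.3, 0.15, n),
            }
        )
        res = ancova_group(df, "alps")
        X = sm.add_constant(
            np.column_stack([(df.group == "AD").astype(float), df.age, df.sex])
        )
        fit = sm.OLS(df.alps, X).fit()
        assert res.coef == pytest.approx(np.asarray(fit.params)[1], rel=1e-10)
        assert res.t == pytest.approx(np.asarray(fit.tvalues)[1], rel=1e-10)
        assert res.p == pytest.approx(np.asarray(fit.pvalues)[1], rel=1e-8)

    def test_small_group_rejected(self):
        df = pd.DataFrame(
            {"group": ["AD", "HC", "HC", "HC"], "age": [1, 2, 3, 4], "sex": [0, 1, 0, 1],
             "alps": [1.0, 1.1, 1.2, 1.3]}
        )
        with pytest.raises(InsufficientDesignError):
            ancova_group(df, "alps")

    def test_balanced_covariates_reduce_to_mean_difference(self):
        # identical covariate values in both groups -> adjusted coef == raw gap
        age = np.array([60.0, 65.0, 70.0, 75.0])
        df = pd.DataFrame(
            {
                "group": ["AD"] * 4 + ["HC"] * 4,
                "age": np.tile(age, 2),
                "sex": [0, 1, 0, 1] * 2,
                "alps": np.concatenate([age * 0.01 + 1.0, age * 0.01 + 1.3]),
            }
        )
        res = ancova_group(df, "alps")
        assert res.coef == pytest.approx(res.mean_ad - res.mean_hc, abs=1e-10)


SIX_ROW_FIXTURE = pd.DataFrame(
    {
        "y": [1.30, 1.10, 1.25, 1.05, 1.40, 1.20],
        "x": [0.062, 0.041, 0.055, 0.038, 0.071, 0.049],
        "age": [66.0, 74.0, 69.0, 78.0, 62.0, 71.0],
        "sex": [0, 1, 0, 1, 1, 0],
    }
)


def normal_equations_oracle(df, outcome, predictor, covariates):
    """Independent oracle: closed-form z-scored OLS via explicit normal equations."""
    z = lambda v: (v - v.mean()) / v.std(ddof=1)
    cols = [predictor, *covariates]
    X = [np.ones(len(df))]
    for c in cols:
        v = df[c].to_numpy(float)
        X.append(v if set(np.unique(v)) <= {0.0, 1.0} else z(v))
    X = np.column_stack(X)
    y = z(df[outcome].to_numpy(float))
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    se = np.sqrt(np.diag(resid @ resid / dof * xtx_inv))
    r2 = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
    adj = 1 - (1 - r2) * (len(y) - 1) / (len(y) - (X.shape[1] - 1) - 1)
    p = 2 * sps.t.sf(abs(beta[1] / se[1]), dof)
    return beta[1], se[1], adj, p


class TestLinreg:
    def test_outcome_equals_predictor(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0], "x": [1.0, 2.0, 3.0, 4.0]})
        res = linreg_standardized(df, "y", "x")
        assert res.beta == pytest.approx(1.0, abs=1e-12)
        assert res.adj_r2 == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_predictor_near_zero(self, rng):
        n = 5000
        df = pd.DataFrame({"y": rng.normal(size=n), "x": rng.normal(size=n)})
        res = linreg_standardized(df, "y", "x")
        assert abs(res.beta) < 4 / np.sqrt(n)

    def test_six_row_fixture_matches_normal_equations(self):
        res = linreg_standardized(SIX_ROW_FIXTURE, "y", "x", ("age", "sex"))
        b, se, adj, p = normal_equations_oracle(SIX_ROW_FIXTURE, "y", "x", ("age", "sex"))
        assert res.beta == pytest.approx(b, rel=1e-10)
        assert res.se == pytest.approx(se, rel=1e-10)
        assert res.adj_r2 == pytest.approx(adj, rel=1e-10)
        assert res.p == pytest.approx(p, rel=1e-8)
        assert res.n == 6

    def test_six_row_fixture_matches_statsmodels(self):
        import statsmodels.api as sm

        df = SIX_ROW_FIXTURE
        z = lambda v: (v - v.mean()) / v.std(ddof=1)
        X = sm.add_constant(np.column_stack([z(df.x), z(df.age), df.sex]))
        fit = sm.OLS(z(df.y), X).fit()
        res = linreg_standardized(df, "y", "x", ("age", "sex"))
        assert res.beta == pytest.approx(np.asarray(fit.params)[1], rel=1e-10)
        assert res.se == pytest.approx(np.asarray(fit.bse)[1], rel=1e-10)
        assert res.adj_r2 == pytest.approx(fit.rsquared_adj, rel=1e-10)

    def test_listwise_deletion_reports_n(self):
        df = SIX_ROW_FIXTURE.copy()
        df.loc[0, "age"] = np.nan
        res = linreg_standardized(df, "y", "x", ("age", "sex"))
        assert res.n == 5

    def test_adjusted_r2_never_exceeds_r2(self, rng):
        df = pd.DataFrame(
            {"y": rng.normal(size=30), "x": rng.normal(size=30), "age": rng.normal(size=30)}
        )
        res = linreg_standardized(df, "y", "x", ("age",))
        # recompute plain R^2 independently
        _, _, adj, _ = normal_equations_oracle(df, "y", "x", ("age",))
        assert res.adj_r2 == pytest.approx(adj, rel=1e-10)

    @settings(max_examples=25, deadline=None)
    @given(
        scale_y=st.floats(0.01, 100.0), shift_y=st.floats(-50, 50),
        scale_x=st.floats(0.01, 100.0), shift_x=st.floats(-50, 50),
    )
    def test_standardized_beta_affine_invariant(self, scale_y, shift_y, scale_x, shift_x):
        df = SIX_ROW_FIXTURE.copy()
        base = linreg_standardized(df, "y", "x", ("age", "sex"))
        df["y"] = df["y"] * scale_y + shift_y
        df["x"] = df["x"] * scale_x + shift_x
        res = linreg_standardized(df, "y", "x", ("age", "sex"))
        assert abs(res.beta) == pytest.approx(abs(base.beta), rel=1e-6)
        assert res.adj_r2 == pytest.approx(base.adj_r2, rel=1e-6)


def mw_enumeration_oracle(x, y):
    """Independent oracle: exact two-sided p by enumerating all labelings."""
    pooled = np.concatenate([x, y])
    nx = len(x)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    us = []
    for comb in itertools.combinations(range(len(pooled)), nx):
        r = sps.rankdata(pooled)[list(comb)]
        us.append(r.sum() - nx * (nx + 1) / 2)
    us = np.asarray(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return u_obs, min(1.0, p)


class TestMannWhitney:
    def test_textbook_example(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(2 / 6, abs=1e-12)

    def test_all_tied(self):
        u, p = mann_whitney_u([5, 5, 5], [5, 5])
        assert u == 3 * 2 / 2

    def test_u_plus_uprime_identity(self, rng):
        for _ in range(50):
            nx, ny = rng.integers(1, 10, 2)
            x = rng.integers(0, 6, nx).astype(float)  # ties likely
            y = rng.integers(0, 6, ny).astype(float)
            u1, _ = mann_whitney_u(x, y)
            u2, _ = mann_whitney_u(y, x)
            assert u1 + u2 == nx * ny

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_p_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        nx = int(rng.integers(2, 5))
        ny = int(rng.integers(2, 9 - nx))
        vals = rng.permutation(np.arange(20, dtype=float))[: nx + ny]  # tie-free
        x, y = vals[:nx], vals[nx:]
        u, p = mann_whitney_u(x, y)
        u_o, p_o = mw_enumeration_oracle(x, y)
        assert u == u_o
        assert p == pytest.approx(p_o, abs=1e-12)

    def test_large_sample_uniform_p_under_null(self, rng):
        ps = []
        for _ in range(500):
            x = rng.normal(size=15)
            y = rng.normal(size=15)
            ps.append(mann_whitney_u(x, y)[1])
        stat, p = sps.kstest(ps, "uniform")
        assert p > 0.001  # p-values approximately uniform under the null

    def test_empty_rejected(self):
        with pytest.raises(DataValidationError):
            mann_whitney_u([], [1.0])


class TestWmhTransforms:
    def test_log_transform_values(self):
        out = log_transform_wmh([0.0, 9.0, 999.0])
        assert np.allclose(out, [0.0, 1.0, 3.0])

    def test_negative_rejected(self):
        with pytest.raises(DataValidationError):
            log_transform_wmh([-1.0])


class TestDichotomize:
    def test_mmse_boundary(self):
        df = pd.DataFrame({"mmse": [26, 27, 30]})
        labels = dichotomize(df, "mmse", "mmse27")
        assert list(labels) == ["low", "high", "high"]

    def test_cdr_boundary(self):
        df = pd.DataFrame({"cdr_global": [0.0, 0.5, 1.0]})
        labels = dichotomize(df, "cdr_global", "cdr0")
        assert list(labels) == ["low", "high", "high"]

    def test_unknown_rule(self):
        with pytest.raises(DataValidationError):
            dichotomize(pd.DataFrame({"x": [1]}), "x", "nope")
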