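import numpy as np
import pandas as pd
import pytest
from scipy import integrate, special, stats

from megfalff.cohort import make_cohort
from megfalff.glm import (FALFFRegression, leverage_check, partial_r_to_t,
                          permutation_fwe, report_clusters, t_to_partial_r,
                          t_to_z)
from megfalff.volume import VolumeGrid


@pytest.fixture(scope="module")
def cohort48():
    return make_cohort(48, seed=7)


def _random_model(cohort, n_vox=6, seed=0, **kw):
    rng = np.random.default_rng(seed)
    Y = rng.normal(size=(len(cohort), n_vox))
    return FALFFRegression(Y, cohort, **kw)


class TestFit:
    def test_residual_df_matches_design(self, cohort48):
        res = _random_model(cohort48).fit()
        assert res.df == 43
        assert res.df_model == 4

    def test_matches_statsmodels_ols(self, cohort48):
        """Voxel-wise t, F and R^2 agree with an independent OLS fit."""
        import statsmodels.api as sm
        model = _random_model(cohort48, n_vox=4, seed=1)
        res = model.fit()
        for v in range(4):
            fit = sm.OLS(model.Y[:, v], model.X).fit()
            assert -fit.tvalues[1] == pytest.approx(res.t[v], rel=1e-10)
            assert fit.rsquared == pytest.approx(res.r2[v], rel=1e-10)
            assert fit.fvalue == pytest.approx(res.F_all[v], rel=1e-10)

    def test_f_consistent_with_r2(self, cohort48):
        res = _random_model(cohort48, n_vox=10, seed=2).fit()
        n, p = 48, 5
        f_from_r2 = (res.r2 / (p - 1)) / ((1 - res.r2) / (n - p))
        assert np.allclose(res.F_all, f_from_r2, atol=1e-10)

    def test_perfect_fit_is_capped_and_flagged(self, cohort48):
        Y = np.column_stack([-2.0 * cohort48["happiness"].to_numpy() + 1.0,
                             np.random.default_rng(3).normal(size=48)])
        res = FALFFRegression(Y, cohort48).fit()
        assert res.perfect_fit[0] and not res.perfect_fit[1]
        assert np.isfinite(res.z).all()

    def test_partial_r_sign_convention(self, cohort48):
        """Reported t tests the negative association; partial r keeps the raw sign."""
        rng = np.random.default_rng(4)
        h = cohort48["happiness"].to_numpy()
        Y = np.column_stack([-h + 0.1 * rng.normal(size=48),
                             h + 0.1 * rng.normal(size=48)])
        res = FALFFRegression(Y, cohort48).fit()
        assert res.t[0] > 0 and res.partial_r[0] < 0
        assert res.t[1] < 0 and res.partial_r[1] > 0

    def test_collinear_design_names_column(self, cohort48):
        df = cohort48.copy()
        df["iq"] = 2.0 * df["age"]
        with pytest.raises(ValueError, match="iq"):
            _random_model(df)

    def test_permuted_trait_null_calibration(self, cohort48):
        """Type-I error of the contrast test at alpha=.05 under a permuted trait."""
        rng = np.random.default_rng(5)
        n_sims = 400
        df = cohort48.copy()
        hits = 0
        for _ in range(n_sims):
            df["happiness"] = rng.permutation(df["happiness"].to_numpy())
            Y = rng.normal(size=(48, 1))
            res = FALFFRegression(Y, df).fit()
            p = 2 * stats.t.sf(abs(res.t[0]), res.df)
            hits += p < 0.05
        ci = 3 * np.sqrt(0.05 * 0.95 / n_sims)
        assert abs(hits / n_sims - 0.05) < ci


class TestEffectSizeConversions:
    @pytest.mark.parametrize("t,df,expected", [
        (4.43, 43, 0.56), (3.28, 43, 0.45), (-0.58, 43, -0.09), (0.0, 43, 0.0),
    ])
    def test_published_conversions(self, t, df, expected):
        assert round(t_to_partial_r(t, df), 2) == pytest.approx(expected)

    def test_roundtrip_identity(self):
        r = np.linspace(-0.95, 0.95, 39)
        for df in (1, 5, 43, 500):
            back = t_to_partial_r(partial_r_to_t(r, df), df)
            assert np.allclose(back, r, atol=1e-12)

    def test_agrees_with_pingouin_partial_corr(self, cohort48):
        """|t|/sqrt(t^2+df) equals the partial correlation computed directly."""
        import pingouin as pg
        rng = np.random.default_rng(6)
        df = cohort48.copy()
        df["y"] = (-0.5 * df["happiness"] + 0.02 * df["iq"]
                   + rng.normal(size=48))
        res = FALFFRegression(df[["y"]].to_numpy(), df).fit()
        expected = pg.partial_corr(df, x="happiness", y="y",
                                   covar=["sex", "age", "iq"])["r"].iloc[0]
        assert res.partial_r[0] == pytest.approx(expected, abs=1e-10)

    def test_df_validation(self):
        with pytest.raises(ValueError):
            t_to_partial_r(1.0, 0)
        with pytest.raises(ValueError):
            t_to_z(1.0, 0)


class TestTtoZ:
    def test_zero_maps_to_zero(self):
        assert t_to_z(0.0, 5) == 0.0

    def test_converges_to_normal_for_large_df(self):
        assert t_to_z(1.96, 100_000) == pytest.approx(1.96, abs=1e-3)

    def test_matches_numerical_integration_oracle(self):
        """z at (t=2, df=10) from direct quadrature of the t density."""
        df = 10
        pdf = lambda x: (special.gamma((df + 1) / 2)
                         / (np.sqrt(df * np.pi) * special.gamma(df / 2))
                         * (1 + x**2 / df) ** (-(df + 1) / 2))
        tail, _ = integrate.quad(pdf, 2.0, np.inf)
        expected = stats.norm.isf(tail)
        assert t_to_z(2.0, 10) == pytest.approx(expected, rel=1e-8)

    def test_monotone_sign_preserving_and_finite_in_tails(self):
        t = np.array([-60.0, -3.0, -0.5, 0.0, 0.5, 3.0, 60.0])
        z = t_to_z(t, 20)
        assert np.all(np.diff(z) > 0)
        assert np.all(np.sign(z) == np.sign(t))
        assert np.all(np.isfinite(z))


class TestLeverage:
    def test_balanced_identical_rows(self):
        X = np.tile([1.0, 2.0], (10, 1))
        X = np.column_stack([X[:, 0], np.tile([0, 1], 5)])  # rank 2, two groups
        h, _ = leverage_check(X)
        assert np.allclose(np.sort(np.unique(h.round(12))), [0.2, 0.2][:1])

    def test_sum_equals_column_count(self, cohort48):
        model = _random_model(cohort48)
        h, _ = leverage_check(model.X)
        assert h.sum() == pytest.approx(5.0, abs=1e-10)

    def test_extreme_subject_has_maximal_leverage_and_is_flagged(self, cohort48):
        df = cohort48.copy()
        df.loc[0, "age"] = 90.0
        model = _random_model(df)
        h, flags = leverage_check(model.X, threshold=0.21)
        assert np.argmax(h) == 0
        assert flags[0]

    def test_results_leverage_accessor(self, cohort48):
        res = _random_model(cohort48).fit()
        h, flags = res.leverage(threshold=0.21)
        assert h.shape == (48,)


class TestClusters:
    def _grid(self):
        return VolumeGrid(affine=np.diag([2.0, 2.0, 2.0, 1.0]), shape=(12, 12, 12))

    def test_single_voxel_cluster_volume(self):
        t = np.zeros((12, 12, 12))
        t[5, 5, 5] = 4.0
        out = report_clusters(t, self._grid(), threshold=3.0)
        assert len(out) == 1
        assert out.loc[0, "k_voxels"] == 1
        assert out.loc[0, "k_mm3"] == pytest.approx(8.0)
        assert (out.loc[0, ["x_mm", "y_mm", "z_mm"]] == [10.0, 10.0, 10.0]).all()

    def test_twenty_three_voxel_cluster_is_184_mm3(self):
        t = np.zeros((12, 12, 12))
        idx = np.unravel_index(np.arange(23), (3, 3, 3))
        t[idx[0] + 4, idx[1] + 4, idx[2] + 4] = 5.0
        out = report_clusters(t, self._grid(), threshold=3.0)
        assert out.loc[0, "k_voxels"] == 23
        assert out.loc[0, "k_mm3"] == pytest.approx(184.0)

    def test_corner_touching_components_split_under_6_connectivity(self):
        t = np.zeros((12, 12, 12))
        t[2, 2, 2] = 4.0
        t[3, 3, 3] = 4.5  # touches only at a corner
        assert len(report_clusters(t, self._grid(), 3.0, connectivity=26)) == 1
        assert len(report_clusters(t, self._grid(), 3.0, connectivity=6)) == 2

    def test_empty_map_gives_empty_report(self):
        out = report_clusters(np.zeros((12, 12, 12)), self._grid(), 3.0)
        assert len(out) == 0


class TestPermutationFWE:
    def test_singleton_roi_equals_unadjusted_permutation_p(self, cohort48):
        """Max over a single voxel is that voxel's own permutation null."""
        rng = np.random.default_rng(8)
        model = _random_model(cohort48, n_vox=5, seed=9)
        roi = np.zeros(5, bool)
        roi[2] = True
        p = permutation_fwe(model.Y, model.X, model.contrast, roi=roi,
                            n_perm=300, seed=4)
        # independent re-implementation for the single voxel
        y = model.Y[:, [2]]
        c = model.contrast
        Z = model.X[:, c == 0]
        Rz = y - Z @ np.linalg.pinv(Z) @ y
        from megfalff.glm import _t_stats
        t_obs = _t_stats(y, model.X, c)[0][0]
        rng2 = np.random.default_rng(4)
        count = 0
        for _ in range(300):
            perm = rng2.permutation(48)
            t_b = _t_stats(Rz[perm], model.X, c)[0][0]
            count += abs(t_b) >= abs(t_obs)
        assert p[2] == pytest.approx((1 + count) / 301)
        assert np.isnan(p[0])

    def test_planted_effect_attains_minimum_p(self, cohort48):
        rng = np.random.default_rng(10)
        h = cohort48["happiness"].to_numpy()
        Y = rng.normal(size=(48, 4))
        Y[:, 1] = -3.0 * h + 0.05 * rng.normal(size=48)
        model = FALFFRegression(Y, cohort48)
        p = model.fit().permutation_fwe(n_perm=199, seed=1)
        assert p[1] == pytest.approx(1.0 / 200.0)

    def test_minimum_attainable_p_with_99_permutations(self, cohort48):
        model = _random_model(cohort48, n_vox=3, seed=11)
        p = permutation_fwe(model.Y, model.X, model.contrast, n_perm=99, seed=0)
        assert np.nanmin(p) >= 0.01

    def test_too_few_subjects_rejected(self):
        cohort = make_cohort(6, seed=1)
        Y = np.random.default_rng(12).normal(size=(6, 2))
        X = np.column_stack([np.ones(6), cohort["happiness"]])
        with pytest.raises(ValueError):
            permutation_fwe(Y, X, np.array([0.0, -1.0]), n_perm=100, seed=0)


def test_interaction_covariate_variant(cohort48):
    """The happiness-by-sex interaction preset adds a column (df = n - 6)."""
    model = _random_model(cohort48, interactions=(("happiness", "sex"),))
    assert model.column_names[-1] == "happinessxsex"
    res = model.fit()
    assert res.df == 42


def test_no_covariate_variant(cohort48):
    model = _random_model(cohort48, covariates=())
    assert model.fit().df == 46


def test_summary_mentions_key_quantities(cohort48):
    res = _random_model(cohort48).fit()
    res.permutation_fwe(n_perm=99, seed=0)
    text = res.summary()
    assert "df=43" in text and "happiness" in text and "partial r" in text
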