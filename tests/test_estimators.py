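"""Regression machinery: splines, WLS, 2SLS, first-stage F, model builders."""

import numpy as np
import pandas as pd
import pytest
from scipy.interpolate import CubicSpline

import trionurture as tn
from trionurture import estimators as E
from trionurture.pipeline import _recovery_frame


class TestNaturalSplineBasis:
    def test_second_derivative_vanishes_beyond_boundaries(self, rng):
        x = rng.uniform(0, 10, 200)
        basis, knots = tn.natural_spline_basis(x, df=2)

        def second_deriv(col, t, h=1e-3):
            def f(v):
                b, _ = tn.natural_spline_basis(np.array([v]), knots=knots)
                return b[0, col]
            return (f(t + h) - 2 * f(t) + f(t - h)) / h ** 2

        for col in range(basis.shape[1]):
            for t in (knots[0] - 1.0, knots[-1] + 1.0, knots[-1] + 3.0):
                assert abs(second_deriv(col, t)) < 1e-6

    def test_reproduces_natural_cubic_spline_exactly(self, rng):
        # any natural cubic spline on the same knots lies in the span of
        # [1, basis]; fit by least squares and check the residual vanishes
        knots = np.array([1.0, 4.0, 9.0])
        target = CubicSpline(knots, [2.0, -1.0, 3.0], bc_type="natural")
        x = np.linspace(1.0, 9.0, 200)
        basis, _ = tn.natural_spline_basis(x, knots=knots)
        X = np.column_stack([np.ones_like(x), basis])
        coef, *_ = np.linalg.lstsq(X, target(x), rcond=None)
        assert np.max(np.abs(X @ coef - target(x))) < 1e-8

    def test_needs_three_distinct_values(self):
        with pytest.raises(ValueError, match="3 distinct"):
            tn.natural_spline_basis(np.array([1.0, 1.0, 2.0]))


class TestFitWls:
    def test_intercept_only_closed_form(self, rng):
        y = rng.normal(size=40)
        X = pd.DataFrame({"const": np.ones(40)})
        res = tn.fit_wls(y, X)
        assert abs(res.params["const"] - y.mean()) < 1e-12
        expected_se = y.std() / np.sqrt(40) * np.sqrt(40 / 39)
        assert abs(res.se["const"] - expected_se) < 1e-10

    def test_row_duplication_with_halved_weights_invariant(self, rng):
        y = rng.normal(size=30)
        X = pd.DataFrame({"const": 1.0, "x": rng.normal(size=30)})
        res1 = tn.fit_wls(y, X)
        y2 = np.concatenate([y, y])
        X2 = pd.concat([X, X], ignore_index=True)
        res2 = tn.fit_wls(y2, X2, weights=np.full(60, 0.5))
        assert np.allclose(res1.params, res2.params)

    def test_matches_normal_equations(self, rng):
        n, k = 50, 3
        X = pd.DataFrame(rng.normal(size=(n, k)), columns=list("abc"))
        y = rng.normal(size=n)
        w = rng.uniform(0.5, 2.0, n)
        res = tn.fit_wls(y, X, weights=w)
        A = X.to_numpy() * w[:, None]
        beta = np.linalg.solve(A.T @ X.to_numpy(), A.T @ y)
        assert np.max(np.abs(res.params.to_numpy() - beta)) < 1e-10

    def test_matches_statsmodels_hc1(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        n = 80
        X = pd.DataFrame({"const": 1.0, "x": rng.normal(size=n),
                          "z": rng.normal(size=n)})
        y = rng.normal(size=n)
        mine = tn.fit_wls(y, X)
        ref = sm.OLS(y, X.to_numpy()).fit(cov_type="HC1")
        assert np.allclose(mine.params.to_numpy(), ref.params)
        assert np.allclose(mine.se.to_numpy(), ref.bse, rtol=1e-8)

    def test_collinear_column_dropped_with_warning(self, rng, caplog):
        X = pd.DataFrame({"const": 1.0, "x": rng.normal(size=20)})
        X["x2"] = 2.0 * X["x"]
        res = tn.fit_wls(rng.normal(size=20), X)
        assert res.dropped == ["x2"]

    def test_nonpositive_weights_rejected(self, rng):
        X = pd.DataFrame({"const": np.ones(5)})
        with pytest.raises(ValueError, match="weights"):
            tn.fit_wls(np.zeros(5), X, weights=np.array([1, 1, 0, 1, 1.0]))


class TestFitIv2sls:
    def test_self_instrument_equals_wls(self, rng):
        n = 60
        x = rng.normal(size=n)
        y = 2.0 * x + rng.normal(size=n)
        exog = pd.DataFrame({"const": np.ones(n)})
        iv = tn.fit_iv2sls(y, pd.DataFrame({"x": x}),
                           pd.DataFrame({"zx": x}), exog)
        wls = tn.fit_wls(y, pd.DataFrame({"x": x, "const": 1.0}))
        assert abs(iv.params["x"] - wls.params["x"]) < 1e-10

    def test_four_point_ratio_of_covariances(self):
        z = np.array([0.0, 1.0, 0.0, 1.0])
        x = np.array([1.0, 2.0, 3.0, 6.0])
        y = np.array([2.0, 3.0, 5.0, 9.0])
        res = tn.fit_iv2sls(y, pd.DataFrame({"x": x}),
                            pd.DataFrame({"z": z}),
                            pd.DataFrame({"const": np.ones(4)}))
        closed = np.cov(z, y)[0, 1] / np.cov(z, x)[0, 1]
        assert abs(closed - 1.25) < 1e-12
        assert abs(res.params["x"] - 1.25) < 1e-10

    def test_invariant_to_instrument_reparameterization(self, rng):
        n = 100
        z1, z2 = rng.normal(size=n), rng.normal(size=n)
        x1 = z1 + 0.5 * z2 + rng.normal(size=n)
        x2 = z2 - 0.2 * z1 + rng.normal(size=n)
        y = x1 - x2 + rng.normal(size=n)
        exog = pd.DataFrame({"const": np.ones(n)})
        endog = pd.DataFrame({"x1": x1, "x2": x2})
        a = tn.fit_iv2sls(y, endog, pd.DataFrame({"z1": z1, "z2": z2}), exog)
        # invertible linear mix of the instruments
        b = tn.fit_iv2sls(y, endog, pd.DataFrame(
            {"w1": 3 * z1 - z2, "w2": z1 + z2}), exog)
        assert np.max(np.abs(a.params.to_numpy() - b.params.to_numpy())) < 1e-8

    def test_manual_two_stage_agrees_with_projection(self, rng):
        n = 120
        z = rng.normal(size=n)
        x = z + rng.normal(size=n)
        y = 0.7 * x + rng.normal(size=n)
        exog = pd.DataFrame({"const": np.ones(n)})
        res = tn.fit_iv2sls(y, pd.DataFrame({"x": x}),
                            pd.DataFrame({"z": z}), exog)
        # manual: first-stage fitted values replace the endogenous column
        Z = np.column_stack([z, np.ones(n)])
        xhat = Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
        X2 = np.column_stack([xhat, np.ones(n)])
        beta = np.linalg.lstsq(X2, y, rcond=None)[0]
        assert abs(res.params["x"] - beta[0]) < 1e-10

    def test_matches_statsmodels(self, rng):
        from statsmodels.sandbox.regression.gmm import IV2SLS
        n = 90
        z = rng.normal(size=(n, 2))
        x = z @ [1.0, 0.5] + rng.normal(size=n)
        c = rng.normal(size=n)
        y = 0.4 * x + 0.2 * c + rng.normal(size=n)
        exog = pd.DataFrame({"const": np.ones(n), "c": c})
        mine = tn.fit_iv2sls(y, pd.DataFrame({"x": x}),
                             pd.DataFrame({"z1": z[:, 0], "z2": z[:, 1]}),
                             exog)
        Xfull = np.column_stack([x, np.ones(n), c])
        Zfull = np.column_stack([z, np.ones(n), c])
        ref = IV2SLS(y, Xfull, Zfull).fit()
        assert np.allclose(mine.params.to_numpy(), ref.params, atol=1e-8)

    def test_underidentification_rejected(self, rng):
        n = 30
        with pytest.raises(ValueError, match="under-identified"):
            tn.fit_iv2sls(rng.normal(size=n),
                          pd.DataFrame({"x1": rng.normal(size=n),
                                        "x2": rng.normal(size=n)}),
                          pd.DataFrame({"z": rng.normal(size=n)}),
                          pd.DataFrame({"const": np.ones(n)}))


class TestFirstStageF:
    def test_single_instrument_equals_t_squared(self, rng):
        n = 70
        z = rng.normal(size=n)
        x = 0.4 * z + rng.normal(size=n)
        exog = pd.DataFrame({"const": np.ones(n)})
        F = tn.first_stage_partial_F(x, pd.DataFrame({"z": z}), exog)
        fs = tn.fit_wls(x, pd.DataFrame({"z": z, "const": 1.0}))
        # classical (non-robust) t^2: recompute with homoskedastic SE
        X = np.column_stack([z, np.ones(n)])
        beta = np.linalg.lstsq(X, x, rcond=None)[0]
        resid = x - X @ beta
        s2 = resid @ resid / (n - 2)
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[0, 0])
        assert abs(F - (beta[0] / se) ** 2) < 1e-10
        assert fs is not None

    def test_null_instrument_mean_near_one(self, rng):
        n = 60
        Fs = []
        for _ in range(500):
            z = rng.normal(size=n)
            x = rng.normal(size=n)
            exog = pd.DataFrame({"const": np.ones(n)})
            Fs.append(tn.first_stage_partial_F(x, pd.DataFrame({"z": z}),
                                               exog))
        # central F(1, n-k) has mean (n-k)/(n-k-2) ~ 1.04
        assert abs(np.mean(Fs) - 1.0) < 0.2

    def test_no_instruments_rejected(self, rng):
        with pytest.raises(ValueError, match="q = 0"):
            tn.first_stage_partial_F(rng.normal(size=10),
                                     pd.DataFrame(index=range(10)),
                                     pd.DataFrame({"const": np.ones(10)}))


class TestCohortModels:
    def test_phenotypic_recovers_nurture_without_genetic_confounding(self):
        # delta = 0 removes the direct-genetic confound; with gamma_m = 0.26
        # the phenotypic mother coefficient is consistent (up to self-report
        # attenuation, kept negligible here)
        zero = (0.0,) * 6
        sim = tn.SimConfig(n_families=20_000, n_snps=60, delta=zero,
                           gamma_m=(0.26,) * 6, sigma_report=0.0,
                           attrition_base=1.0, attrition_slope=0.0, seed=41)
        df, _ = _recovery_frame(sim, seed=41)
        res = tn.fit_phenotypic_model(df, "bmi_child_17", 17.0)
        est, se = res.params["bmi_mother_self"], res.se["bmi_mother_self"]
        assert abs(est - 0.26) < 2 * se

    def test_trio_mr_recovers_both_parents(self):
        sim = tn.SimConfig(n_families=50_000, n_snps=300,
                           gamma_m=(0.32,) * 6, gamma_p=(0.0,) * 6,
                           attrition_base=1.0, attrition_slope=0.0, seed=43)
        df, _ = _recovery_frame(sim, seed=43)
        res = tn.fit_trio_mr(df, "bmi_child_17", 17.0)
        assert abs(res.params["bmi_mother_self"] - 0.32) \
            < 2.5 * res.se["bmi_mother_self"]
        assert abs(res.params["bmi_father_self"]) \
            < 2.5 * res.se["bmi_father_self"]
        assert min(res.first_stage_F.values()) > 30

    def test_pgi_model_null_parents_positive_child(self):
        zero = (0.0,) * 6
        sim = tn.SimConfig(n_families=20_000, n_snps=100, gamma_m=zero,
                           gamma_p=zero, attrition_base=1.0,
                           attrition_slope=0.0, seed=47)
        df, _ = _recovery_frame(sim, seed=47)
        res = tn.fit_pgi_model(df, "bmi_child_17", 17.0)
        for parent in ("pgi_mother", "pgi_father"):
            assert abs(res.params[parent]) < 2.5 * res.se[parent]
        assert res.params["pgi_child"] > 5 * res.se["pgi_child"]

    def test_pgi_model_structural_values(self):
        # mother coefficient ~ gamma_m * lambda (first-stage kg/m^2 per PGI
        # SD); child ~ delta
        sim = tn.SimConfig(n_families=50_000, n_snps=300,
                           gamma_m=(0.32,) * 6, delta=(0.9,) * 6,
                           attrition_base=1.0, attrition_slope=0.0, seed=53)
        df, truth = _recovery_frame(sim, seed=53)
        res = tn.fit_pgi_model(df, "bmi_child_17", 17.0)
        lam = truth.lambda_first_stage
        assert abs(res.params["pgi_mother"] - 0.32 * lam) \
            < 3 * res.se["pgi_mother"] + 0.03
        assert abs(res.params["pgi_child"] - 0.9) \
            < 3 * res.se["pgi_child"] + 0.05
        ratio = res.extra["ratio_mother_child"]
        assert ratio is not None and 0.2 < ratio < 0.55

    def test_lpm_constant_outcome(self):
        sim = tn.SimConfig(n_families=500, n_snps=30, seed=3,
                           attrition_base=1.0, attrition_slope=0.0)
        df, _ = _recovery_frame(sim, seed=3)
        df["flag"] = 1.0
        res = tn.fit_lpm(df, "flag", 17.0, mode="phenotypic")
        assert abs(res.params["bmi_mother_self"]) < 1e-10
        assert abs(res.params["const"] - 1.0) < 1e-10

    def test_lpm_slope_matches_gaussian_threshold_oracle(self):
        """The LPM slope for a dichotomized latent-threshold diet item
        equals the average derivative of the Gaussian threshold
        probability with respect to maternal BMI (numerical integration
        oracle), within Monte-Carlo error."""
        from scipy import stats as sps
        c_m, load = 0.08, 0.8
        sim = tn.SimConfig(n_families=30_000, n_snps=60, diet_c_m=c_m,
                           delta=(0.0,) * 6, gamma_m=(0.0,) * 6,
                           sigma_report=0.0, rho_am=0.0,
                           attrition_base=1.0, attrition_slope=0.0, seed=59)
        df, _ = _recovery_frame(sim, seed=59)
        item = df["diet_fruit_17"].to_numpy()
        df["fruit_top"] = tn.dichotomize(item, 4)
        res = tn.fit_lpm(df, "fruit_top", 17.0, mode="phenotypic")
        slope = res.params["bmi_mother_self"]
        se = res.se["bmi_mother_self"]
        # latent | cm ~ N(-load*c_m*cm, load^2 + 1); top-category cut sits
        # at the 75th percentile of the item latent's marginal
        var_d = c_m ** 2 * sim.sd_bmi_parent ** 2 + 1.0
        sd_lat = np.sqrt(load ** 2 * var_d + 1.0)
        cut = sps.norm.ppf(0.75) * sd_lat
        sd_cond = np.sqrt(load ** 2 + 1.0)
        grid = np.linspace(-4, 4, 2001) * sim.sd_bmi_parent
        dens = sps.norm.pdf(grid, scale=sim.sd_bmi_parent)
        dens /= dens.sum()
        deriv = (-load * c_m / sd_cond) * sps.norm.pdf(
            (cut + load * c_m * grid) / sd_cond)
        oracle = float(np.sum(deriv * dens))
        assert abs(slope - oracle) < 2 * se

    def test_lpm_rejects_nonbinary(self):
        sim = tn.SimConfig(n_families=100, n_snps=20, seed=3)
        df, _ = _recovery_frame(sim, seed=3)
        with pytest.raises(ValueError, match="binary"):
            tn.fit_lpm(df, "bmi_child_17", 17.0)

    def test_all_missing_outcome_rejected(self):
        sim = tn.SimConfig(n_families=100, n_snps=20, seed=3)
        df, _ = _recovery_frame(sim, seed=3)
        df["bmi_child_17"] = np.nan
        with pytest.raises(ValueError, match="complete cases"):
            tn.fit_phenotypic_model(df, "bmi_child_17", 17.0)
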