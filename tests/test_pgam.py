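"""Penalized IRLS engine: deviance, inner fit, smoothing selection, scale
estimation, posterior inference and diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize as sopt

import statsmodels.api as sm

from dosegam.pgam import (DesignMatrix, Fac, Lin, Ti, anova_compare,
                          criterion_value, estimate_scale_quasi, fit_at_lambda,
                          leverage_and_cooks, exclude_high_cooks,
                          optimize_smoothing, poisson_deviance,
                          posterior_interval)

from .conftest import toy_table


def _toy_design(n=20, k=4, seed=0, slope=0.3, curve=0.0, keep_df=False):
    rng = np.random.default_rng(seed)
    x = np.sort(rng.uniform(0.0, 1.0, n))
    py = rng.uniform(50.0, 150.0, n)
    eta = np.log(py) + 1.0 + slope * x + curve * np.sin(3 * x)
    y = rng.poisson(np.exp(eta))
    df = pd.DataFrame({"py": py, "x": x, "obs": y})
    d = DesignMatrix(df, [Ti(("x",), k=k)], offset="py")
    return (d, y, df) if keep_df else (d, y)


class TestDeviance:
    def test_zero_iff_perfect_fit(self):
        assert poisson_deviance([1, 2, 3], [1, 2, 3]) == 0.0

    @pytest.mark.parametrize("obs,mu,expected", [
        ([0], [2], 4.0),
        ([2], [1], 2 * (2 * np.log(2) - 1)),
    ])
    def test_hand_evaluated_values(self, obs, mu, expected):
        assert poisson_deviance(obs, mu) == pytest.approx(expected, rel=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            poisson_deviance([-1], [1])


class TestInnerFit:
    def test_intercept_only_closed_form(self):
        rng = np.random.default_rng(1)
        py = rng.uniform(10, 100, 30)
        y = rng.poisson(0.05 * py)
        df = pd.DataFrame({"py": py, "obs": y})
        d = DesignMatrix(df, [], offset="py")
        fit = fit_at_lambda(d, y, [])
        assert np.allclose(fit.mu, y.sum() / py.sum() * py, rtol=1e-8)

    def test_score_equation_sum_mu_equals_sum_obs(self):
        d, y = _toy_design(n=40, curve=0.8)
        fit = fit_at_lambda(d, y, [1.0])
        assert abs(fit.mu.sum() - y.sum()) / y.sum() < 1e-6

    def test_infinite_lambda_degenerates_to_log_linear_glm(self):
        d, y, df = _toy_design(n=50, curve=0.5, keep_df=True)
        fit = fit_at_lambda(d, y, [1e9])
        X = sm.add_constant(df["x"].to_numpy())
        glm = sm.GLM(y, X, family=sm.families.Poisson(),
                     offset=np.log(df["py"])).fit()
        assert np.allclose(fit.mu, glm.mu, rtol=1e-4)

    def test_matches_brute_force_penalized_deviance_minimizer(self):
        # generic-optimizer oracle, independent of the PIRLS path
        for seed in (0, 1, 2):
            d, y = _toy_design(n=20, k=4, seed=seed, curve=0.6)
            lam = 1.0
            fit = fit_at_lambda(d, y, [lam])
            S = d.total_penalty(np.array([lam]))

            def pen_dev(beta):
                mu = np.exp(d.offset + d.X @ beta)
                return poisson_deviance(y, mu) + beta @ S @ beta

            res = sopt.minimize(pen_dev, np.zeros(d.p), method="BFGS",
                                options={"gtol": 1e-10, "maxiter": 2000})
            assert np.allclose(fit.beta, res.x, atol=1e-6)
            assert pen_dev(fit.beta) <= res.fun + 1e-8

    def test_wrong_lambda_count_errors(self):
        d, y = _toy_design()
        with pytest.raises(ValueError, match="smoothing parameters"):
            fit_at_lambda(d, y, [1.0, 1.0])

    def test_deviance_monotone_in_lambda(self):
        d, y = _toy_design(n=60, curve=1.0)
        devs = [fit_at_lambda(d, y, [l]).dev for l in (1e-4, 1e-2, 1.0, 1e2, 1e4)]
        assert np.all(np.diff(devs) >= -1e-8)

    def test_offset_contract(self):
        # scaling py by c shifts the intercept by -log c; fitted mu unchanged
        d, y, df = _toy_design(n=30, keep_df=True)
        fit = fit_at_lambda(d, y, [1.0])
        df2 = df.copy()
        df2["py"] *= 10.0
        d2 = DesignMatrix(df2, [Ti(("x",), k=4)], offset="py")
        fit2 = fit_at_lambda(d2, y, [1.0])
        assert fit2.beta[0] - fit.beta[0] == pytest.approx(-np.log(10), abs=1e-6)
        assert np.allclose(fit.mu, fit2.mu, rtol=1e-6)


class TestSmoothingSelection:
    def test_linear_truth_gives_null_space_edf(self):
        rng = np.random.default_rng(10)
        n = 400
        x = np.sort(rng.uniform(0, 1, n))
        py = rng.uniform(100, 200, n)
        y = rng.poisson(py * np.exp(-3.0 + 0.8 * x))
        df = pd.DataFrame({"py": py, "x": x})
        d = DesignMatrix(df, [Ti(("x",), k=6)], offset="py")
        fit = optimize_smoothing(d, y, method="ML")
        smooth_edf = fit.edf - 1.0  # subtract intercept
        assert smooth_edf < 1.5

    def test_determinism(self):
        d, y = _toy_design(n=50, curve=0.7)
        f1 = optimize_smoothing(d, y)
        f2 = optimize_smoothing(d, y)
        assert np.array_equal(f1.lam, f2.lam)
        assert f1.score == f2.score

    def test_nested_null_smooth_scores_close(self):
        # adding a zero-effect smooth moves the ML score by < 2 units
        rng = np.random.default_rng(3)
        n = 300
        x = np.sort(rng.uniform(0, 1, n))
        z = rng.uniform(0, 1, n)
        py = rng.uniform(100, 200, n)
        y = rng.poisson(py * np.exp(-3.0 + np.sin(2 * x)))
        df = pd.DataFrame({"py": py, "x": x, "z": z})
        d1 = DesignMatrix(df, [Ti(("x",), k=6)], offset="py")
        d2 = DesignMatrix(df, [Ti(("x",), k=6), Ti(("z",), k=6)], offset="py")
        f1 = optimize_smoothing(d1, y)
        f2 = optimize_smoothing(d2, y)
        assert abs(f1.score - f2.score) < 2.0

    def test_gcv_also_supported(self):
        d, y = _toy_design(n=40, curve=0.8)
        fit = optimize_smoothing(d, y, method="GCV")
        assert fit.score == pytest.approx(
            d.n * fit.dev / (d.n - fit.edf) ** 2)

    def test_min_sp_honored(self):
        d, y = _toy_design(n=40, curve=1.5)
        fit = optimize_smoothing(d, y, min_sp=10.0)
        assert np.all(fit.lam >= 10.0 - 1e-9)

    def test_edf_between_null_and_full_dimension(self):
        d, y = _toy_design(n=40, curve=0.8)
        fit = optimize_smoothing(d, y)
        assert 1.0 - 1e-6 <= fit.edf <= d.p + 1e-6
        assert fit.dfres == pytest.approx(d.n - fit.edf)


class TestPosterior:
    def test_zero_contrast_degenerate(self):
        d, y = _toy_design()
        fit = fit_at_lambda(d, y, [1.0])
        est, lo, hi = posterior_interval(fit, np.zeros((1, d.p)))
        assert est[0] == lo[0] == hi[0] == 0.0
        assert np.exp(est[0]) == 1.0

    def test_wrong_contrast_width_errors(self):
        d, y = _toy_design()
        fit = fit_at_lambda(d, y, [1.0])
        with pytest.raises(ValueError, match="columns"):
            posterior_interval(fit, np.zeros((1, d.p + 3)))

    def test_width_scales_with_sqrt_phi(self):
        d, y = _toy_design(n=50, curve=0.5)
        C = np.zeros((1, d.p))
        C[0, 1] = 1.0
        f1 = fit_at_lambda(d, y, [1.0], family="quasipoisson", phi=1.0)
        f2 = fit_at_lambda(d, y, [1.0], family="quasipoisson", phi=2.0)
        _, lo1, hi1 = posterior_interval(f1, C)
        _, lo2, hi2 = posterior_interval(f2, C)
        assert (hi2[0] - lo2[0]) / (hi1[0] - lo1[0]) == pytest.approx(
            np.sqrt(2.0), rel=1e-8)


class TestQuasiScale:
    def test_poisson_data_recovers_unit_scale(self):
        rng = np.random.default_rng(8)
        n = 2000
        x = np.sort(rng.uniform(0, 1, n))
        py = rng.uniform(50, 150, n)
        mu = py * np.exp(-3.0 + 0.5 * x)
        y = rng.poisson(mu)
        df = pd.DataFrame({"py": py, "x": x})
        d = DesignMatrix(df, [Ti(("x",), k=5)], offset="py")
        fit = estimate_scale_quasi(d, y)
        assert abs(fit.phi - 1.0) < 0.1

    def test_doubled_variance_recovers_phi_two(self):
        rng = np.random.default_rng(9)
        n = 2000
        x = np.sort(rng.uniform(0, 1, n))
        py = rng.uniform(50, 150, n)
        mu = py * np.exp(-3.0 + 0.5 * x)
        # negative binomial with n=mu, p=1/2 has mean mu and variance 2*mu
        y = rng.negative_binomial(mu, 0.5)
        df = pd.DataFrame({"py": py, "x": x})
        d = DesignMatrix(df, [Ti(("x",), k=5)], offset="py")
        fit = estimate_scale_quasi(d, y)
        assert abs(fit.phi - 2.0) < 0.2

    def test_saturated_toy_clamps_at_floor(self):
        # perfect fit -> Pearson chi2 = 0 -> scale at its lower clamp
        py = np.array([10.0, 20.0, 30.0, 40.0])
        y = np.array([1.0, 2.0, 3.0, 4.0])  # exactly proportional to py
        df = pd.DataFrame({"py": py})
        d = DesignMatrix(df, [], offset="py")
        fit = estimate_scale_quasi(d, y)
        assert fit.phi == pytest.approx(1e-4)


class TestDiagnostics:
    def test_leverage_sums_to_edf(self):
        d, y = _toy_design(n=40, curve=0.8)
        fit = fit_at_lambda(d, y, [0.5])
        h, cd = leverage_and_cooks(fit)
        assert h.sum() == pytest.approx(fit.edf, abs=1e-8)
        assert np.all(cd >= 0)

    def test_split_cell_halves_leverage(self):
        # splitting a cell into two identical halves (py/2, obs/2) leaves the
        # fit invariant and halves each half's leverage
        rng = np.random.default_rng(4)
        py = rng.uniform(50, 100, 10)
        x = np.sort(rng.uniform(0, 1, 10))
        y = rng.poisson(0.1 * py).astype(float)
        df = pd.DataFrame({"py": py, "x": x})
        d1 = DesignMatrix(df, [Lin("x")], offset="py")
        f1 = fit_at_lambda(d1, y, [])
        half = df.iloc[[-1]].assign(py=py[-1] / 2.0)
        df2 = pd.concat([df.iloc[:-1], half, half], ignore_index=True)
        y2 = np.concatenate([y[:-1], [y[-1] / 2.0, y[-1] / 2.0]])
        d2 = DesignMatrix(df2, [Lin("x")], offset="py")
        f2 = fit_at_lambda(d2, y2, [])
        assert np.allclose(f1.beta, f2.beta, atol=1e-8)
        h1, _ = leverage_and_cooks(f1)
        h2, _ = leverage_and_cooks(f2)
        assert h2[-1] == pytest.approx(h1[-1] / 2.0, rel=1e-6)

    def test_zero_exclusion_returns_identical_table(self):
        d, y, df = _toy_design(n=30, keep_df=True)
        fit = fit_at_lambda(d, y, [1.0])
        out = exclude_high_cooks(df, fit, q=0)
        pd.testing.assert_frame_equal(out, df)

    def test_exclusion_drops_top_five_percent(self):
        d, y, df = _toy_design(n=40, keep_df=True)
        fit = fit_at_lambda(d, y, [1.0])
        out = exclude_high_cooks(df, fit, q=5.0)
        assert len(out) == 38  # ceil-free quantile cut on 40 cells


class TestAnova:
    def test_identical_models_give_p_one(self):
        d, y = _toy_design(n=40)
        f = fit_at_lambda(d, y, [1.0])
        out = anova_compare(f, f)
        assert out["p"] == 1.0 and out["statistic"] == 0.0

    def test_different_data_rejected(self):
        d1, y1 = _toy_design(n=40, seed=1)
        d2, y2 = _toy_design(n=40, seed=2)
        with pytest.raises(ValueError, match="same data"):
            anova_compare(fit_at_lambda(d1, y1, [1.0]),
                          fit_at_lambda(d2, y2, [1.0]))

    def test_null_extra_smooth_rejects_at_nominal_rate(self):
        rng = np.random.default_rng(12)
        n = 150
        rejections = 0
        reps = 40
        for _ in range(reps):
            x = np.sort(rng.uniform(0, 1, n))
            z = rng.uniform(0, 1, n)
            py = rng.uniform(100, 200, n)
            y = rng.poisson(py * np.exp(-3.0 + 0.5 * x)).astype(float)
            df = pd.DataFrame({"py": py, "x": x, "z": z})
            d1 = DesignMatrix(df, [Lin("x")], offset="py")
            d2 = DesignMatrix(df, [Lin("x"), Ti(("z",), k=5)], offset="py")
            f1 = fit_at_lambda(d1, y, [])
            f2 = optimize_smoothing(d2, y)
            if anova_compare(f1, f2)["p"] < 0.05:
                rejections += 1
        # ~5% nominal; allow generous binomial slack at 40 replicates
        assert rejections <= 8
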