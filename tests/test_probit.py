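"""Probit MLE, sandwich covariance, and average partial effects."""

import numpy as np
import pandas as pd
import pytest
from scipy import special
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from selva.probit import (DesignMatrix, PerfectSeparationError, ape_binary,
                          ape_continuous, fit_probit_mle, predict_prob,
                          robust_vcov)


def make_design(cols, quad_pairs=None):
    return DesignMatrix(pd.DataFrame(cols), quad_pairs=quad_pairs or {})


@pytest.fixture
def toy_fit(rng):
    n = 200
    x = rng.standard_normal(n)
    b = rng.standard_normal(n)
    bcol = (b > 0).astype(float)
    eta = 0.3 - 0.8 * x + 0.1 * x**2 + 0.6 * bcol
    y = (eta + rng.standard_normal(n) > 0).astype(int)
    design = make_design({"x": x, "x2": x**2, "d": bcol},
                         quad_pairs={"x": "x2"})
    return design, y, fit_probit_mle(design, y)


class TestFit:
    def test_intercept_only_closed_form(self, rng):
        # pure intercept model solved exactly: beta0 = Phi^-1(ybar)
        y = (rng.random(500) < 0.42).astype(int)
        tiny = rng.standard_normal(500) * 1e-10  # numerically inert column
        design = make_design({"z": tiny})
        fit = fit_probit_mle(design, y)
        assert fit.coef("const") == pytest.approx(norm.ppf(y.mean()), abs=1e-6)

    def test_matches_statsmodels(self, toy_fit):
        sm = pytest.importorskip("statsmodels.api")
        design, y, fit = toy_fit
        ref = sm.Probit(y, design.X).fit(disp=0)
        assert fit.beta_hat == pytest.approx(ref.params, abs=1e-6)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-8)
        assert fit.se_model() == pytest.approx(ref.bse, rel=1e-4)

    def test_one_covariate_matches_golden_section(self, rng):
        # independent optimizer oracle: profile the slope on a no-intercept
        # one-covariate likelihood via scalar minimization
        n = 50
        x = rng.standard_normal(n)
        y = (0.9 * x + rng.standard_normal(n) > 0).astype(int)

        def negll_slope(b):
            eta = b * x
            return -np.where(y == 1, special.log_ndtr(eta),
                             special.log_ndtr(-eta)).sum()

        res = minimize_scalar(negll_slope, bounds=(-10, 10), method="bounded",
                              options={"xatol": 1e-10})
        # same model via the package: keep the intercept but hold it at
        # zero by centring? Instead fit both and compare the profile
        design = make_design({"x": x})
        fit = fit_probit_mle(design, y)
        # evaluate the package's likelihood at the oracle's slope with the
        # fitted intercept profile; the joint optimum cannot be worse
        assert negll_slope(res.x) >= -fit.loglik - 1e-5

    def test_single_class_and_separation_errors(self, rng):
        x = rng.standard_normal(60)
        with pytest.raises(ValueError, match="single class"):
            fit_probit_mle(make_design({"x": x}), np.ones(60, dtype=int))
        y_sep = (x > 0).astype(int)  # perfectly separated
        with pytest.raises(PerfectSeparationError):
            fit_probit_mle(make_design({"x": x}), y_sep)

    def test_local_maximality(self, toy_fit, rng):
        design, y, fit = toy_fit
        X = design.X

        def ll(beta):
            eta = X @ beta
            return np.where(y == 1, special.log_ndtr(eta),
                            special.log_ndtr(-eta)).sum()

        base = ll(fit.beta_hat)
        for _ in range(100):
            delta = rng.standard_normal(len(fit.beta_hat)) * 0.05
            assert ll(fit.beta_hat + delta) <= base + 1e-10


class TestRobustVcov:
    def test_diagonal_positive(self, toy_fit):
        _, _, fit = toy_fit
        assert (np.diag(fit.vcov_robust) > 0).all()

    def test_hand_assembled_sandwich_on_10_rows(self):
        x = np.array([0.5, -1.2, 0.3, 2.0, -0.7, 1.1, -0.2, 0.9, -1.5, 0.4])
        y = np.array([1, 0, 1, 1, 0, 1, 0, 1, 0, 1])
        design = make_design({"x": x})
        fit = fit_probit_mle(design, y)
        X = design.X
        eta = X @ fit.beta_hat
        P = special.ndtr(eta)
        phi = norm.pdf(eta)
        with np.errstate(divide="ignore", invalid="ignore"):
            lam = np.where(y == 1, phi / P, -phi / (1 - P))
        w = lam * (lam + eta)
        A = sum(np.outer(X[i], X[i]) * w[i] for i in range(10))
        B = sum(np.outer(X[i] * lam[i], X[i] * lam[i]) for i in range(10))
        expected = np.linalg.inv(A) @ B @ np.linalg.inv(A)
        got = robust_vcov(fit, design, y)
        assert got == pytest.approx(expected, rel=1e-8)

    def test_robust_close_to_model_when_correctly_specified(self, rng):
        n = 20_000
        x = rng.standard_normal(n)
        y = (0.2 + 0.7 * x + rng.standard_normal(n) > 0).astype(int)
        design = make_design({"x": x})
        fit = fit_probit_mle(design, y)
        assert fit.se_robust() == pytest.approx(fit.se_model(), rel=0.10)


class TestAPE:
    def test_zero_coefficients_give_zero_ape(self, toy_fit):
        design, y, fit = toy_fit
        fit0 = fit
        fit0.beta_hat = np.zeros_like(fit.beta_hat)
        assert ape_continuous(fit0, design, "x") == 0.0
        assert ape_binary(fit0, design, "d") == 0.0

    def test_continuous_matches_finite_difference(self, rng):
        n = 100
        x = rng.standard_normal(n)
        other = rng.standard_normal(n)
        y = (0.4 * x - 0.2 * x**2 + 0.3 * other
             + rng.standard_normal(n) > 0).astype(int)
        design = make_design({"x": x, "x2": x**2, "z": other},
                             quad_pairs={"x": "x2"})
        fit = fit_probit_mle(design, y)
        got = ape_continuous(fit, design, "x")
        h = 1e-5
        up = design.with_columns({"x": x + h})
        dn = design.with_columns({"x": x - h})
        fd = np.mean((special.ndtr(up.X @ fit.beta_hat)
                      - special.ndtr(dn.X @ fit.beta_hat)) / (2 * h))
        assert got == pytest.approx(fd, abs=1e-6)

    def test_no_quadratic_reduces_to_bk_mean_phi(self, toy_fit, rng):
        n = 80
        x = rng.standard_normal(n)
        y = (0.5 * x + rng.standard_normal(n) > 0).astype(int)
        design = make_design({"x": x})
        fit = fit_probit_mle(design, y)
        expected = fit.coef("x") * norm.pdf(design.X @ fit.beta_hat).mean()
        assert ape_continuous(fit, design, "x") == pytest.approx(expected)

    def test_binary_matches_row_wise_oracle(self, rng):
        n = 20
        d = (rng.random(n) > 0.5).astype(float)
        z = rng.standard_normal(n)
        y = (0.3 + 0.8 * d - 0.2 * z + rng.standard_normal(n) > 0).astype(int)
        design = make_design({"d": d, "z": z})
        fit = fit_probit_mle(design, y)
        bk = fit.coef("d")
        j = design.col("d")
        rows = []
        for i in range(n):
            eta_wo = design.X[i] @ fit.beta_hat - design.X[i, j] * bk
            rows.append(special.ndtr(eta_wo + bk) - special.ndtr(eta_wo))
        assert ape_binary(fit, design, "d") == pytest.approx(np.mean(rows))

    def test_binary_ape_sign_follows_coefficient(self, rng):
        n = 500
        d = (rng.random(n) > 0.5).astype(float)
        y = (0.5 * d - 0.2 + rng.standard_normal(n) > 0).astype(int)
        design = make_design({"d": d})
        fit = fit_probit_mle(design, y)
        assert np.sign(ape_binary(fit, design, "d")) == np.sign(fit.coef("d"))

    def test_rescaling_covariate_rescales_ape(self, rng):
        n = 300
        x = rng.standard_normal(n)
        y = (0.6 * x + rng.standard_normal(n) > 0).astype(int)
        d1 = make_design({"x": x})
        d2 = make_design({"x": 10.0 * x})
        ape1 = ape_continuous(fit_probit_mle(d1, y), d1, "x")
        ape2 = ape_continuous(fit_probit_mle(d2, y), d2, "x")
        assert ape2 == pytest.approx(ape1 / 10.0, rel=1e-4)

    def test_intercept_and_nonbinary_errors(self, toy_fit):
        design, y, fit = toy_fit
        with pytest.raises(ValueError, match="intercept"):
            ape_continuous(fit, design, "const")
        with pytest.raises(ValueError, match="binary"):
            ape_binary(fit, design, "x")


class TestPredict:
    def test_zero_index_gives_half_and_monotone(self, rng):
        n = 100
        x = np.sort(rng.standard_normal(n))
        y = (x + rng.standard_normal(n) > 0).astype(int)
        design = make_design({"x": x})
        fit = fit_probit_mle(design, y)
        p = predict_prob(fit, design)
        assert (np.diff(p) >= -1e-12).all()  # monotone in x (positive coef)
        # cross-check against an erf-based normal CDF
        eta = design.X @ fit.beta_hat
        erf_cdf = 0.5 * (1 + special.erf(eta / np.sqrt(2)))
        assert p == pytest.approx(erf_cdf, abs=1e-12)

    def test_column_mismatch_raises(self, toy_fit, rng):
        design, y, fit = toy_fit
        other = make_design({"w": rng.standard_normal(len(design.data))})
        with pytest.raises(ValueError, match="columns"):
            predict_prob(fit, other)


def test_parameter_recovery_on_nonspatial_landscapes():
    """sigma2=0 landscapes: |beta_hat - beta| < 3 SE in >= 94/100 replicates."""
    from selva.synth import SynthConfig, generate_landscape

    n_ok = 0
    n_rep = 100
    for rep in range(n_rep):
        land = generate_landscape(SynthConfig(
            n_rows=100, n_cols=100, rho=0.0, sigma2=0.0,
            mask_fraction=0.0, seed=20_000 + rep))
        design, y, _ = land.design_and_outcome()
        fit = fit_probit_mle(design, y)
        truth = land.true_beta_vector(fit.columns)
        ok = np.abs(fit.beta_hat - truth) < 3 * fit.se_robust()
        n_ok += int(ok.all())
    assert n_ok >= 94
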