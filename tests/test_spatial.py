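"""Gibbs sampler for the regional spatial probit."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from selva.probit import DesignMatrix, ape_binary, ape_continuous, fit_probit_mle
from selva.raster import RasterGrid
from selva.regions import partition_raster, rook_region_weights
from selva.spatial import (MCMCSettings, ape_spatial, draw_truncated_latent,
                           fit_sls_probit, fitted_probabilities, gibbs_theta_scan,
                           log_det_grid)


@pytest.fixture(scope="module")
def fitted():
    """One shared fit on the default 50x50 landscape (rho=0.5, sigma2=1)."""
    from selva.synth import SynthConfig, generate_landscape

    land = generate_landscape(SynthConfig(seed=11))
    design, y, ridx = land.design_and_outcome()
    W = rook_region_weights(land.partition)
    post = fit_sls_probit(design, y, land.partition, W,
                          MCMCSettings(seed=42), region_index=ridx)
    return land, design, y, ridx, W, post


class TestLogDetGrid:
    def test_rho_zero_gives_zero(self):
        part = partition_raster(RasterGrid(np.zeros((25, 25))), 5)
        W = rook_region_weights(part)
        rho, ld = log_det_grid(W, 201)
        g = np.argmin(np.abs(rho))
        # interpolate between nearest grid points around rho=0
        assert abs(ld[g]) < 0.05
        assert np.isfinite(ld).all()

    def test_matches_dense_determinant(self):
        part = partition_raster(RasterGrid(np.zeros((50, 60))), 5)  # m = 120
        W = rook_region_weights(part)
        rho, ld = log_det_grid(W, 41)
        dense = W.W.toarray()
        for g in range(0, 41, 5):
            sign, expected = np.linalg.slogdet(np.eye(120) - rho[g] * dense)
            assert sign == 1
            assert ld[g] == pytest.approx(expected, abs=1e-8)


class TestTruncatedDraws:
    def test_signs_respect_truncation(self, rng):
        mean = rng.normal(0, 3, 5000)
        y = (rng.random(5000) > 0.5).astype(int)
        x = draw_truncated_latent(mean, y, rng)
        assert (x[y == 1] > 0).all()
        assert (x[y == 0] <= 0).all()

    def test_extreme_means_stay_finite(self, rng):
        mean = np.array([-40.0, 40.0, -40.0, 40.0])
        y = np.array([1, 0, 0, 1])
        x = draw_truncated_latent(mean, y, rng)
        assert np.isfinite(x).all()
        assert x[0] > 0 and x[1] <= 0

    def test_moments_match_truncated_normal(self, rng):
        from scipy.stats import truncnorm
        m = 0.7
        draws = draw_truncated_latent(np.full(40_000, m),
                                      np.ones(40_000, dtype=int), rng)
        ref = truncnorm(-m, np.inf, loc=m, scale=1)
        assert draws.mean() == pytest.approx(ref.mean(), abs=0.02)
        assert draws.std() == pytest.approx(ref.std(), rel=0.05)


class TestSampler:
    def test_same_seed_identical_draws(self, fitted):
        land, design, y, ridx, W, post = fitted
        again = fit_sls_probit(design, y, land.partition, W,
                               MCMCSettings(seed=42), region_index=ridx)
        assert (again.beta_draws == post.beta_draws).all()
        assert (again.rho_draws == post.rho_draws).all()
        assert (again.theta_draws == post.theta_draws).all()

    def test_recovers_truth_on_default_conditions(self, fitted):
        land, design, y, ridx, W, post = fitted
        truth = land.true_beta_vector(post.columns)
        ci = post.beta_interval()
        # central 95% intervals cover truth for every coefficient
        assert ((ci[:, 0] <= truth) & (truth <= ci[:, 1])).all()
        lo, hi = post.rho_interval()
        assert lo <= land.truth.rho <= hi
        assert abs(post.rho_mean - land.truth.rho) < 0.3

    def test_small_sigma2_prior_matches_nonspatial_mle(self):
        # forcing theta ~ 0 through a tight sigma2 prior reduces the
        # hierarchical model to the plain probit
        from selva.synth import SynthConfig, generate_landscape

        land = generate_landscape(SynthConfig(seed=5, rho=0.0, sigma2=0.0))
        design, y, ridx = land.design_and_outcome()
        W = rook_region_weights(land.partition)
        settings = MCMCSettings(n_burn=200, n_keep=300, seed=1,
                                sigma2_prior_shape=1e6,
                                sigma2_prior_scale=1e-4 * 1e6)
        post = fit_sls_probit(design, y, land.partition, W, settings,
                              region_index=ridx)
        mle = fit_probit_mle(design, y)
        assert (np.abs(post.beta_mean - mle.beta_hat)
                < 3 * post.beta_sd + 1e-9).all()
        assert np.abs(post.theta_mean).max() < 0.1

    def test_strong_dependence_detected(self):
        # rho=0.7 data: posterior rho positive, 95% interval excludes 0
        from selva.synth import SynthConfig, generate_landscape

        land = generate_landscape(SynthConfig(seed=8, rho=0.7, sigma2=1.0))
        design, y, ridx = land.design_and_outcome()
        W = rook_region_weights(land.partition)
        post = fit_sls_probit(design, y, land.partition, W,
                              MCMCSettings(seed=2), region_index=ridx)
        lo, hi = post.rho_interval()
        assert post.rho_mean > 0
        assert lo > 0

    def test_latent_truncation_and_admissible_draws(self, fitted):
        land, design, y, ridx, W, post = fitted
        lo, hi = W.admissible_interval()
        assert ((post.rho_draws > lo) & (post.rho_draws < hi)).all()
        assert (post.sigma2_draws > 0).all()

    def test_observation_without_region_rejected(self, fitted):
        land, design, y, ridx, W, _ = fitted
        bad = ridx.copy()
        bad[0] = land.partition.m + 5
        with pytest.raises(ValueError, match="region"):
            fit_sls_probit(design, y, land.partition, W,
                           MCMCSettings(n_burn=1, n_keep=1), region_index=bad)


def test_prior_only_theta_scan_reproduces_sar_covariance(rng):
    """Gibbs scans with no data converge to the SAR prior covariance."""
    part = partition_raster(RasterGrid(np.zeros((25, 25))), 5)  # m = 25
    W = rook_region_weights(part)
    rho, sigma2 = 0.5, 1.0
    m = part.m
    A = (sp.identity(m) - rho * W.W).tocsr()
    B = ((A.T @ A) / sigma2).tocsr()
    B.sum_duplicates()
    expected_cov = np.linalg.inv(B.toarray())

    theta = np.zeros(m)
    zeros = np.zeros(m)
    draws = []
    for it in range(6000):
        gibbs_theta_scan(theta, zeros, zeros, B, rng)
        if it >= 1000:
            draws.append(theta.copy())
    draws = np.array(draws)
    emp = np.cov(draws.T)
    scale = np.sqrt(np.outer(np.diag(expected_cov), np.diag(expected_cov)))
    assert np.abs(emp - expected_cov).max() / scale.max() < 0.15
    assert np.abs(np.diag(emp) - np.diag(expected_cov)).max() < 0.25


class TestFittedValues:
    def test_zero_parameters_give_half(self, fitted):
        land, design, y, ridx, W, post = fitted
        import copy

        p0 = copy.copy(post)
        p0.beta_draws = np.zeros_like(post.beta_draws)
        p0.theta_draws = np.zeros_like(post.theta_draws)
        assert fitted_probabilities(p0, design) == pytest.approx(0.5)

    def test_region_constancy_and_hand_evaluation(self):
        # 3-region toy: cells with identical x in the same region share p
        from scipy.special import ndtr

        part = partition_raster(RasterGrid(np.zeros((5, 15))), 5)
        W = rook_region_weights(part)
        ridx = part.region_id_per_cell[part.region_id_per_cell >= 0]
        x = np.tile(np.linspace(-1, 1, 25), 3)
        design = DesignMatrix(pd.DataFrame({"x": x}))
        y = (x > 0).astype(int)
        y[0] = 1 - y[0]  # avoid separation
        post = fit_sls_probit(design, y, part, W,
                              MCMCSettings(n_burn=50, n_keep=50, seed=3),
                              region_index=ridx)
        p = fitted_probabilities(post, design)
        expected = ndtr(design.X @ post.beta_mean
                        + post.theta_mean[ridx])
        assert p == pytest.approx(expected)
        same = (x == x[0]) & (ridx == ridx[0])
        assert np.unique(p[same]).size == 1


class TestSpatialAPE:
    def test_reductions_and_finite_difference(self, fitted):
        land, design, y, ridx, W, post = fitted
        # theta = 0 reduces to the NSP APE at the same coefficients
        import copy

        p0 = copy.copy(post)
        p0.theta_draws = np.zeros_like(post.theta_draws)
        from selva.spatial import _fit_from_posterior

        fit = _fit_from_posterior(post)
        assert ape_spatial(p0, design, "dist1") == pytest.approx(
            ape_continuous(fit, design, "dist1"))
        # finite-difference oracle including theta in the index
        from scipy.special import ndtr

        h = 1e-5
        x = design.data["dist1"].to_numpy()
        up = design.with_columns({"dist1": x + h})
        dn = design.with_columns({"dist1": x - h})
        off = post.theta_mean[ridx]
        fd = np.mean((ndtr(up.X @ post.beta_mean + off)
                      - ndtr(dn.X @ post.beta_mean + off)) / (2 * h))
        assert ape_spatial(post, design, "dist1") == pytest.approx(fd, abs=1e-6)

    def test_binary_kind(self, fitted):
        land, design, y, ridx, W, post = fitted
        got = ape_spatial(post, design, "bin1", kind="binary")
        from selva.spatial import _fit_from_posterior

        fit = _fit_from_posterior(post)
        ref = ape_binary(fit, design, "bin1",
                         offsets=post.theta_mean[ridx])
        assert got == pytest.approx(ref)
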