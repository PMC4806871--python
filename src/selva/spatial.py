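"""Hierarchical Bayesian probit with region-level spatial autoregressive effects.

Model, for cell i in region j:

    y*_ij = x_ij' beta + theta_j + e_ij,   e_ij ~ N(0, 1)
    y_ij  = 1[y*_ij > 0]
    theta_j = rho sum_k w_jk theta_k + mu_j,   mu_j ~ N(0, sigma^2)

so the m regional effects follow a spatial autoregressive (SAR) process
theta ~ N(0, sigma^2 [(I - rho W)'(I - rho W)]^-1) over the row-normalized
region weight matrix W.  The latent error variance is fixed at 1 for
probit identification.

Estimation is by Gibbs sampling with data augmentation:

1. latent y* from its truncated-normal conditional (inverse-CDF, tail-safe),
2. beta from its multivariate-normal conditional given y* - theta,
3. each theta_j from a univariate normal combining its n_j observations
   with the SAR prior precision (systematic scan in label order),
4. sigma^2 from its inverse-gamma conditional,
5. rho by griddy Gibbs over a precomputed log-determinant grid of
   ln|I - rho W|.

Point estimates are posterior means of the retained draws; reported
standard errors are the standard deviations of those draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy import special
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .probit import DesignMatrix, ProbitFit, ape_binary, ape_continuous
from .regions import RegionPartition, RegionWeights

__all__ = [
    "MCMCSettings",
    "SpatialProbitPosterior",
    "fit_sls_probit",
    "log_det_grid",
    "fitted_probabilities",
    "ape_spatial",
    "draw_truncated_latent",
    "gibbs_theta_scan",
]


@dataclass
class MCMCSettings:
    """Sampler configuration; defaults follow the diffuse-prior convention.

    beta ~ N(0, c^-1 I) with tiny precision c; p(sigma^2) follows an
    inverse gamma with shape/scale (0, 0), i.e. proportional to
    1/sigma^2; rho is uniform over the admissible spectral interval.
    """

    n_burn: int = 500
    n_keep: int = 500
    seed: int = 0
    rho_grid_size: int = 201
    beta_prior_precision: float = 1e-8
    sigma2_prior_shape: float = 0.0
    sigma2_prior_scale: float = 0.0

    def __post_init__(self) -> None:
        if self.n_burn < 1 or self.n_keep < 1:
            raise ValueError("n_burn and n_keep must be >= 1")
        if self.rho_grid_size < 2:
            raise ValueError("rho_grid_size must be >= 2")


@dataclass
class SpatialProbitPosterior:
    """Retained MCMC draws plus references to the partition and weights."""

    beta_draws: np.ndarray    # (n_keep, p)
    rho_draws: np.ndarray     # (n_keep,)
    sigma2_draws: np.ndarray  # (n_keep,)
    theta_draws: np.ndarray   # (n_keep, m)
    columns: list[str]
    region_index: np.ndarray  # (n,) region label per observation
    partition: RegionPartition
    weights: RegionWeights
    settings: MCMCSettings
    split_diagnostic: dict[str, float] = field(default_factory=dict)

    @property
    def beta_mean(self) -> np.ndarray:
        return self.beta_draws.mean(axis=0)

    @property
    def beta_sd(self) -> np.ndarray:
        return self.beta_draws.std(axis=0, ddof=1)

    @property
    def theta_mean(self) -> np.ndarray:
        return self.theta_draws.mean(axis=0)

    @property
    def rho_mean(self) -> float:
        return float(self.rho_draws.mean())

    @property
    def rho_sd(self) -> float:
        return float(self.rho_draws.std(ddof=1))

    def rho_interval(self, level: float = 0.95) -> tuple[float, float]:
        lo = (1 - level) / 2
        return tuple(np.quantile(self.rho_draws, [lo, 1 - lo]))

    def beta_interval(self, level: float = 0.95) -> np.ndarray:
        lo = (1 - level) / 2
        return np.quantile(self.beta_draws, [lo, 1 - lo], axis=0).T

    def summary(self) -> dict[str, dict[str, float]]:
        out = {
            name: {"mean": float(mu), "sd": float(sd)}
            for name, mu, sd in zip(self.columns, self.beta_mean, self.beta_sd)
        }
        out["rho"] = {"mean": self.rho_mean, "sd": self.rho_sd}
        out["sigma2"] = {
            "mean": float(self.sigma2_draws.mean()),
            "sd": float(self.sigma2_draws.std(ddof=1)),
        }
        return out


def draw_truncated_latent(
    mean: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Inverse-CDF truncated-normal draws with unit variance.

    Truncation is to (0, inf) where y = 1 and (-inf, 0] where y = 0.
    Uses log_ndtr / ndtri_exp so extreme means do not overflow: for
    y = 1,  x = m - ndtri_exp(log u + log Phi(m))  maps u in (0,1) to
    the upper tail through the survival function.
    """
    u = rng.random(mean.shape)
    np.clip(u, 1e-16, 1.0 - 1e-16, out=u)
    logu = np.log(u)
    pos = y == 1
    x = np.empty_like(mean, dtype=float)
    x[pos] = mean[pos] - special.ndtri_exp(
        logu[pos] + special.log_ndtr(mean[pos])
    )
    x[~pos] = mean[~pos] + special.ndtri_exp(
        logu[~pos] + special.log_ndtr(-mean[~pos])
    )
    return x


def log_det_grid(
    weights: RegionWeights, grid_size: int = 201, margin: float = 1e-4
) -> tuple[np.ndarray, np.ndarray]:
    """Grid of (rho, ln|I - rho W|) over the open admissible interval.

    The interval endpoints are the reciprocals of W's extreme real
    eigenvalues; ``margin`` shrinks the grid slightly inside the open
    interval.  Determinants come from a sparse LU factorization (the
    determinant is positive throughout the admissible interval).
    """
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    lo, hi = weights.admissible_interval()
    if not np.isfinite(hi):
        hi = 1.0
    if not np.isfinite(lo):
        lo = -1.0 / max(abs(hi), 1.0)
    span = hi - lo
    rho_grid = np.linspace(lo + margin * span, hi - margin * span, grid_size)
    m = weights.m
    I = sp.identity(m, format="csc")
    Wc = weights.W.tocsc()
    logdets = np.empty(grid_size)
    for g, rho in enumerate(rho_grid):
        lu = sp.linalg.splu(I - rho * Wc)
        logdets[g] = float(np.log(np.abs(lu.U.diagonal())).sum())
    if not np.isfinite(logdets).all():
        raise RuntimeError("log-determinant grid contains non-finite values")
    return rho_grid, logdets


def gibbs_theta_scan(
    theta: np.ndarray,
    region_sums: np.ndarray,
    n_per_region: np.ndarray,
    B: sp.csr_matrix,
    rng: np.random.Generator,
) -> None:
    """One systematic scan of the theta conditionals, updating in place.

    ``B`` is the SAR prior precision (I - rho W)'(I - rho W) / sigma^2;
    each theta_j conditional combines its n_j unit-variance observations
    (summed residuals ``region_sums``) with the prior row.  With
    n_per_region = 0 this samples the SAR prior itself.
    """
    m = len(theta)
    indptr, indices, data = B.indptr, B.indices, B.data
    z = rng.standard_normal(m)
    for j in range(m):
        s, e = indptr[j], indptr[j + 1]
        cols = indices[s:e]
        vals = data[s:e]
        pos = np.searchsorted(cols, j)
        Bjj = vals[pos] if pos < len(cols) and cols[pos] == j else 0.0
        cross = vals @ theta[cols] - Bjj * theta[j]
        prec = n_per_region[j] + Bjj
        mean = (region_sums[j] - cross) / prec
        theta[j] = mean + z[j] / np.sqrt(prec)


def fit_sls_probit(
    design: DesignMatrix,
    y: np.ndarray,
    partition: RegionPartition,
    weights: RegionWeights,
    settings: MCMCSettings | None = None,
    region_index: np.ndarray | None = None,
) -> SpatialProbitPosterior:
    """Gibbs sampler for the regional spatial probit.

    ``region_index`` gives the region label of each observation; if
    omitted, observations are assumed to be the partition's unmasked
    cells in row-major order.
    """
    settings = settings or MCMCSettings()
    X = design.X
    y = np.asarray(y).ravel().astype(int)
    n, p = X.shape
    m = partition.m
    if region_index is None:
        region_index = partition.region_id_per_cell[
            partition.region_id_per_cell >= 0
        ]
    region_index = np.asarray(region_index)
    if len(region_index) != n:
        raise ValueError("region_index length does not match design rows")
    if (region_index < 0).any() or (region_index >= m).any():
        raise ValueError("observation with no region in the partition")
    if y.min() == y.max():
        raise ValueError("outcome has a single class")
    if weights.m != m:
        raise ValueError("weight matrix size does not match partition")

    rng = np.random.default_rng(settings.seed)
    rho_grid, logdets = log_det_grid(weights, settings.rho_grid_size)

    W = weights.W.tocsr()
    WpWt = (W + W.T).tocsr()
    WtW = (W.T @ W).tocsr()
    I = sp.identity(m, format="csr")
    n_per_region = np.bincount(region_index, minlength=m).astype(float)

    # beta conditional: fixed posterior precision X'X + cI
    prec_beta = X.T @ X + settings.beta_prior_precision * np.eye(p)
    cb, low = cho_factor(prec_beta)
    Ub = np.linalg.cholesky(prec_beta).T  # upper: prec = Ub' Ub

    beta = np.zeros(p)
    theta = np.zeros(m)
    sigma2 = 1.0
    rho = float(rho_grid[np.argmin(np.abs(rho_grid))])

    n_total = settings.n_burn + settings.n_keep
    beta_draws = np.empty((settings.n_keep, p))
    rho_draws = np.empty(settings.n_keep)
    sigma2_draws = np.empty(settings.n_keep)
    theta_draws = np.empty((settings.n_keep, m))

    for it in range(n_total):
        # 1. latent utilities
        eta = X @ beta + theta[region_index]
        ystar = draw_truncated_latent(eta, y, rng)

        # 2. beta | ystar, theta
        rhs = X.T @ (ystar - theta[region_index])
        mean_b = cho_solve((cb, low), rhs)
        beta = mean_b + solve_triangular(Ub, rng.standard_normal(p))

        # 3. theta_j | rest, systematic scan
        resid = ystar - X @ beta
        region_sums = np.bincount(region_index, weights=resid, minlength=m)
        B = ((I - rho * WpWt + rho * rho * WtW) / sigma2).tocsr()
        B.sum_duplicates()
        gibbs_theta_scan(theta, region_sums, n_per_region, B, rng)

        # 4. sigma^2 | theta, rho  (inverse gamma)
        mu = theta - rho * (W @ theta)
        shape = settings.sigma2_prior_shape + 0.5 * m
        scale = settings.sigma2_prior_scale + 0.5 * float(mu @ mu)
        sigma2 = scale / rng.gamma(shape)

        # 5. rho | theta, sigma^2 by griddy Gibbs
        Wt = W @ theta
        quad = (
            float(theta @ theta)
            - 2.0 * rho_grid * float(theta @ Wt)
            + rho_grid**2 * float(Wt @ Wt)
        )
        logp = logdets - quad / (2.0 * sigma2)
        logp -= logp.max()
        prob = np.exp(logp)
        prob /= prob.sum()
        rho = float(rho_grid[np.searchsorted(np.cumsum(prob), rng.random())])

        k = it - settings.n_burn
        if k >= 0:
            beta_draws[k] = beta
            rho_draws[k] = rho
            sigma2_draws[k] = sigma2
            theta_draws[k] = theta

    half = settings.n_keep // 2
    diag = {}
    if half >= 2:
        sd = rho_draws.std(ddof=1)
        diag["rho_split_mean_diff_in_sd"] = float(
            abs(rho_draws[:half].mean() - rho_draws[half:].mean()) / max(sd, 1e-12)
        )
    return SpatialProbitPosterior(
        beta_draws=beta_draws,
        rho_draws=rho_draws,
        sigma2_draws=sigma2_draws,
        theta_draws=theta_draws,
        columns=design.columns,
        region_index=region_index,
        partition=partition,
        weights=weights,
        settings=settings,
        split_diagnostic=diag,
    )


def fitted_probabilities(
    post: SpatialProbitPosterior, design: DesignMatrix
) -> np.ndarray:
    """In-sample p_ij = Phi(x_ij' beta_bar + theta_bar_j) at posterior means."""
    if design.columns != post.columns:
        raise ValueError("design columns do not match posterior")
    if len(design.data) != len(post.region_index):
        raise ValueError("design rows do not match posterior observations")
    eta = design.X @ post.beta_mean + post.theta_mean[post.region_index]
    return special.ndtr(eta)


def _fit_from_posterior(post: SpatialProbitPosterior) -> ProbitFit:
    p = len(post.beta_mean)
    return ProbitFit(
        beta_hat=post.beta_mean,
        vcov_model=np.eye(p),
        vcov_robust=None,
        loglik=np.nan,
        fitted_prob=np.empty(0),
        converged=True,
        columns=post.columns,
    )


def ape_spatial(
    post: SpatialProbitPosterior,
    design: DesignMatrix,
    k: str,
    kind: str = "continuous",
) -> float:
    """Average partial effect at posterior means, regional effect in the index.

    Same formulas as the non-spatial case; the only difference is that
    the fitted latent index includes theta_bar_j.
    """
    offsets = post.theta_mean[post.region_index]
    fit = _fit_from_posterior(post)
    if kind == "continuous":
        return ape_continuous(fit, design, k, offsets=offsets)
    if kind == "binary":
        return ape_binary(fit, design, k, offsets=offsets)
    raise ValueError("kind must be 'continuous' or 'binary'")
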