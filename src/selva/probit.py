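"""Maximum-likelihood probit with robust standard errors and partial effects.

The land-change outcome is 1 where the latent rent difference
y* = x'beta + e exceeds zero, with e standard normal, so
P(y = 1 | x) = Phi(x'beta).  Quadratic terms (a covariate and its
square) are explicit columns linked by a pairing map; the map drives the
average-partial-effect formula for level+quadratic covariates:

    APE_k = N^-1 sum_i (b_k + 2 b_k2 x_ik) phi(x_i b)

and for a binary covariate the discrete difference

    APE_k = N^-1 sum_i [Phi(x_{-k,i} b_{-k} + b_k) - Phi(x_{-k,i} b_{-k})].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special
from scipy.stats import norm

__all__ = [
    "DesignMatrix",
    "ProbitFit",
    "PerfectSeparationError",
    "fit_probit_mle",
    "robust_vcov",
    "ape_continuous",
    "ape_binary",
    "predict_prob",
]


class PerfectSeparationError(RuntimeError):
    """The likelihood diverges: a hyperplane separates the two classes."""


@dataclass
class DesignMatrix:
    """n x p design with an intercept column and a quadratic-pairing map.

    ``quad_pairs`` maps a level column name to the name of its squared
    column.  Squared columns must equal the element-wise square of their
    level column; no column other than the intercept may be constant.
    """

    data: pd.DataFrame
    intercept: str = "const"
    quad_pairs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.intercept not in self.data.columns:
            self.data = self.data.copy()
            self.data.insert(0, self.intercept, 1.0)
        X = self.data.to_numpy(dtype=float)
        names = list(self.data.columns)
        for j, name in enumerate(names):
            if name != self.intercept and np.ptp(X[:, j]) == 0:
                raise ValueError(f"column {name!r} is constant (non-intercept)")
        for level, sq in self.quad_pairs.items():
            if not np.allclose(self.data[sq], self.data[level] ** 2):
                raise ValueError(f"{sq!r} is not the square of {level!r}")

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    @property
    def X(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def col(self, name: str) -> int:
        return self.columns.index(name)

    def with_columns(self, updates: dict[str, np.ndarray]) -> "DesignMatrix":
        data = self.data.copy()
        for name, vals in updates.items():
            data[name] = vals
        for level, sq in self.quad_pairs.items():
            if level in updates:
                data[sq] = data[level] ** 2
        return DesignMatrix(data, self.intercept, dict(self.quad_pairs))


@dataclass
class ProbitFit:
    beta_hat: np.ndarray
    vcov_model: np.ndarray
    vcov_robust: np.ndarray | None
    loglik: float
    fitted_prob: np.ndarray
    converged: bool
    columns: list[str]
    n_iter: int = 0

    def se_model(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov_model))

    def se_robust(self) -> np.ndarray:
        if self.vcov_robust is None:
            raise ValueError("robust vcov not computed")
        return np.sqrt(np.diag(self.vcov_robust))

    def coef(self, name: str) -> float:
        return float(self.beta_hat[self.columns.index(name)])


def _loglik_parts(X: np.ndarray, y: np.ndarray, beta: np.ndarray):
    """Log-likelihood, per-observation score weight, and working weights.

    Uses log_ndtr for tail-safe evaluation; lambda_i is the per-row
    score factor  phi(eta) (y - Phi) / (Phi (1-Phi)).
    """
    eta = X @ beta
    ll = np.where(y == 1, special.log_ndtr(eta), special.log_ndtr(-eta)).sum()
    phi = norm.pdf(eta)
    P = special.ndtr(eta)
    # inverse Mills expressions, computed in the numerically safe branch
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = np.where(y == 1, phi / np.maximum(P, 1e-300),
                       -phi / np.maximum(1 - P, 1e-300))
    # Hessian weight for the observed information: lam * (lam + eta)
    w = lam * (lam + eta)
    return float(ll), lam, w, eta


def fit_probit_mle(
    design: DesignMatrix,
    y: np.ndarray,
    max_iter: int = 100,
    grad_tol: float = 1e-8,
    ll_tol: float = 1e-12,
) -> ProbitFit:
    """Newton-Raphson probit MLE with step-halving.

    Converges when the gradient max-norm drops below ``grad_tol`` or the
    relative log-likelihood change below ``ll_tol``.  Divergence of the
    coefficients with an improving likelihood (|beta| > 50) is reported
    as perfect separation.
    """
    X = design.X
    y = np.asarray(y).ravel().astype(float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than parameters")
    if y.min() == y.max():
        raise ValueError("outcome has a single class")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")

    beta = np.zeros(p)
    # intercept start at Phi^-1(ybar)
    beta[design.col(design.intercept)] = norm.ppf(y.mean())
    ll, lam, w, _ = _loglik_parts(X, y, beta)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        grad = X.T @ lam
        if np.max(np.abs(grad)) < grad_tol:
            converged = True
            break
        H = (X * w[:, None]).T @ X  # observed information
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("singular information matrix") from exc
        # step-halving line search
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, lam_new, w_new, _ = _loglik_parts(X, y, cand)
            if ll_new >= ll - 1e-13:
                break
            scale *= 0.5
        if np.max(np.abs(cand)) > 50 and ll_new > ll:
            raise PerfectSeparationError(
                "coefficients diverging with improving likelihood"
            )
        rel = abs(ll_new - ll) / max(1.0, abs(ll))
        beta, ll, lam, w = cand, ll_new, lam_new, w_new
        if rel < ll_tol:
            converged = True
            break
    H = (X * w[:, None]).T @ X
    vcov = np.linalg.inv(H)
    vcov = 0.5 * (vcov + vcov.T)
    fit = ProbitFit(
        beta_hat=beta,
        vcov_model=vcov,
        vcov_robust=None,
        loglik=ll,
        fitted_prob=special.ndtr(X @ beta),
        converged=converged,
        columns=design.columns,
        n_iter=n_iter,
    )
    fit.vcov_robust = robust_vcov(fit, design, y)
    return fit


def robust_vcov(fit: ProbitFit, design: DesignMatrix, y: np.ndarray) -> np.ndarray:
    """Huber-White sandwich A^-1 B A^-1.

    A is the observed information, B the outer product of per-observation
    score contributions s_i = lambda_i x_i.
    """
    if not fit.converged:
        raise ValueError("fit did not converge; sandwich undefined")
    X = design.X
    y = np.asarray(y).ravel().astype(float)
    _, lam, w, _ = _loglik_parts(X, y, fit.beta_hat)
    A = (X * w[:, None]).T @ X
    S = X * lam[:, None]
    B = S.T @ S
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError("singular information matrix") from exc
    V = Ainv @ B @ Ainv
    return 0.5 * (V + V.T)


def ape_continuous(
    fit: ProbitFit,
    design: DesignMatrix,
    k: str,
    offsets: np.ndarray | None = None,
) -> float:
    """Average partial effect of continuous covariate ``k``.

    If ``k`` has a paired squared column the level+quadratic formula is
    used; otherwise the quadratic coefficient is zero.  ``offsets`` adds
    a per-row term inside the index (the regional effect of the spatial
    model); default none.
    """
    if k == design.intercept:
        raise ValueError("APE of the intercept is undefined")
    X = design.X
    eta = X @ fit.beta_hat
    if offsets is not None:
        eta = eta + offsets
    bk = fit.beta_hat[design.col(k)]
    bk2 = 0.0
    if k in design.quad_pairs:
        bk2 = fit.beta_hat[design.col(design.quad_pairs[k])]
    xk = X[:, design.col(k)]
    return float(np.mean((bk + 2.0 * bk2 * xk) * norm.pdf(eta)))


def ape_binary(
    fit: ProbitFit,
    design: DesignMatrix,
    k: str,
    offsets: np.ndarray | None = None,
) -> float:
    """Average partial effect of binary covariate ``k`` (discrete difference)."""
    j = design.col(k)
    xk = design.X[:, j]
    if not np.isin(xk, (0.0, 1.0)).all():
        raise ValueError(f"column {k!r} is not binary 0/1")
    X = design.X
    bk = fit.beta_hat[j]
    eta_without = X @ fit.beta_hat - xk * bk
    if offsets is not None:
        eta_without = eta_without + offsets
    return float(np.mean(special.ndtr(eta_without + bk) - special.ndtr(eta_without)))


def predict_prob(fit: ProbitFit, design: DesignMatrix) -> np.ndarray:
    """Phi(X beta_hat) for a design with columns matching the fit."""
    if design.columns != fit.columns:
        raise ValueError(
            f"design columns {design.columns} do not match fit {fit.columns}"
        )
    return special.ndtr(design.X @ fit.beta_hat)
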