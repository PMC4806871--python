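"""Road-construction scenarios: new covariates, probabilities, ensembles.

A planned-roads layer is merged with the current network; road-derived
covariates (distance to roads, distance to prior deforestation) are
recomputed from the merged mask and plugged into the fitted latent
index, giving new probability surfaces:

    non-spatial:  p_i  = Phi(a TC*_i + x_i' b)
    spatial:      p_ij = Phi(a TC*_ij + x_ij' b + rho sum_k w_jk theta_k)

Stochastic deforestation landscapes then compare each cell's probability
with an independent uniform draw (deforested iff p > u); emissions sum
the aboveground carbon of deforested cells, assuming full release.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import special

from .costdist import euclidean_distance
from .evaluate import CrossTab  # noqa: F401  (re-exported convenience)
from .probit import DesignMatrix, ProbitFit, predict_prob
from .raster import RasterGrid
from .spatial import SpatialProbitPosterior

__all__ = [
    "ScenarioEnsemble",
    "merge_road_masks",
    "apply_road_scenario",
    "scenario_probabilities",
    "simulate_landscapes",
    "carbon_emissions",
]


@dataclass
class ScenarioEnsemble:
    """Per-realization deforested-cell counts and carbon totals."""

    counts: np.ndarray          # (n_realizations,) int
    emissions: np.ndarray | None  # (n_realizations,) tons, or None
    seed: int

    @property
    def n_realizations(self) -> int:
        return len(self.counts)

    @property
    def count_range(self) -> tuple[int, int]:
        return int(self.counts.min()), int(self.counts.max())

    @property
    def mean_count(self) -> float:
        return float(self.counts.mean())

    @property
    def mean_emissions(self) -> float | None:
        return None if self.emissions is None else float(self.emissions.mean())

    def summary(self) -> dict:
        out = {
            "n_realizations": self.n_realizations,
            "mean_count": self.mean_count,
            "count_min": self.count_range[0],
            "count_max": self.count_range[1],
            "seed": self.seed,
        }
        if self.emissions is not None:
            out["mean_emissions_tons"] = self.mean_emissions
        return out


def merge_road_masks(base: RasterGrid, new: RasterGrid) -> RasterGrid:
    """Union of the current and planned road masks."""
    if base.shape != new.shape:
        raise ValueError("road mask shapes differ")
    merged = (base.values > 0) | (new.values > 0)
    return base.like((merged & base.mask).astype(float))


def apply_road_scenario(
    design: DesignMatrix,
    rules: Mapping[str, RasterGrid],
    valid_mask: np.ndarray,
    distance_unit_m: float = 1.0,
) -> DesignMatrix:
    """Recompute road-derived distance columns from merged feature masks.

    ``rules`` maps each road-derived column to the (already merged)
    feature raster whose Euclidean distance replaces it; paired
    quadratic columns are re-squared automatically and all other columns
    are untouched.  A rule naming a column absent from the design is an
    error, as is a road-derived column without a rule (callers list the
    derived columns in ``rules`` — there is no other recomputation path).
    """
    updates: dict[str, np.ndarray] = {}
    for col, feature_grid in rules.items():
        if col not in design.columns:
            raise KeyError(f"no recomputation rule target: column {col!r} "
                           "is not in the design")
        d = euclidean_distance(feature_grid).values / distance_unit_m
        updates[col] = d[valid_mask]
    return design.with_columns(updates)


def scenario_probabilities(
    fit: ProbitFit | SpatialProbitPosterior,
    design_star: DesignMatrix,
    mask_grid: RasterGrid,
    model: str = "nsp",
) -> RasterGrid:
    """Probability surface under the scenario design.

    ``model="nsp"`` evaluates Phi(X* b_hat); ``model="sls"`` adds the
    smoothed regional effect rho_hat * (W theta_hat)_j to the index,
    exactly the out-of-sample form of the scenario equations.
    """
    if model == "nsp":
        if not isinstance(fit, ProbitFit):
            raise TypeError("model='nsp' needs a ProbitFit")
        p = predict_prob(fit, design_star)
    elif model == "sls":
        if not isinstance(fit, SpatialProbitPosterior):
            raise TypeError("missing posterior: model='sls' needs a "
                            "SpatialProbitPosterior")
        if design_star.columns != fit.columns:
            raise ValueError("design columns do not match posterior")
        smoothed = fit.weights.W @ fit.theta_mean
        eta = (design_star.X @ fit.beta_mean
               + fit.rho_mean * smoothed[fit.region_index])
        p = special.ndtr(eta)
    else:
        raise ValueError("model must be 'nsp' or 'sls'")
    out = np.zeros(mask_grid.shape)
    out[mask_grid.mask] = p
    return mask_grid.like(out)


def simulate_landscapes(
    prob: RasterGrid,
    n: int,
    seed: int,
    carbon: RasterGrid | None = None,
    keep_realizations: bool = False,
) -> ScenarioEnsemble | tuple[ScenarioEnsemble, np.ndarray]:
    """Stochastic deforestation ensemble from a probability surface.

    Per realization, each unmasked cell receives an independent U(0,1)
    draw and is deforested iff its probability strictly exceeds it; a
    cell with p = 0 can never deforest.  Deterministic given the seed.
    """
    if n < 1:
        raise ValueError("need at least one realization")
    p = prob.valid_values()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("probabilities must lie in [0, 1]")
    if carbon is not None:
        if carbon.shape != prob.shape:
            raise ValueError("carbon surface shape mismatch")
        c = carbon.valid_values()
        if (c < 0).any():
            raise ValueError("negative carbon value")
    rng = np.random.default_rng(seed)
    counts = np.empty(n, dtype=int)
    emissions = np.empty(n) if carbon is not None else None
    reals = np.empty((n, len(p)), dtype=bool) if keep_realizations else None
    for r in range(n):
        u = rng.random(len(p))
        defo = p > u
        counts[r] = int(defo.sum())
        if emissions is not None:
            emissions[r] = float(c[defo].sum())
        if reals is not None:
            reals[r] = defo
    ens = ScenarioEnsemble(counts, emissions, seed)
    return (ens, reals) if keep_realizations else ens


def carbon_emissions(realization: RasterGrid, carbon: RasterGrid) -> float:
    """Total carbon (tons) of deforested cells, assuming full release."""
    if realization.shape != carbon.shape:
        raise ValueError("shape mismatch")
    c = carbon.values
    if (c[carbon.mask] < 0).any():
        raise ValueError("negative carbon value")
    defo = (realization.values > 0) & realization.mask & carbon.mask
    return float(c[defo].sum())
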