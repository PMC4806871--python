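"""Synthetic raster landscapes with known land-change parameters.

The generator emulates the statistical structure the analysis assumes —
a masked lattice of cells grouped into block regions, regional effects
theta drawn from a spatial autoregressive process with dependence rho,
distance-like and categorical covariates, a probit outcome from the
latent-rent model, transport frictions by class, and a smooth
aboveground-carbon surface — so that every downstream stage is testable
and parameter recovery verifiable without any external GIS data.

Stochastic substeps draw from independently spawned substreams of one
master seed, so e.g. adding a covariate does not perturb the regional
effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
import yaml
from scipy.ndimage import gaussian_filter

from .costdist import DEFAULT_FRICTION_TABLE, accumulated_cost, build_friction, euclidean_distance
from .probit import DesignMatrix
from .raster import RasterGrid, write_ascii_grid
from .regions import RegionPartition, partition_raster, rook_region_weights

__all__ = ["SynthConfig", "SyntheticLandscape", "generate_landscape",
           "generate_road_scenario"]

# friction class codes used on the synthetic class raster
CLASS_CODES = {
    "natural_bed_forest": 0.0,
    "class_i_river": 1.0,
    "class_ii_river": 2.0,
    "class_iii_river": 3.0,
    "class_iv_river": 4.0,
    "asphalt_road": 5.0,
    "dirt_road": 6.0,
}
CODE_RATES = {CLASS_CODES[k]: v for k, v in DEFAULT_FRICTION_TABLE.items()}


@dataclass
class SynthConfig:
    """Study conditions for a synthetic landscape.

    Defaults give a 50x50 grid of 900 m cells tiled into 5x5-cell
    regions (m = 100), regional dependence rho = 0.5 with innovation
    variance sigma2 = 1, and three covariates (one distance-like, one
    smooth continuous, one binary) beside the transport-cost term.
    Carbon is in tons per cell, spanning a range whose mean matches
    meso-scale Amazonian aboveground stocks at this cell size.
    """

    n_rows: int = 50
    n_cols: int = 50
    resolution_m: float = 900.0
    block: int = 5
    alpha: float = -0.02          # transport-cost coefficient (per currency unit)
    beta: dict[str, float] = field(default_factory=lambda: {
        "const": 0.3, "dist1": -0.4, "smooth1": 0.3, "bin1": 0.5,
    })
    rho: float = 0.5
    sigma2: float = 1.0
    n_distance: int = 1
    n_smooth: int = 1
    n_binary: int = 1
    friction_table: dict[float, float] = field(
        default_factory=lambda: dict(CODE_RATES))
    carbon_range: tuple[float, float] = (2000.0, 8000.0)
    mask_fraction: float = 0.05
    n_road_lines: int = 3
    n_river_lines: int = 4
    n_markets: int = 2
    distance_unit_m: float = 10_000.0  # distance covariates in units of 10 km
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < self.block or self.n_cols < self.block:
            raise ValueError("grid smaller than one region")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        if not 0 <= self.mask_fraction < 1:
            raise ValueError("mask_fraction must be in [0, 1)")
        if any(v <= 0 for v in self.friction_table.values()):
            raise ValueError("friction values must be positive")
        expected = (["const"]
                    + [f"dist{i+1}" for i in range(self.n_distance)]
                    + [f"smooth{i+1}" for i in range(self.n_smooth)]
                    + [f"bin{i+1}" for i in range(self.n_binary)])
        if set(self.beta) != set(expected):
            raise ValueError(
                f"beta must have entries exactly for {expected}, got {list(self.beta)}"
            )

    def covariate_names(self) -> list[str]:
        return ([f"dist{i+1}" for i in range(self.n_distance)]
                + [f"smooth{i+1}" for i in range(self.n_smooth)]
                + [f"bin{i+1}" for i in range(self.n_binary)])


@dataclass
class SyntheticLandscape:
    """A generated landscape plus the truth that produced it."""

    covariates: dict[str, RasterGrid]  # includes "TC"
    outcome: RasterGrid
    latent: RasterGrid
    theta_true: np.ndarray
    roads_mask: RasterGrid
    markets_mask: RasterGrid
    friction_class: RasterGrid
    carbon: RasterGrid
    partition: RegionPartition
    truth: SynthConfig

    @property
    def mask_grid(self) -> RasterGrid:
        return self.outcome

    def design_and_outcome(self) -> tuple[DesignMatrix, np.ndarray, np.ndarray]:
        """Design matrix, outcome vector and region index over unmasked cells."""
        import pandas as pd

        mask = self.outcome.mask
        cols = {"const": np.ones(int(mask.sum()))}
        cols["TC"] = self.covariates["TC"].values[mask]
        for name in self.truth.covariate_names():
            cols[name] = self.covariates[name].values[mask]
        design = DesignMatrix(pd.DataFrame(cols))
        y = self.outcome.values[mask].astype(int)
        region_index = self.partition.region_id_per_cell[mask]
        return design, y, region_index

    def true_beta_vector(self, columns: list[str]) -> np.ndarray:
        """Truth coefficients ordered like ``columns`` (TC carries alpha)."""
        full = dict(self.truth.beta)
        full["TC"] = self.truth.alpha
        return np.array([full[c] for c in columns])

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, grid in self.covariates.items():
            write_ascii_grid(grid, out / f"cov_{name}.asc")
        write_ascii_grid(self.outcome, out / "outcome.asc")
        write_ascii_grid(self.latent, out / "latent.asc")
        write_ascii_grid(self.roads_mask, out / "roads.asc")
        write_ascii_grid(self.markets_mask, out / "markets.asc")
        write_ascii_grid(self.friction_class, out / "friction_class.asc")
        write_ascii_grid(self.carbon, out / "carbon.asc")
        truth = {
            "alpha": self.truth.alpha,
            "beta": dict(self.truth.beta),
            "rho": self.truth.rho,
            "sigma2": self.truth.sigma2,
            "seed": self.truth.seed,
            "block": self.truth.block,
            "resolution_m": self.truth.resolution_m,
        }
        (out / "truth.yaml").write_text(yaml.safe_dump(truth))


def _draw_line_cells(shape, rng) -> tuple[np.ndarray, np.ndarray]:
    """Cells of one random straight segment across the grid (Bresenham-like)."""
    nrows, ncols = shape
    r0, r1 = rng.integers(0, nrows, 2)
    c0, c1 = rng.integers(0, ncols, 2)
    length = max(abs(int(r1) - int(r0)), abs(int(c1) - int(c0))) + 1
    rr = np.round(np.linspace(r0, r1, length * 2)).astype(int)
    cc = np.round(np.linspace(c0, c1, length * 2)).astype(int)
    return rr, cc


def _rasterize_lines(shape, n_lines, rng) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    for _ in range(n_lines):
        rr, cc = _draw_line_cells(shape, rng)
        out[rr, cc] = True
    return out


def _smooth_field(shape, rng, sigma=3.0) -> np.ndarray:
    """Low-frequency standardized random field."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    return (f - f.mean()) / f.std()


def generate_landscape(config: SynthConfig) -> SyntheticLandscape:
    """Generate a landscape from the latent-rent model with SAR regional effects.

    theta solves (I - rho W) theta = mu with mu ~ N(0, sigma2) i.i.d.
    per region over the rook region weights of the generated mask; the
    per-cell latent is y* = alpha TC + x'beta + theta_j + e with e
    standard normal, and y = 1[y* > 0].  Deterministic given the seed.
    """
    shape = (config.n_rows, config.n_cols)
    streams = [np.random.default_rng(s) for s in
               np.random.SeedSequence(config.seed).spawn(8)]
    (rng_mask, rng_lines, rng_smooth, rng_bin,
     rng_theta, rng_e, rng_carbon, _spare) = streams

    # nodata mask as random blobs (exercises partial border regions)
    if config.mask_fraction > 0:
        blob = gaussian_filter(rng_mask.standard_normal(shape), sigma=2.0)
        thr = np.quantile(blob, config.mask_fraction)
        valid = blob > thr
    else:
        valid = np.ones(shape, dtype=bool)
    base = RasterGrid(np.zeros(shape), valid, config.resolution_m)

    # transport features and friction classes
    roads = _rasterize_lines(shape, config.n_road_lines, rng_lines)
    rivers = _rasterize_lines(shape, config.n_river_lines, rng_lines)
    class_vals = np.full(shape, CLASS_CODES["natural_bed_forest"])
    river_codes = [CLASS_CODES["class_i_river"], CLASS_CODES["class_ii_river"],
                   CLASS_CODES["class_iii_river"], CLASS_CODES["class_iv_river"]]
    class_vals[rivers] = rng_lines.choice(river_codes, size=int(rivers.sum()))
    class_vals[roads] = CLASS_CODES["dirt_road"]
    friction_class = base.like(class_vals)

    # markets sit on the river network (fluvial access dominates), so
    # market-access cost is not collinear with road distance
    net = rivers & valid
    if not net.any():
        net = (roads | rivers) & valid
    if not net.any():
        net = valid
    flat = np.flatnonzero(net)
    chosen = rng_lines.choice(flat, size=min(config.n_markets, len(flat)),
                              replace=False)
    markets = np.zeros(shape, dtype=bool)
    markets[np.unravel_index(chosen, shape)] = True
    markets_grid = base.like(markets.astype(float))
    roads_grid = base.like((roads & valid).astype(float))

    # accumulated transport cost to the cheapest market
    friction = build_friction(friction_class, config.friction_table)
    tc = accumulated_cost(friction, markets_grid).cost
    tc_vals = tc.values.copy()
    finite = np.isfinite(tc_vals)
    tc_vals[~finite] = tc_vals[finite].max() if finite.any() else 0.0
    tc = base.like(tc_vals)

    covariates: dict[str, RasterGrid] = {"TC": tc}
    # the first distance covariate is distance to the road network (the
    # scenario channel); any further ones measure other linear features
    for i in range(config.n_distance):
        if i == 0 and roads_grid.values.any():
            feats_grid = roads_grid
        else:
            feats = _rasterize_lines(shape, 2, rng_lines)
            feats_grid = base.like((feats & valid).astype(float))
            if not feats_grid.values.any():
                feats_grid = roads_grid
        d = euclidean_distance(feats_grid).values / config.distance_unit_m
        covariates[f"dist{i+1}"] = base.like(d)
    for i in range(config.n_smooth):
        covariates[f"smooth{i+1}"] = base.like(_smooth_field(shape, rng_smooth))
    for i in range(config.n_binary):
        fld = _smooth_field(shape, rng_bin)
        covariates[f"bin{i+1}"] = base.like((fld > 0).astype(float))

    # regional effects from the SAR process over the rook weights
    partition = partition_raster(base, config.block)
    m = partition.m
    mu = rng_theta.standard_normal(m) * np.sqrt(config.sigma2)
    if m >= 2:
        W = rook_region_weights(partition)
        lo, hi = W.admissible_interval()
        if not (lo < config.rho < hi):
            raise ValueError(
                f"rho={config.rho} outside the admissible interval "
                f"({lo:.4f}, {hi:.4f}) for the generated weight matrix"
            )
        A = sp.identity(m, format="csc") - config.rho * W.W.tocsc()
        theta = sp.linalg.spsolve(A, mu)
    else:
        if config.rho != 0:
            raise ValueError("rho must be 0 for a single-region landscape")
        theta = mu

    # latent rents and the probit outcome
    eta = np.full(shape, 0.0)
    eta += config.alpha * tc.values
    eta += config.beta["const"]
    for name in config.covariate_names():
        eta += config.beta[name] * covariates[name].values
    theta_cell = np.zeros(shape)
    inside = partition.region_id_per_cell >= 0
    theta_cell[inside] = theta[partition.region_id_per_cell[inside]]
    e = rng_e.standard_normal(shape)
    latent_vals = eta + theta_cell + e
    latent = base.like(np.where(valid, latent_vals, 0.0))
    outcome = base.like((valid & (latent_vals > 0)).astype(float))

    carbon_field = _smooth_field(shape, rng_carbon)
    c01 = (carbon_field - carbon_field.min()) / np.ptp(carbon_field)
    lo_c, hi_c = config.carbon_range
    carbon = base.like(lo_c + c01 * (hi_c - lo_c))

    return SyntheticLandscape(
        covariates=covariates,
        outcome=outcome,
        latent=latent,
        theta_true=theta,
        roads_mask=roads_grid,
        markets_mask=markets_grid,
        friction_class=friction_class,
        carbon=carbon,
        partition=partition,
        truth=config,
    )


def generate_road_scenario(
    landscape: SyntheticLandscape, n_segments: int, seed: int
) -> RasterGrid:
    """Union of the existing roads mask and random new straight segments."""
    if n_segments < 0:
        raise ValueError("n_segments must be >= 0")
    rng = np.random.default_rng(seed)
    base = landscape.roads_mask
    merged = base.values.astype(bool).copy()
    new = _rasterize_lines(base.shape, n_segments, rng)
    merged |= new & base.mask
    return base.like(merged.astype(float))
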