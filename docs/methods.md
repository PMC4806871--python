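# Methods

## Model

The analysis treats deforestation as a threshold-crossing of a latent
rent difference. For cell *i* in region *j*:

    y*_ij = α TC_ij + x_ij'β + θ_j + e_ij,   e_ij ~ N(0,1)  i.i.d.
    y_ij  = 1[y*_ij > 0]

The idiosyncratic error variance is fixed at 1: a probit is identified
only up to scale, and fixing Var(e) = 1 makes coefficients and average
partial effects comparable across specifications. The regional effects
follow a simultaneous autoregressive process over the m×m row-normalized
region weight matrix W,

    θ = ρ W θ + μ,   μ ~ N(0, σ² I_m)   ⇒   θ ~ N(0, σ²[(I−ρW)'(I−ρW)]⁻¹),

which is proper for ρ strictly inside (1/λ_min, 1/λ_max), the reciprocal
extreme real eigenvalues of W (the upper bound is 1 for a row-stochastic
W). Regions are square blocks of cells (default 5×5); blocks at the
raster border or containing nodata hold fewer cells, and blocks with no
valid cell are dropped. Two weight kinds are implemented: rook contiguity
on the block lattice (surviving N/S/E/W neighbours, equally weighted) and
inverse centroid distance to the k = 24 nearest regions. Distances
between regions use block-lattice units; only ratios survive row
normalization, so the metric choice is immaterial.

## Estimation

**Non-spatial probit.** Newton–Raphson on the analytic gradient and
observed information, with step-halving; convergence at gradient
max-norm < 1e-8 or relative log-likelihood change < 1e-12. Coefficients
exceeding 50 in magnitude while the likelihood still improves are
reported as perfect separation. Huber–White standard errors use the
sandwich A⁻¹BA⁻¹ with A the observed information and B the outer product
of per-observation scores. Average partial effects follow the
level-plus-quadratic formula for continuous covariates (the quadratic
pairing is an explicit column map, not an automatic expansion) and the
discrete difference for binary ones; delta-method APE standard errors
are not implemented.

**Spatial probit.** Gibbs sampling with data augmentation, one sweep per
iteration:

1. latent y* from its truncated-normal conditional. Draws use the
   inverse-CDF through the survival function,
   `x = m − ndtri_exp(log u + log Φ(m))` for the (0,∞) branch, which is
   tail-safe at means of ±40 where naive `Φ⁻¹` evaluation overflows;
2. β from its Gaussian conditional with diffuse N(0, c⁻¹I) prior
   (c = 1e-8); the posterior precision X'X + cI is factored once;
3. each θ_j from a univariate normal combining its n_j unit-variance
   observations with the SAR prior precision B = (I−ρW)'(I−ρW)/σ²,
   updated as a systematic scan in label order. A region whose rook
   neighbours were all dropped has a zero W row, so B gives it the
   exchangeable N(0, σ²) prior automatically;
4. σ² from its inverse-gamma conditional. The default prior is the
   scale-invariant p(σ²) ∝ 1/σ² (shape = scale = 0), overridable in
   `MCMCSettings`;
5. ρ by griddy Gibbs: the conditional log-density
   ln|I−ρW| − θ'(I−ρW)'(I−ρW)θ/(2σ²) is evaluated on a 201-point grid
   spanning the open admissible interval (log-determinants precomputed
   by sparse LU, quadratic form expanded once per sweep), normalized by
   log-sum-exp, and a grid point drawn by inverse CDF. This makes the
   ρ update deterministic given the uniform draw, which simplifies
   testing relative to a Metropolis step.

Defaults are 500 burn-in and 500 retained draws with no thinning; point
estimates are means of the retained draws and reported standard errors
their standard deviations. Convergence is asserted by the fixed burn-in;
a split-half diagnostic (difference of the two half-chain ρ means in
posterior-SD units) is recorded in the posterior object but not
enforced. In-sample fitted probabilities use Φ(x'β̄ + θ̄_j); scenario
(out-of-sample) surfaces use the smoothed form Φ(x*'β̄ + ρ̄ Σ_k w_jk θ̄_k),
and both are exposed.

## Cost distance

The market-access covariate is the accumulated least cost from each cell
to its cheapest market over the friction surface (currency per meter by
transport class; the default table spans river classes at 1.03e-5 to
7.5e-5, roads at 1e-4 to 3e-4, and unimproved forest at 2e-3 per meter).
Costs accumulate on the 8-connected lattice with edge cost
((f_a+f_b)/2)·L, L = resolution for rook steps and resolution·√2 for
diagonals, matching standard GIS cost-distance semantics. Nodata cells
are removed from the graph, so voids block routes. The multi-source run
(a virtual source over all market cells) equals the cell-wise minimum of
per-market runs, which is verified rather than assumed. Euclidean
distance covariates use an exact distance transform and are not blocked
by nodata.

## Evaluation

The predicted-change map thresholds the probability surface at the p*
that makes the predicted count equal the observed count; ties at p* are
broken by ascending row-major index so the count is always exact. The
fuzzy two-way statistic credits near misses: each cell's directional
similarity to a map is the largest kernel weight 2^(−d/2) over that
map's changed cells within the window (d in cell units; a 5×5 window
caps d at 2√2), the per-cell value is the minimum of the two directions,
and the global statistic averages over cells predicted changed in the
first map. The combination rule (min of directions) and the averaging
population are reconstructions of the usual two-way definition; a
union-population variant is available behind a flag.

## Scenarios and carbon

Planned road segments are merged into the current network and every
road-derived distance column is recomputed from the merged mask (paired
quadratic columns re-squared). Stochastic landscapes use the strict rule
"deforested iff p > u" with one independent uniform per unmasked cell,
so cells with p = 0 never deforest; already-deforested (masked) cells
are excluded throughout. Emissions per realization sum the carbon of
deforested cells, assuming full release; carbon is stored as tons per
cell.

## Synthetic landscapes

The generator emulates the statistical structure the analysis assumes:
a nodata mask drawn as smooth random blobs (so border regions with
partial cell counts are exercised), straight-line road and river
features, friction classes assigned by feature type, markets placed on
the river network (fluvial access dominates, which keeps market-access
cost from being collinear with road distance), a road-distance covariate
(the scenario channel) plus smooth and binary covariates from
low-frequency Gaussian random fields, regional effects from an exact
sparse solve of (I−ρW)θ = μ, and a smooth carbon surface scaled to
2,000–8,000 t per cell — a range whose mean matches meso-scale Amazonian
aboveground stocks at an 81-ha cell. Each stochastic substep draws from
an independently spawned substream of the master seed, so adding a
covariate does not perturb θ. Defaults: 50×50 cells of 900 m, block 5
(m = 100 regions), ρ = 0.5, σ² = 1, α = −0.02 per currency unit,
β = (0.3, −0.4, 0.3, 0.5) for intercept, road distance (units of 10 km),
smooth field, and binary indicator.

What the generator does *not* emulate: real covariate marginals or their
joint distribution, river-network topology, anisotropic travel,
multi-year dynamics, or geographic projections. Passing tests therefore
demonstrate the correctness and internal consistency of the machinery
and its ability to recover known parameters under the assumed data-
generating process — not fidelity to any particular real landscape.

## Problem sizes and numerical choices

Parameter-recovery checks run 20 replicate 50×50 landscapes with the
full 500+500 sampler; 95% posterior intervals for ρ and each coefficient
are required to cover truth in at least 17 of 20, and the mean
posterior-mean ρ to sit within 0.1 of truth. Interval coverage of
individual coefficients fluctuates a few replicates around the nominal
19/20 across seed batches — hierarchical-posterior intervals are not
exact frequentist intervals at m = 100 regions. The end-to-end scenario
check uses a 100×100 landscape with five road lines, where the planted
negative road-distance effect is estimated with a stable sign; at 50×50
a single smooth covariate competes with regional noise of similar
magnitude and its fitted sign can flip. The log-determinant grid is
validated against dense `slogdet` up to m ≈ 200; the sampler's grid uses
201 points with a relative margin of 1e-4 inside the open admissible
interval. Degenerate inputs are rejected rather than repaired: all-nodata
partitions, single-region weight requests, inadmissible ρ, empty source
or feature masks, non-binary outcomes, and probabilities outside [0,1].

## Known limitations

Individual-cell-level dependence (block = 1) works mechanically but is
untested at scale; APE standard errors are absent; the sampler's θ scan
is a Python loop over regions, adequate to m of a few thousand but not
beyond; ESRI ASCII is the only raster format, and grids are planar with
constant resolution (no CRS handling).
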