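# selva

Raster-based land-change analysis with a hierarchical Bayesian spatial
probit: synthetic Amazonian-style landscapes, friction-weighted market
access, non-spatial and regional spatial probit estimation, count-matched
and fuzzy map evaluation, and stochastic road-construction scenarios with
carbon-emission accounting.

## The problem

Deforestation models on large raster grids usually ignore spatial
dependence, because a cell-level spatial weight matrix for hundreds of
thousands of cells is computationally out of reach. The model implemented
here assigns dependence between *regions* — square blocks of cells —
instead of individual cells: a full 15×15 raster needs only a 9×9 region
weight matrix instead of a 225×225 cell matrix. For cell *i* in region *j*,

    y*_ij = α·TC_ij + x_ij'β + θ_j + e_ij,      e_ij ~ N(0, 1)
    y_ij  = 1[y*_ij > 0]
    θ_j   = ρ Σ_k w_jk θ_k + μ_j,               μ_j ~ N(0, σ²)

where `y*` is the latent rent difference between cleared and forested
land, `TC` the accumulated transport cost to the nearest market (Dijkstra
least cost over a per-meter friction surface, minimum over markets),
`x` the covariates, `θ_j` a regional effect following a spatial
autoregressive (SAR) process over the row-normalized region weight
matrix `W`, and `ρ` the spatial-dependence parameter. Estimation is by
Gibbs sampling with truncated-normal data augmentation; `ρ` is drawn by
griddy Gibbs over a precomputed `ln|I − ρW|` grid. Point estimates are
means of the retained draws (default 500 after 500 burn-in) and reported
standard errors their standard deviations.

Model fit is judged the way land-change modellers do: threshold the
probability surface at the `p*` that matches the observed change count,
cross-tabulate hits/omissions/commissions, and score near-miss agreement
with the two-way fuzzy similarity (5×5 window, weight `2^(−d/2)`). Road
scenarios merge planned segments into the network, recompute the
road-derived covariates, and propagate the new probability surfaces into
ensembles of stochastic deforestation landscapes (cell deforested iff
`p > u`, `u ~ U(0,1)`) whose realizations are intersected with an
aboveground-carbon surface.

Because the original GIS layers are not redistributable, a synthetic
landscape generator with known `α, β, ρ, σ²`, friction classes and a
smooth carbon surface stands in for them, so every stage is testable and
parameter recovery verifiable.

## Worked example

The numbered scripts under `analysis/` run the full study on the default
synthetic landscape (50×50 cells of 900 m, 100 regions, ρ = 0.5, σ² = 1):

```sh
python analysis/01_generate_landscape.py   # landscape + truth sidecar
python analysis/03_fit_nonspatial_probit.py
python analysis/04_fit_spatial_probit.py
python analysis/05_evaluate_allocation.py
python analysis/06_road_scenarios.py
```

At the default seed this prints (abridged):

```
04: rook4: rho = 0.642 (0.101), 95% CI [0.440, 0.820]  (truth 0.5)
05: nsp: p* = 0.4624, hit fraction = 61%, fuzzy two-way = 0.8595
    sls: p* = 0.4639, hit fraction = 81%, fuzzy two-way = 0.945
06: nsp: mean 1213.6 deforested cells [1146, 1285], mean emissions 6.58e+06 t C
    sls: mean 1041.3 deforested cells [973, 1114], mean emissions 5.62e+06 t C
```

The posterior for ρ covers the true dependence; the spatial model
allocates the observed amount of deforestation far better than the
non-spatial fit (81% vs 61% of changed cells hit, fuzzy similarity 0.95
vs 0.86) because its fitted surface carries the regional block structure
— the same qualitative gap that motivates regional spatial probits on
real deforestation rasters. The scenario ensembles quantify how many
cells the planned roads tip into deforestation and the carbon released
if they are cleared.

A `selva` command-line tool exposes the same stages
(`selva synth|partition|costdist|fit-nsp|fit-sls|evaluate|simulate|run`).

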