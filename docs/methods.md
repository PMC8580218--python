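# Methods

## Model

The package estimates how much wastewater-derived nitrogen (N) and how much
of a pathogen proxy (fecal indicator organisms, FIO) reach coastal waters,
and where. It is a source-to-sea chain of five deterministic stages operating
on a shared raster grid (square cells, edge `cell_km`, default 1 km):

1. **Effluent.** Per-cell annual N by disposal category:

   `N_t = pop × protein × 0.16 × f_t × (1 − r_t)`, t ∈ {direct, septic, sewered}

   where `pop` is persons per cell, `protein` the national protein
   consumption (g person⁻¹ yr⁻¹), 0.16 the fraction of ingested protein
   excreted as N, `f_t` the population share using disposal category t (by
   country and urban/rural settlement class), and `r_t` the category's N
   removal efficiency — 0.55 for sewered treatment, 0.80 for septic
   (soil/drain-field uptake), 0 for open defecation. `c_t = f_t(1 − r_t)` is
   the *production coefficient*: the inverse of removal efficiency. The FIO
   proxy is `pop × Σ_t f_t w_t` with unitless per-category emission weights
   `w`; no per-person FIO production values are published, so the defaults
   (1.0 / 0.5 / 0.05 for direct / septic / sewered) are explicitly
   placeholder weights ordered by treatment intensity and are configurable.
   Septic and direct contributions (N and FIO) are zeroed on cells whose
   centre lies strictly more than 1 km (Euclidean, configurable) from
   surface water or the coast — such inputs soak into the landscape rather
   than reaching a waterway. Sewered effluent is piped and unaffected. A
   config switch (`proximity_sources`) can restrict the rule to septic only.

2. **Watersheds.** D8 steepest-descent routing over land: each cell drains
   to the 8-neighbour with the greatest elevation drop, diagonal drops
   divided by √2, ties broken in fixed E, SE, S, SW, W, NW, N, NE order. A
   cell with no strictly lower land neighbour is terminal; the cells sharing
   a terminal form a basin. Terminals touching the ocean are coastal
   pourpoints; interior terminals mark endorheic basins, excluded from
   marine totals. Effluent rasters are summed per basin and attributed to
   pourpoints; national discharge sums pourpoints per country, crediting a
   transboundary basin wholly to the pourpoint's country. A precomputed
   basin raster + pourpoint table can be supplied instead of a DEM.

3. **Plume.** Each retained pourpoint's load spreads over 8-connected ocean
   cells along shortest over-water step paths (wrapping around islands and
   headlands; no advection): `value = load × (1 − d)^steps` with per-cell
   loss `d = 0.005` (retain 99.5%). Cells whose total-N value falls below
   0.05% of the largest retained pourpoint load are truncated to zero, and
   pourpoints with total N < 1 g are dropped before pluming. Overlapping
   plumes add; all source fields of one plume share the total-N truncation
   mask, so per-cell source additivity is preserved. "0.5% of the value in
   the previous cell" is read as 0.5% *lost* per step; the opposite reading
   (retain 0.5%) would extinguish any plume within two cells and is
   reachable by setting `decay_per_cell = 0.995`.

4. **Habitat exposure.** Habitat features are rasterised centre-overlap at
   half-size cells, then a model cell is habitat if any fine subcell is —
   slivers missing every fine-cell centre vanish. Exposure is the plume
   value on habitat cells; a cell is dominated by untreated inputs when
   `n_direct + n_septic > n_sewered` (ties → sewered, deterministic);
   hotspots are habitat cells at or above the 97.5th quantile of total-N
   exposure across the whole habitat.

5. **Reports.** Across watersheds with positive N and FIO, log10(N) is
   regressed on log10(FIO) (OLS); residuals are z-scored and |z| > 2
   labels a watershed high_N / low_N (disproportionate nitrogen given its
   pathogen load). Concentration tables sort watersheds by load and report
   top-k shares of the global total.

## Imputation cascade

National sanitation statistics are incomplete in practice, so the factor
stage fills gaps with tagged provenance: missing urban/rural strata take the
national row; wholly missing countries take per-category medians of observed
same-region, same-stratum values, renormalised to sum to 1 (medians of
compositions need not); missing protein takes the prediction of
`protein ~ α + β·ln(GDP per capita)` fit on complete cases (the standard
Engel-curve form; ≥ 3 complete cases required) where GDP is known, else the
regional median; missing FIO factors take a random-forest prediction from
population size and rural share, tuned over a small seeded grid
(trees ∈ {100, 500}, depth ∈ {∞, 8}) by 10-fold CV with a 70/30 holdout
RMSE reported, else the regional median. Every imputed value is written to
an audit log (country, field, rule). The published description lists the
national FIO factor among the forest's predictors; since that is the
prediction target itself, the implementation uses the two genuine
covariates.

## Quantile convention

Hotspot thresholds use a nearest-rank rule: the threshold is the smallest
sample value with at least the quantile's share of the sample strictly below
it (`sorted[min(ceil(q·n), n−1)]`, 0-based). On 1,000 distinct exposures and
q = 0.975 this flags exactly the top 25 cells. On a constant sample
(including all-zero exposure) the threshold equals that constant and every
habitat cell is flagged — documented degenerate behaviour. Whether
zero-exposure cells belong in the quantile domain is genuinely ambiguous;
the default includes them ("across the entire range of the habitat"), and
`HotspotRule(include_unexposed=False)` restricts to exposed cells.

## Synthetic worlds

`synth.generate_world` builds the test geography: blobby islands with a
1-cell ocean border; a DEM equal to the chessboard distance-to-coast ramp
plus smooth noise of amplitude 0.4 (< 0.5, which guarantees every land cell
has a strictly descending 8-neighbour path to the coast — verified by a
brute-force tracing test); optional carved interior sinks; Voronoi country
labels; population allocated by a single multinomial draw over a mixture of
log-normal-mass Gaussian settlement kernels (so the raster sums exactly to
the configured total); urban cells are the densest cells holding the
configured urban population share; rivers traced down the DEM form the
surface-water mask. Default condition choices: 100 k people on a 64×64
grid, 50% urban, protein generated as `3000 + 2800·ln(GDP)` g yr⁻¹ plus
N(0, 1500) noise with log-normal GDP (median ≈ 8 k) — putting protein in
the realistic 15–40 kg yr⁻¹ range; urban sanitation mixes lean sewered and
rural mixes lean direct/septic (Dirichlet draws). Missingness is injected
by dropping whole strata or whole countries from the observable tables
while a ground-truth copy is retained, enabling recovery tests.

What the generator does *not* emulate: real coastline geometry and
bathymetry, census-based population placement, the multi-level settlement
continuum (settlement class is binary urban/rural), nested sub-basins,
seasonal hydrology, and any correlation between sanitation access and GDP.
Passing tests therefore demonstrate correctness of the model mechanics and
the statistical machinery, not calibration against real-world totals —
reproducing published global numbers requires the original global rasters.

## Numerical choices

- DEM units are arbitrary; only elevation ordering matters for routing.
- Basin terminal resolution uses pointer doubling (O(cells · log path)).
- Plume breadth-first search stops at the step count where the decayed value
  must fall below the truncation threshold, bounding work per pourpoint.
- Pourpoints on land are snapped to the first adjacent ocean cell in the
  fixed neighbour order.
- The N-vs-FIO residual standard deviation is treated as zero (no outliers)
  when it is at rounding-noise level (≤ 1e-12 of the log-load scale),
  so exactly proportional loads classify as proportional.
- Treatment-mix rows are renormalised to sum to 1; a warning and an audit
  row are emitted when the raw sum deviates by more than 0.01.
- Log-log fits exclude nonpositive loads rather than adding a pseudo-count;
  zero-input watersheds are labelled proportional.

## Problem sizes

The test suite runs worlds of 32–64 cells per side (one 128×128 world for
the stage-to-stage conservation check), 200 random ≤ 12×12 DEMs against the
brute-force flow oracle, and 100 random ≤ 20×20 ocean masks against a BFS
oracle; these sizes exercise every code path while keeping the default
suite fast on a laptop.

## Known limitations

No in-stream N retention or decay during overland transport; no nearshore
advection, currents or residence time; no treatment-plant-level
(primary/secondary/tertiary) heterogeneity — a uniform sewered removal rate
is used; FIO is a unitless population-correlated index, not organism
counts; FIO pluming is off by default (exposure mapping is N-based).
Phosphorus and other wastewater pollutants are out of scope.
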