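"""Synthetic-world generation.

Builds internally consistent miniature planets — population and settlement
rasters, a drainable elevation model, country labels, sanitation-access and
protein/GDP tables with controllable missingness, surface-water lines and
ocean habitat patches — carrying the statistical structure the wastewater
model assumes, so the full pipeline can be exercised without any external
download.

Every stochastic choice is driven by a single :class:`numpy.random.Generator`
seeded from ``WorldConfig.rng_seed``; identical configs therefore produce
bit-identical worlds.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Point, mapping

from .rasters import write_ascii_grid

# Settlement-class codes. The settlement raster is defined exactly where
# population > 0: uninhabited cells (including ocean) carry 0.
UNINHABITED, RURAL, URBAN = 0, 1, 2

# D8 neighbour offsets in the fixed tie-break order used everywhere in the
# package: E, SE, S, SW, W, NW, N, NE.
D8_OFFSETS = ((0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1))


@dataclass
class WorldConfig:
    """Parameters of a synthetic world.

    Fractions are proportions in [0, 1]. ``dem_noise`` is the amplitude of
    the smooth noise added to the distance-to-coast ramp, in ramp units per
    cell; values below 0.5 guarantee a strictly descending path to the coast
    from every land cell (sink-free mode).
    """

    grid_rows: int = 64
    grid_cols: int = 64
    cell_km: float = 1.0
    n_countries: int = 4
    n_islands: int = 1
    population_total: int = 100_000
    urban_fraction: float = 0.5
    n_settlement_centers: int = 0  # 0 -> 3 per country
    n_rivers: int = 0  # 0 -> one per country
    n_sinks: int = 0  # interior endorheic sinks carved into the DEM
    dem_noise: float = 0.4
    sanitation_strata_missing: float = 0.0
    sanitation_country_missing: float = 0.0
    protein_missing: float = 0.0
    gdp_missing: float = 0.0  # applied among protein-missing countries
    protein_noise_sd: float = 1500.0
    n_habitat_patches: int = 12
    rng_seed: int = 0

    def validate(self) -> None:
        if self.grid_rows < 8 or self.grid_cols < 8:
            raise ValueError("grid must be at least 8x8")
        if self.cell_km <= 0:
            raise ValueError("cell_km must be positive")
        if self.population_total < 0:
            raise ValueError("population_total must be >= 0")
        if self.n_countries < 1 or self.n_islands < 1:
            raise ValueError("need at least one country and one island")
        for name in (
            "urban_fraction",
            "sanitation_strata_missing",
            "sanitation_country_missing",
            "protein_missing",
            "gdp_missing",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class SyntheticWorld:
    """A generated world: co-registered rasters plus country-level tables."""

    config: WorldConfig
    population: np.ndarray  # persons per cell (int64)
    settlement: np.ndarray  # uint8: 0 uninhabited, 1 rural, 2 urban
    land: np.ndarray  # bool
    dem: np.ndarray  # float, arbitrary units; 0 on ocean
    surface_water: np.ndarray  # bool, inland surface water
    country: np.ndarray  # int32 country id per land cell, -1 elsewhere
    countries: list  # country ids present
    regions: pd.DataFrame  # columns: country, region
    sanitation: pd.DataFrame  # observable view
    sanitation_truth: pd.DataFrame  # complete ground truth
    protein_gdp: pd.DataFrame  # observable view
    protein_gdp_truth: pd.DataFrame
    habitats: dict = field(default_factory=dict)  # kind -> list of shapely geoms

    @property
    def ocean(self) -> np.ndarray:
        return ~self.land

    @property
    def cell_km(self) -> float:
        return self.config.cell_km


def _smooth_noise(rng, shape, sigma=2.0, amplitude=0.4):
    """Smooth random field scaled to max |value| = amplitude."""
    raw = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    peak = np.abs(raw).max()
    if peak == 0:
        return raw
    return raw * (amplitude / peak)


def _make_land(rng, rows, cols, n_islands):
    """Union of blobby islands; the outer 1-cell border is always ocean."""
    yy, xx = np.mgrid[0:rows, 0:cols]
    land = np.zeros((rows, cols), dtype=bool)
    base_r = max(2.5, 0.55 * min(rows, cols) / (1.0 + math.sqrt(n_islands)))
    for _ in range(n_islands):
        cy = rng.uniform(0.25 * rows, 0.75 * rows)
        cx = rng.uniform(0.25 * cols, 0.75 * cols)
        r0 = base_r * rng.uniform(0.8, 1.25)
        # radial harmonics give a wiggly coastline with headlands
        amps = rng.uniform(-0.22, 0.22, size=3)
        phases = rng.uniform(0, 2 * math.pi, size=3)
        theta = np.arctan2(yy - cy, xx - cx)
        r = r0 * (
            1.0
            + sum(a * np.cos((k + 1) * theta + p) for k, (a, p) in enumerate(zip(amps, phases)))
        )
        land |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    land[0, :] = land[-1, :] = False
    land[:, 0] = land[:, -1] = False
    if not land.any():
        raise ValueError("generated world has no land; increase the grid size")
    return land


def _make_dem(rng, land, noise_amp, n_sinks):
    """Distance-to-coast ramp plus smooth noise; optional carved sinks."""
    # chessboard distance: every land cell at ramp d has an 8-neighbour at d-1
    dist = ndimage.distance_transform_cdt(land, metric="chessboard").astype(float)
    dem = np.where(land, dist + _smooth_noise(rng, land.shape, amplitude=noise_amp), 0.0)
    if n_sinks:
        interior = np.argwhere(dist >= 3)
        if len(interior):
            picks = interior[rng.choice(len(interior), size=min(n_sinks, len(interior)), replace=False)]
            for r, c in picks:
                neigh = dem[max(r - 1, 0) : r + 2, max(c - 1, 0) : c + 2]
                dem[r, c] = neigh.min() - 1.0
    return dem


def _label_countries(rng, land, n_countries):
    """Voronoi partition of land cells around random seed cells."""
    from scipy.spatial import cKDTree

    land_cells = np.argwhere(land)
    n_countries = min(n_countries, len(land_cells))
    seed_idx = rng.choice(len(land_cells), size=n_countries, replace=False)
    seeds = land_cells[np.sort(seed_idx)]
    tree = cKDTree(seeds)
    _, owner = tree.query(land_cells)
    country = np.full(land.shape, -1, dtype=np.int32)
    country[land_cells[:, 0], land_cells[:, 1]] = owner.astype(np.int32)
    return country, list(range(n_countries))


def _allocate_population(rng, land, total, n_centers):
    """Log-normal clustered allocation: multinomial draw over a mixture of
    Gaussian settlement kernels, so the raster sums exactly to ``total``."""
    pop = np.zeros(land.shape, dtype=np.int64)
    if total <= 0:
        return pop
    land_cells = np.argwhere(land)
    n_centers = max(1, min(n_centers, len(land_cells)))
    centers = land_cells[rng.choice(len(land_cells), size=n_centers, replace=False)]
    masses = rng.lognormal(mean=0.0, sigma=1.0, size=n_centers)
    sigmas = rng.uniform(1.5, 4.0, size=n_centers)
    d2 = (
        (land_cells[:, None, 0] - centers[None, :, 0]) ** 2
        + (land_cells[:, None, 1] - centers[None, :, 1]) ** 2
    ).astype(float)
    w = (masses[None, :] * np.exp(-d2 / (2.0 * sigmas[None, :] ** 2))).sum(axis=1)
    w += 1e-9  # every land cell is reachable, avoids zero-probability rows
    counts = rng.multinomial(int(total), w / w.sum())
    pop[land_cells[:, 0], land_cells[:, 1]] = counts
    return pop


def _classify_settlement(population, urban_fraction):
    """Urban = densest cells holding ``urban_fraction`` of people; the rest
    of the inhabited cells are rural."""
    settlement = np.zeros(population.shape, dtype=np.uint8)
    inhabited = population > 0
    settlement[inhabited] = RURAL
    total = population.sum()
    if total == 0 or urban_fraction <= 0:
        return settlement
    idx = np.argwhere(inhabited)
    vals = population[inhabited]
    order = np.argsort(vals, kind="stable")[::-1]
    cum = np.cumsum(vals[order])
    k = int(np.searchsorted(cum, urban_fraction * total) + 1)
    chosen = idx[order[:k]]
    settlement[chosen[:, 0], chosen[:, 1]] = URBAN
    return settlement


def _steepest_descent_path(dem, land, start):
    """Follow the package's D8 rule from ``start`` until a terminal cell."""
    rows, cols = dem.shape
    path = [start]
    r, c = start
    while True:
        best_drop, best = 0.0, None
        for dr, dc in D8_OFFSETS:
            nr, nc = r + dr, c + dc
            if not (0 <= nr < rows and 0 <= nc < cols) or not land[nr, nc]:
                continue
            w = math.sqrt(2.0) if dr and dc else 1.0
            drop = (dem[r, c] - dem[nr, nc]) / w
            if drop > best_drop:
                best_drop, best = drop, (nr, nc)
        if best is None:
            return path
        path.append(best)
        r, c = best


def _make_rivers(rng, dem, land, n_rivers):
    water = np.zeros(land.shape, dtype=bool)
    land_cells = np.argwhere(land)
    if not len(land_cells) or n_rivers <= 0:
        return water
    # rivers start high (far inland) and run down the DEM to the coast
    dist = ndimage.distance_transform_cdt(land, metric="chessboard")
    high = land_cells[dist[land_cells[:, 0], land_cells[:, 1]] >= max(2, dist.max() - 1)]
    if not len(high):
        high = land_cells
    starts = high[rng.choice(len(high), size=min(n_rivers, len(high)), replace=False)]
    for r, c in starts:
        for rr, cc in _steepest_descent_path(dem, land, (int(r), int(c))):
            water[rr, cc] = True
    return water


def generate_sanitation_table(config: WorldConfig, countries, rng=None, urban_pop_share=None):
    """Per country x {urban, rural, national} treatment-mix fractions.

    Returns ``(observable, truth)`` DataFrames with columns
    ``country, strata, f_direct, f_septic, f_sewered``. Missingness removes
    whole strata (urban+rural) or whole countries from the observable view
    only; the truth table always carries every row.
    """
    if not len(countries):
        raise ValueError("countries must be non-empty")
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 1)
    rows = []
    for country in countries:
        # urban mixes lean sewered, rural mixes lean direct/septic
        urban = rng.dirichlet((1.0, 1.5, 3.5))
        rural = rng.dirichlet((2.5, 2.5, 1.0))
        share = 0.5 if urban_pop_share is None else float(urban_pop_share.get(country, 0.5))
        national = share * urban + (1.0 - share) * rural
        for strata, mix in (("urban", urban), ("rural", rural), ("national", national)):
            rows.append(
                {
                    "country": country,
                    "strata": strata,
                    "f_direct": mix[0],
                    "f_septic": mix[1],
                    "f_sewered": mix[2],
                }
            )
    truth = pd.DataFrame(rows)
    drop_strata = rng.random(len(countries)) < config.sanitation_strata_missing
    drop_country = rng.random(len(countries)) < config.sanitation_country_missing
    keep = []
    for i, country in enumerate(countries):
        for _, row in truth[truth.country == country].iterrows():
            if drop_country[i]:
                continue
            if drop_strata[i] and row["strata"] != "national":
                continue
            keep.append(row)
    observable = pd.DataFrame(keep, columns=truth.columns).reset_index(drop=True)
    return observable, truth


# Protein consumption rises roughly linearly in log GDP per capita
# (Engel-curve shape); these coefficients put protein in the observed
# worldwide range of ~15-40 kg per person per year.
PROTEIN_ALPHA = 3000.0
PROTEIN_BETA = 2800.0


def protein_from_gdp(gdp_per_capita):
    """Deterministic core of the synthetic protein generator (g yr^-1)."""
    return PROTEIN_ALPHA + PROTEIN_BETA * np.log(gdp_per_capita)


def generate_protein_gdp_table(config: WorldConfig, countries, rng=None):
    """Per-country protein (g person^-1 yr^-1) and GDP per capita.

    Protein is a noisy increasing function of log GDP so the downstream
    regression imputation has recoverable signal. Returns
    ``(observable, truth)``; in the observable view protein is masked for a
    ``protein_missing`` share of countries and GDP additionally masked for a
    ``gdp_missing`` share of those.
    """
    if not len(countries):
        raise ValueError("countries must be non-empty")
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 2)
    gdp = rng.lognormal(mean=9.0, sigma=1.1, size=len(countries))
    protein = protein_from_gdp(gdp)
    if config.protein_noise_sd > 0:
        protein = protein + rng.normal(0.0, config.protein_noise_sd, size=len(countries))
    protein = np.clip(protein, 5000.0, None)
    truth = pd.DataFrame(
        {"country": list(countries), "protein": protein, "gdp": gdp, "uninhabited": False}
    )
    observable = truth.copy()
    miss_protein = rng.random(len(countries)) < config.protein_missing
    miss_gdp = miss_protein & (rng.random(len(countries)) < config.gdp_missing)
    observable.loc[miss_protein, "protein"] = np.nan
    observable.loc[miss_gdp, "gdp"] = np.nan
    return observable, truth


def generate_habitat_layer(world: SyntheticWorld, habitat_kind: str, n_patches: int, seed: int):
    """Place habitat features (points and small polygons) over ocean cells.

    Features sit at sub-cell precision near the coast so the centre-overlap
    rasterisation rule is genuinely exercised. Raises if the world has no
    ocean.
    """
    ocean = world.ocean
    if not ocean.any():
        raise ValueError("world has no ocean; cannot place marine habitat")
    rng = np.random.default_rng(seed)
    cell = world.cell_km
    nrows = ocean.shape[0]
    # prefer nearshore ocean (where plumes actually reach)
    shore_dist = ndimage.distance_transform_cdt(ocean, metric="chessboard")
    near = np.argwhere(ocean & (shore_dist <= 6))
    if not len(near):
        near = np.argwhere(ocean)
    feats = []
    for _ in range(n_patches):
        r, c = near[rng.integers(len(near))]
        x = (c + rng.uniform(0.05, 0.95)) * cell
        y = (nrows - r - rng.uniform(0.05, 0.95)) * cell
        if rng.random() < 0.25:
            feats.append(Point(x, y))
        else:
            radius = rng.uniform(0.2, 1.1) * cell
            feats.append(Point(x, y).buffer(radius, quad_segs=8))
    return feats


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate a full synthetic world from ``config`` (deterministic in
    ``config.rng_seed``)."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    land = _make_land(rng, config.grid_rows, config.grid_cols, config.n_islands)
    dem = _make_dem(rng, land, config.dem_noise, config.n_sinks)
    country, countries = _label_countries(rng, land, config.n_countries)
    n_centers = config.n_settlement_centers or 3 * len(countries)
    population = _allocate_population(rng, land, config.population_total, n_centers)
    settlement = _classify_settlement(population, config.urban_fraction)
    n_rivers = config.n_rivers or len(countries)
    surface_water = _make_rivers(rng, dem, land, n_rivers)

    # region membership: ~4 countries per geopolitical region
    n_regions = max(1, math.ceil(len(countries) / 4))
    region_of = rng.integers(0, n_regions, size=len(countries))
    regions = pd.DataFrame(
        {"country": countries, "region": [f"R{r}" for r in region_of]}
    )

    # country-level urban population share feeds the national sanitation row
    urban_pop_share = {}
    for cid in countries:
        in_c = country == cid
        tot = population[in_c].sum()
        urb = population[in_c & (settlement == URBAN)].sum()
        urban_pop_share[cid] = float(urb / tot) if tot > 0 else 0.5

    sanitation, sanitation_truth = generate_sanitation_table(
        config, countries, rng=rng, urban_pop_share=urban_pop_share
    )
    protein_gdp, protein_gdp_truth = generate_protein_gdp_table(config, countries, rng=rng)
    pop_by_country = {
        cid: int(population[country == cid].sum()) for cid in countries
    }
    for df in (protein_gdp, protein_gdp_truth):
        df["uninhabited"] = df["country"].map(lambda c: pop_by_country.get(c, 0) == 0)

    world = SyntheticWorld(
        config=config,
        population=population,
        settlement=settlement,
        land=land,
        dem=dem,
        surface_water=surface_water,
        country=country,
        countries=countries,
        regions=regions,
        sanitation=sanitation,
        sanitation_truth=sanitation_truth,
        protein_gdp=protein_gdp,
        protein_gdp_truth=protein_gdp_truth,
    )
    if config.n_habitat_patches > 0 and world.ocean.any():
        half = config.n_habitat_patches // 2
        world.habitats["coral"] = generate_habitat_layer(
            world, "coral", config.n_habitat_patches - half, seed=config.rng_seed + 11
        )
        world.habitats["seagrass"] = generate_habitat_layer(
            world, "seagrass", half, seed=config.rng_seed + 12
        )
    return world


def write_world(world: SyntheticWorld, outdir) -> None:
    """Write a world directory: .asc rasters, CSV tables, GeoJSON habitats."""
    os.makedirs(outdir, exist_ok=True)
    cell = world.cell_km
    write_ascii_grid(os.path.join(outdir, "population.asc"), world.population, cell)
    write_ascii_grid(os.path.join(outdir, "settlement.asc"), world.settlement, cell)
    write_ascii_grid(os.path.join(outdir, "land.asc"), world.land.astype(np.uint8), cell)
    write_ascii_grid(os.path.join(outdir, "dem.asc"), world.dem, cell)
    write_ascii_grid(
        os.path.join(outdir, "surface_water.asc"), world.surface_water.astype(np.uint8), cell
    )
    write_ascii_grid(os.path.join(outdir, "country.asc"), world.country, cell, nodata=-1)
    world.sanitation.to_csv(os.path.join(outdir, "sanitation.csv"), index=False)
    world.sanitation_truth.to_csv(os.path.join(outdir, "sanitation_truth.csv"), index=False)
    world.protein_gdp.to_csv(os.path.join(outdir, "protein_gdp.csv"), index=False)
    world.protein_gdp_truth.to_csv(os.path.join(outdir, "protein_gdp_truth.csv"), index=False)
    world.regions.to_csv(os.path.join(outdir, "regions.csv"), index=False)
    for kind, feats in world.habitats.items():
        fc = {
            "type": "FeatureCollection",
            "features": [
                {"type": "Feature", "properties": {"habitat": kind}, "geometry": mapping(g)}
                for g in feats
            ],
        }
        with open(os.path.join(outdir, f"habitat_{kind}.geojson"), "w") as fh:
            json.dump(fc, fh)
    with open(os.path.join(outdir, "config.json"), "w") as fh:
        json.dump(dataclasses.asdict(world.config), fh, indent=1)
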