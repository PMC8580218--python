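"""Per-cell wastewater effluent rasters.

Nitrogen reaching water from a cell is population x protein consumption x
the 0.16 protein-to-N excretion fraction x the production coefficient of
each disposal category; the pathogen proxy (FIO) is population x the
mix-weighted emission factor. Septic and open-defecation loads only count
when the cell centre lies within 1 km of surface water or the coast —
those inputs soak into the landscape otherwise, while sewered effluent is
piped regardless of distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .factors import FIOWeights, RemovalRates, n_production_coefficient
from .synth import RURAL, URBAN, SyntheticWorld

#: Fraction of ingested protein excreted as nitrogen compounds.
PROTEIN_TO_N = 0.16

SOURCES = ("sewered", "septic", "direct")


@dataclass
class EffluentGrid:
    """Annual N (g yr^-1 cell^-1) by source and unitless FIO rasters."""

    n_sewered: np.ndarray
    n_septic: np.ndarray
    n_direct: np.ndarray
    fio_sewered: np.ndarray
    fio_septic: np.ndarray
    fio_direct: np.ndarray
    cell_km: float = 1.0
    year: int = 2015

    @property
    def n_total(self) -> np.ndarray:
        return self.n_sewered + self.n_septic + self.n_direct

    @property
    def fio_total(self) -> np.ndarray:
        return self.fio_sewered + self.fio_septic + self.fio_direct

    def copy(self) -> "EffluentGrid":
        return EffluentGrid(
            self.n_sewered.copy(),
            self.n_septic.copy(),
            self.n_direct.copy(),
            self.fio_sewered.copy(),
            self.fio_septic.copy(),
            self.fio_direct.copy(),
            self.cell_km,
            self.year,
        )


def pixel_effluent(pop, protein, mix, rates: RemovalRates = RemovalRates(),
                   protein_to_n: float = PROTEIN_TO_N):
    """N effluent by source for one pixel (or broadcastable arrays).

    ``N_t = pop * protein * 0.16 * f_t * (1 - r_t)`` in g N yr^-1.
    Returns ``(n_direct, n_septic, n_sewered)``.
    """
    pop = np.asarray(pop, dtype=float)
    protein = np.asarray(protein, dtype=float)
    if np.any(pop < 0) or np.any(protein < 0):
        raise ValueError("population and protein must be non-negative")
    c = n_production_coefficient(mix, rates)
    base = pop * protein * protein_to_n
    return base * c["c_direct"], base * c["c_septic"], base * c["c_sewered"]


def pixel_fio(pop, mix, weights: FIOWeights = FIOWeights()):
    """Unitless FIO load for one pixel: population x sum_t f_t w_t."""
    pop = np.asarray(pop, dtype=float)
    if np.any(pop < 0):
        raise ValueError("population must be non-negative")
    f_direct, f_septic, f_sewered = (np.asarray(m, dtype=float) for m in mix)
    weights.validate()
    return pop * (
        f_direct * weights.w_direct + f_septic * weights.w_septic + f_sewered * weights.w_sewered
    )


def apply_proximity_rule(grid: EffluentGrid, water_mask, coast_mask, distance_km: float = 1.0,
                         sources=("septic", "direct")) -> EffluentGrid:
    """Zero non-sewered loads on cells farther than ``distance_km`` from water.

    Distance is Euclidean between cell centres; cells with centre strictly
    farther than the threshold from every water/coast cell centre lose the
    listed source components (N and FIO alike). Sewered loads are never
    touched. Returns a new grid.
    """
    water_mask = np.asarray(water_mask, dtype=bool)
    coast_mask = np.asarray(coast_mask, dtype=bool)
    if water_mask.shape != grid.n_septic.shape or coast_mask.shape != grid.n_septic.shape:
        raise ValueError("mask shape does not match effluent grid")
    out = grid.copy()
    if not np.isfinite(distance_km):
        return out
    near = water_mask | coast_mask
    if not near.any():
        far = np.ones_like(near)
    else:
        dist = ndimage.distance_transform_edt(~near) * grid.cell_km
        far = dist > distance_km
    for source in sources:
        if source == "sewered":
            raise ValueError("the proximity rule never applies to sewered loads")
        getattr(out, f"n_{source}")[far] = 0.0
        getattr(out, f"fio_{source}")[far] = 0.0
    return out


def build_effluent_grids(world: SyntheticWorld, factors, rates: RemovalRates = RemovalRates(),
                         fio_weights: FIOWeights = FIOWeights(),
                         proximity_km: float = 1.0,
                         proximity_sources=("septic", "direct"),
                         protein_to_n: float = PROTEIN_TO_N) -> EffluentGrid:
    """Vectorised per-cell effluent from a world and a complete factor table.

    Each inhabited cell looks up its country's urban or rural coefficients
    by settlement class (inhabited-but-unclassed cells count as rural) and
    the country's protein value, then the surface-water proximity rule is
    applied. Raises if any populated cell has no country label or its
    country lacks factors.
    """
    pop = world.population.astype(float)
    inhabited = pop > 0
    bad = inhabited & (world.country < 0)
    if bad.any():
        cells = np.argwhere(bad)[:10].tolist()
        raise ValueError(f"populated cells without a country label, e.g. {cells}")

    mixes = factors.mixes
    protein_tab = factors.protein
    max_id = int(world.country.max()) if (world.country >= 0).any() else -1
    # per-country lookup arrays indexed by country id, per stratum
    lut = {}
    for stratum in ("urban", "rural"):
        sub = mixes[mixes.strata == stratum].set_index("country")
        for col in ("c_direct", "c_septic", "c_sewered", "fio_factor",
                    "f_direct", "f_septic", "f_sewered"):
            arr = np.full(max_id + 1, np.nan)
            for cid in sub.index:
                if 0 <= int(cid) <= max_id:
                    arr[int(cid)] = sub.at[cid, col]
            lut[(stratum, col)] = arr
    prot_arr = np.full(max_id + 1, np.nan)
    psub = protein_tab.set_index("country")
    for cid in psub.index:
        if 0 <= int(cid) <= max_id:
            prot_arr[int(cid)] = psub.at[cid, "protein"]

    shape = pop.shape
    zeros = lambda: np.zeros(shape)
    grid = EffluentGrid(zeros(), zeros(), zeros(), zeros(), zeros(), zeros(),
                        cell_km=world.cell_km)
    cls = world.settlement
    for stratum, mask in (("urban", inhabited & (cls == URBAN)),
                          ("rural", inhabited & (cls != URBAN))):
        if not mask.any():
            continue
        cid = world.country[mask]
        protein = prot_arr[cid]
        if np.isnan(protein).any():
            missing = sorted(set(cid[np.isnan(protein)].tolist()))
            raise ValueError(f"countries with population but no protein value: {missing}")
        base = pop[mask] * protein * protein_to_n
        for source in SOURCES:
            c = lut[(stratum, f"c_{source}")][cid]
            if np.isnan(c).any():
                missing = sorted(set(cid[np.isnan(c)].tolist()))
                raise ValueError(f"countries with population but no {stratum} factors: {missing}")
            getattr(grid, f"n_{source}")[mask] = base * c
            f = lut[(stratum, f"f_{source}")][cid]
            w = getattr(fio_weights, f"w_{source}")
            getattr(grid, f"fio_{source}")[mask] = pop[mask] * f * w
    coast = world.ocean
    return apply_proximity_rule(grid, world.surface_water, coast,
                                distance_km=proximity_km, sources=proximity_sources)
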