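"""Watershed delineation and load aggregation.

Flow is routed by D8 steepest descent over land: each cell drains to the
8-neighbour with the greatest elevation drop (diagonal drops divided by
sqrt(2); ties broken in fixed E, SE, S, SW, W, NW, N, NE order). A cell with
no strictly lower land neighbour is terminal; basins are the groups of
cells sharing a terminal. A terminal that touches the ocean is that basin's
coastal pourpoint; interior terminals mark endorheic (internal) basins,
which are excluded from marine totals. Effluent rasters are summed over
basin membership and attributed to pourpoints, and pourpoint loads are
summed per country — a transboundary basin is credited wholly to the
country holding its pourpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .effluent import EffluentGrid
from .synth import D8_OFFSETS

SQRT2 = math.sqrt(2.0)

LOAD_COLS = ("n_sewered", "n_septic", "n_direct", "n_total", "fio")


@dataclass
class WatershedSet:
    """Basin labels plus per-basin records (and loads once aggregated)."""

    labels: np.ndarray  # int32 basin id per land cell, -1 elsewhere
    basins: pd.DataFrame  # id, area_cells, pp_row, pp_col, drains_to_ocean [, loads]

    @property
    def n_basins(self) -> int:
        return len(self.basins)


def d8_flow_targets(dem, land_mask):
    """Flat-index flow target per cell; -1 where terminal or not land.

    Only land neighbours are candidates; the steepest positive drop wins,
    first-in-order on ties.
    """
    dem = np.asarray(dem, dtype=float)
    land = np.asarray(land_mask, dtype=bool)
    if dem.shape != land.shape:
        raise ValueError("dem and land mask shapes differ")
    if not np.isfinite(dem[land]).all():
        raise ValueError("DEM must be finite on land")
    rows, cols = dem.shape
    # pad with +inf so off-grid and ocean neighbours never win
    elev = np.where(land, dem, np.inf)
    padded = np.pad(elev, 1, constant_values=np.inf)
    best_drop = np.zeros((rows, cols))
    target = np.full((rows, cols), -1, dtype=np.int64)
    flat = np.arange(rows * cols).reshape(rows, cols)
    flat_padded = np.pad(flat, 1, constant_values=-1)
    for dr, dc in D8_OFFSETS:
        nelev = padded[1 + dr : 1 + dr + rows, 1 + dc : 1 + dc + cols]
        w = SQRT2 if dr and dc else 1.0
        drop = (dem - nelev) / w
        better = land & (drop > best_drop)
        best_drop[better] = drop[better]
        target[better] = flat_padded[1 + dr : 1 + dr + rows, 1 + dc : 1 + dc + cols][better]
    target[~land] = -1
    return target


def _coastal_mask(land):
    """Land cells 8-adjacent to ocean (or to the grid edge)."""
    rows, cols = land.shape
    padded = np.pad(land, 1, constant_values=False)
    coastal = np.zeros_like(land)
    for dr, dc in D8_OFFSETS:
        coastal |= ~padded[1 + dr : 1 + dr + rows, 1 + dc : 1 + dc + cols]
    return coastal & land


def delineate(dem, land_mask) -> WatershedSet:
    """Partition land into D8 basins with pourpoints.

    Terminal resolution uses pointer doubling, so cost is O(cells x log
    longest-flow-path).
    """
    land = np.asarray(land_mask, dtype=bool)
    rows, cols = land.shape
    target = d8_flow_targets(dem, land)
    nxt = np.arange(rows * cols)
    has_target = target.ravel() >= 0
    nxt[has_target] = target.ravel()[has_target]
    while True:
        nxt2 = nxt[nxt]
        if np.array_equal(nxt2, nxt):
            break
        nxt = nxt2
    labels = np.full((rows, cols), -1, dtype=np.int32)
    land_flat = land.ravel()
    if land_flat.any():
        terminals = nxt[land_flat]
        uniq, inv = np.unique(terminals, return_inverse=True)
        labels.ravel()[land_flat] = inv.astype(np.int32)
        coastal = _coastal_mask(land).ravel()
        records = []
        areas = np.bincount(inv, minlength=len(uniq))
        for b, term in enumerate(uniq):
            records.append(
                {
                    "id": b,
                    "area_cells": int(areas[b]),
                    "pp_row": int(term // cols),
                    "pp_col": int(term % cols),
                    "drains_to_ocean": bool(coastal[term]),
                }
            )
        basins = pd.DataFrame(records)
    else:
        basins = pd.DataFrame(
            columns=["id", "area_cells", "pp_row", "pp_col", "drains_to_ocean"]
        ).astype({"id": int, "area_cells": int, "pp_row": int, "pp_col": int,
                  "drains_to_ocean": bool})
    return WatershedSet(labels=labels, basins=basins)


def aggregate(watersheds: WatershedSet, effluent: EffluentGrid) -> WatershedSet:
    """Sum effluent rasters over basin membership; returns a new
    :class:`WatershedSet` whose basin table carries per-source loads."""
    labels = watersheds.labels
    if labels.shape != effluent.n_sewered.shape:
        raise ValueError("basin label and effluent raster shapes differ")
    basins = watersheds.basins.copy()
    n = len(basins)
    on_land = labels >= 0
    lab = labels[on_land]
    fields = {
        "n_sewered": effluent.n_sewered,
        "n_septic": effluent.n_septic,
        "n_direct": effluent.n_direct,
        "n_total": effluent.n_total,
        "fio": effluent.fio_total,
    }
    for name, raster in fields.items():
        sums = np.bincount(lab, weights=raster[on_land], minlength=n) if n else np.array([])
        basins[name] = sums
    return WatershedSet(labels=labels, basins=basins)


def pourpoint_loads(watersheds: WatershedSet, country_raster=None) -> pd.DataFrame:
    """Ocean-draining basins as a pourpoint table (one row per pourpoint)."""
    basins = watersheds.basins
    missing = [c for c in LOAD_COLS if c not in basins.columns]
    if missing:
        raise ValueError(f"basin loads not aggregated yet (missing {missing})")
    pp = basins[basins.drains_to_ocean].copy().reset_index(drop=True)
    if country_raster is not None:
        country_raster = np.asarray(country_raster)
        pp["country"] = [
            int(country_raster[r, c]) for r, c in zip(pp.pp_row, pp.pp_col)
        ]
    return pp


def country_discharge(pourpoints: pd.DataFrame) -> pd.DataFrame:
    """Per-country marine discharge by source, summed over pourpoints.

    Each basin's whole load goes to the country containing its pourpoint,
    matching how national discharge is reported for transboundary basins.
    """
    if "country" not in pourpoints.columns:
        raise ValueError("pourpoint table lacks country labels")
    if pourpoints["country"].lt(0).any():
        bad = pourpoints[pourpoints.country < 0][["pp_row", "pp_col"]].values.tolist()
        raise ValueError(f"pourpoints without a country label at {bad}")
    return (
        pourpoints.groupby("country", as_index=False)[list(LOAD_COLS)]
        .sum()
        .sort_values("country")
        .reset_index(drop=True)
    )


def load_precomputed(labels, pourpoint_table) -> WatershedSet:
    """Wrap an externally produced basin-label raster + pourpoint table
    (columns id, pp_row, pp_col, drains_to_ocean) as a WatershedSet."""
    labels = np.asarray(labels, dtype=np.int32)
    basins = pd.DataFrame(pourpoint_table).copy()
    required = {"id", "pp_row", "pp_col", "drains_to_ocean"}
    if not required.issubset(basins.columns):
        raise ValueError(f"pourpoint table needs columns {sorted(required)}")
    if "area_cells" not in basins.columns:
        ids, counts = np.unique(labels[labels >= 0], return_counts=True)
        area = dict(zip(ids.tolist(), counts.tolist()))
        basins["area_cells"] = basins["id"].map(area).fillna(0).astype(int)
    return WatershedSet(labels=labels, basins=basins)
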