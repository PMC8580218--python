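"""Ocean plume propagation from coastal pourpoints.

Each retained pourpoint's load spreads over ocean cells along shortest
8-connected over-water paths (so plumes wrap around headlands and islands
but are not advected), losing a fixed fraction of value per cell step:
``value = load * (1 - decay_per_cell)**steps``. Cells whose total-N value
falls below a cutoff expressed as a fraction of the largest retained
pourpoint load are truncated to zero, and pourpoints below a minimum N load
are dropped before pluming. Overlapping plumes add.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .synth import D8_OFFSETS

PLUME_SOURCES = ("n_sewered", "n_septic", "n_direct")

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class PlumeParams:
    """Plume decay/truncation parameters.

    decay_per_cell: fraction of value lost per ocean-cell step (0.005
    = 0.5% loss, i.e. retain 99.5%).
    cutoff_fraction: minimum retained value as a fraction of the largest
    retained pourpoint's total-N load (0.0005 = 0.05%).
    min_pourpoint_load: pourpoints below this total N (g) are excluded.
    """

    decay_per_cell: float = 0.005
    cutoff_fraction: float = 0.0005
    min_pourpoint_load: float = 1.0
    include_fio: bool = False

    def validate(self):
        if not 0.0 < self.decay_per_cell < 1.0:
            raise ValueError("decay_per_cell must be in (0, 1)")
        if not 0.0 < self.cutoff_fraction < 1.0:
            raise ValueError("cutoff_fraction must be in (0, 1)")
        if self.min_pourpoint_load < 0:
            raise ValueError("min_pourpoint_load must be >= 0")
        return self


@dataclass
class PlumeField:
    """Summed ocean plume rasters by source (zero on land)."""

    n_sewered: np.ndarray
    n_septic: np.ndarray
    n_direct: np.ndarray
    fio: np.ndarray | None = None
    params: PlumeParams = field(default_factory=PlumeParams)
    n_sources_retained: int = 0

    @property
    def n_total(self) -> np.ndarray:
        return self.n_sewered + self.n_septic + self.n_direct


def snap_to_ocean(ocean_mask, cell):
    """Return ``cell`` if it is ocean, else its first ocean 8-neighbour in
    fixed E, SE, S, SW, W, NW, N, NE order. Raises if none exists."""
    ocean = np.asarray(ocean_mask, dtype=bool)
    r, c = cell
    if ocean[r, c]:
        return (r, c)
    rows, cols = ocean.shape
    for dr, dc in D8_OFFSETS:
        nr, nc = r + dr, c + dc
        if 0 <= nr < rows and 0 <= nc < cols and ocean[nr, nc]:
            return (nr, nc)
    raise ValueError(f"cell {cell} is on land with no adjacent ocean cell")


def ocean_step_distance(ocean_mask, source_cell, max_steps=None):
    """Minimum 8-connected over-water step count from ``source_cell``.

    Returns an int array (-1 where unreachable or land). The source is
    snapped to an adjacent ocean cell if it lies on land. Implemented as a
    breadth-first frontier expansion, optionally stopped at ``max_steps``.
    """
    ocean = np.asarray(ocean_mask, dtype=bool)
    src = snap_to_ocean(ocean, source_cell)
    dist = np.full(ocean.shape, -1, dtype=np.int32)
    frontier = np.zeros(ocean.shape, dtype=bool)
    frontier[src] = True
    dist[src] = 0
    d = 0
    while frontier.any():
        if max_steps is not None and d >= max_steps:
            break
        d += 1
        grown = ndimage.binary_dilation(frontier, structure=_STRUCT8)
        frontier = grown & ocean & (dist < 0)
        dist[frontier] = d
    return dist


def plume_single(pourpoint, ocean_mask, params: PlumeParams, global_max: float):
    """Plume one pourpoint; returns dict of per-source rasters (or None if
    the pourpoint is excluded by the minimum-load rule).

    ``pourpoint`` is a mapping with pp_row, pp_col, n_sewered, n_septic,
    n_direct, n_total (and fio if pluming FIO). Cells where the total-N
    value would fall below ``cutoff_fraction * global_max`` are zeroed in
    every source field, keeping per-cell source additivity.
    """
    params.validate()
    load_total = float(pourpoint["n_total"])
    if load_total < params.min_pourpoint_load:
        return None
    ocean = np.asarray(ocean_mask, dtype=bool)
    threshold = params.cutoff_fraction * global_max
    retain = 1.0 - params.decay_per_cell
    if load_total > 0 and threshold > 0:
        # decay below the cutoff is unreachable past this many steps
        max_steps = int(math.floor(math.log(threshold / load_total) / math.log(retain))) if threshold < load_total else 0
    else:
        max_steps = None
    dist = ocean_step_distance(ocean, (int(pourpoint["pp_row"]), int(pourpoint["pp_col"])), max_steps=max_steps)
    reached = dist >= 0
    decay = np.zeros(ocean.shape)
    decay[reached] = retain ** dist[reached]
    total_field = load_total * decay
    keep = total_field >= threshold
    decay[~keep] = 0.0
    out = {name: float(pourpoint[name]) * decay for name in PLUME_SOURCES}
    if params.include_fio and "fio" in pourpoint:
        out["fio"] = float(pourpoint["fio"]) * decay
    return out


def plume_all(pourpoints, ocean_mask, params: PlumeParams = PlumeParams()) -> PlumeField:
    """Sum plumes of all retained pourpoints into one field per source.

    The cutoff reference (``global_max``) is the largest total-N load among
    retained pourpoints, applied uniformly to every source field.
    """
    params.validate()
    ocean = np.asarray(ocean_mask, dtype=bool)
    if isinstance(pourpoints, pd.DataFrame):
        rows = [row for _, row in pourpoints.iterrows()]
    else:
        rows = list(pourpoints)
    retained = [r for r in rows if float(r["n_total"]) >= params.min_pourpoint_load]
    shape = ocean.shape
    fields = {name: np.zeros(shape) for name in PLUME_SOURCES}
    fio = np.zeros(shape) if params.include_fio else None
    if retained:
        global_max = max(float(r["n_total"]) for r in retained)
        for r in retained:
            single = plume_single(r, ocean, params, global_max)
            if single is None:
                continue
            for name in PLUME_SOURCES:
                fields[name] += single[name]
            if fio is not None and "fio" in single:
                fio += single["fio"]
    return PlumeField(
        n_sewered=fields["n_sewered"],
        n_septic=fields["n_septic"],
        n_direct=fields["n_direct"],
        fio=fio,
        params=params,
        n_sources_retained=len(retained),
    )
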