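"""Plain-text raster I/O (ESRI ASCII grid).

All model rasters live on a single row/column grid with square cells of edge
``cell_km`` kilometres. Row 0 is the top row; the x axis runs east along
columns, y runs north, so the cell centre of ``(row, col)`` is at
``x = (col + 0.5) * cell_km`` and ``y = (n_rows - row - 0.5) * cell_km``.

The ESRI ASCII grid format is used for on-disk rasters: it is a plain-text
interchange format readable by every mainstream GIS.
"""

from __future__ import annotations

import numpy as np

__all__ = ["write_ascii_grid", "read_ascii_grid", "cell_centers"]


def write_ascii_grid(path, array, cell_km: float = 1.0, nodata: float = -1.0) -> None:
    """Write a 2-D array as an ESRI ASCII grid (plain text)."""
    arr = np.asarray(array)
    if arr.ndim != 2:
        raise ValueError("raster must be 2-D")
    nrows, ncols = arr.shape
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner 0.0\n"
        f"yllcorner 0.0\n"
        f"cellsize {cell_km!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    if np.issubdtype(arr.dtype, np.integer) or arr.dtype == bool:
        fmt = "%d"
        arr = arr.astype(np.int64)
    else:
        fmt = "%.10g"
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, arr, fmt=fmt)


def read_ascii_grid(path):
    """Read an ESRI ASCII grid. Returns ``(array, cell_km, nodata)``."""
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                meta[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        arr = np.loadtxt(fh)
    arr = arr.reshape(int(meta["nrows"]), int(meta["ncols"]))
    return arr, meta.get("cellsize", 1.0), meta.get("nodata_value", -1.0)


def cell_centers(shape, cell_km: float = 1.0):
    """Return ``(x, y)`` centre-coordinate arrays (km) for every cell."""
    nrows, ncols = shape
    x = (np.arange(ncols) + 0.5) * cell_km
    y = (nrows - np.arange(nrows) - 0.5) * cell_km
    return np.meshgrid(x, y)
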