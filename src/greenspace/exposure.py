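"""Zonal extraction of greenness metrics within boundary geometries.

The aggregation operator is a plain mean of the raster pixels whose
*centers* fall inside the geometry (no partial-pixel area weighting) —
a simple rule that an exhaustive point-in-polygon enumeration can check
exactly. Nodata pixels are excluded; a geometry that captures no pixel
center yields a missing value.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from .boundaries import BoundarySet
from .greenness import GreennessRaster
from .grids import RasterGrid

log = logging.getLogger(__name__)

METRICS = ["MXN", "TIN"]

#: Short column codes used in the wide exposure layout.
SCHEME_CODES = {
    "county": "IL",
    "h1ha": "1H/1HA",
    "h10ha": "1H/10HAs",
    "place": "CP",
    "urban_area": "UA",
    "combined": "CP+UA",
}


def zonal_mean(
    values: np.ndarray, grid: RasterGrid, geometry: BaseGeometry
) -> float:
    """Mean of non-nodata pixels whose centers lie inside ``geometry``.

    Returns NaN (missing) for empty geometries or when no valid pixel
    center is captured.
    """
    if geometry is None or geometry.is_empty:
        log.debug("zonal_mean: empty geometry -> missing")
        return float("nan")
    if values.shape != grid.shape:
        raise ValueError("raster shape does not match the grid")

    rows, cols = grid.window(geometry.bounds)
    if rows.stop <= rows.start or cols.stop <= cols.start:
        return float("nan")
    xs = grid.x_centers()[cols]
    ys = grid.y_centers()[rows]
    xx, yy = np.meshgrid(xs, ys)
    shapely.prepare(geometry)
    inside = shapely.contains_xy(geometry, xx.ravel(), yy.ravel()).reshape(xx.shape)
    if not inside.any():
        return float("nan")
    vals = values[rows, cols][inside]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        log.debug("zonal_mean: geometry covers only nodata pixels -> missing")
        return float("nan")
    return float(vals.mean())


def build_exposure_table(
    greenness: GreennessRaster, boundaries: list[BoundarySet]
) -> pd.DataFrame:
    """One exposure record per county x scheme x buffer x metric.

    Counties with an empty geometry under a scheme get missing values.
    Duplicate (county, scheme, buffer, metric) combinations in the input
    boundary list are a hard failure.
    """
    bands = {"MXN": greenness.mxn, "TIN": greenness.tin}
    records = []
    for bset in boundaries:
        for county_id, geom in bset.geometries.items():
            for metric, band in bands.items():
                records.append(
                    {
                        "county_id": county_id,
                        "scheme": bset.scheme,
                        "buffer_m": bset.buffer_m,
                        "metric": metric,
                        "value": zonal_mean(band, greenness.grid, geom),
                    }
                )
    table = pd.DataFrame(records)
    keys = table[["county_id", "scheme", "buffer_m", "metric"]]
    if keys.duplicated().any():
        dupes = keys[keys.duplicated()].drop_duplicates()
        raise ValueError(
            f"duplicate exposure records for: {dupes.to_dict(orient='records')}"
        )
    return table


def exposure_wide(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the tidy exposure table to one county per row.

    Columns are named ``{metric}-{scheme code}`` (e.g. ``TIN-CP+UA``),
    with a ``@{buffer}m`` suffix for buffered variants.
    """
    t = table.copy()

    def colname(r):
        code = SCHEME_CODES.get(r["scheme"], r["scheme"])
        name = f"{r['metric']}-{code}"
        if r["buffer_m"]:
            name += f"@{int(r['buffer_m'])}m"
        return name

    t["column"] = t.apply(colname, axis=1)
    wide = t.pivot(index="county_id", columns="column", values="value")
    wide.columns.name = None
    return wide.reset_index()
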