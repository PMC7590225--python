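"""Community-activity-space boundary schemes and coverage accounting.

Six per-county boundary schemes delimit where a county's population
plausibly lives and moves, i.e. where green-space exposure should be
measured:

======  =====================================================
county  the whole county (the naive administrative unit)
h1ha    block groups with >= 1 household per hectare, dissolved
h10ha   block groups with >= 1 household per 10 hectares
place   census places clipped to the county
urban_area  census urban areas clipped to the county
combined    union of place and urban_area, clipped to the county
======  =====================================================

Each scheme can additionally be buffered (Euclidean, meters) to probe
the scaling component of the modifiable areal unit problem; buffers may
extend past county lines, but exposure stays attributed to the owning
county. Counties can legitimately end up with an empty geometry under a
scheme (e.g. no urban area) — downstream analyses drop them listwise
for that scheme.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from shapely import union_all
from shapely.geometry import Polygon
from shapely.geometry.base import BaseGeometry

log = logging.getLogger(__name__)

SCHEMES = ["county", "h1ha", "h10ha", "place", "urban_area", "combined"]
BUFFERS_M = [0, 300, 500, 1000]

#: Minimum household density (households / hectare) of the two
#: residential-density schemes.
DENSITY_THRESHOLDS = {"h1ha": 1.0, "h10ha": 0.1}

#: Segments per quarter circle for buffer arcs (area error < 0.5 %).
BUFFER_QUAD_SEGS = 16

_EMPTY = Polygon()


@dataclass
class BoundarySet:
    """Per-county exposure geometry for one scheme and buffer distance."""

    scheme: str
    buffer_m: float
    geometries: dict[str, BaseGeometry]  # county_id -> geometry (may be empty)
    clipped_to_county: bool
    provenance: str

    def union(self) -> BaseGeometry:
        return union_all([g for g in self.geometries.values() if not g.is_empty])

    def empty_counties(self) -> list[str]:
        return [cid for cid, g in self.geometries.items() if g.is_empty]


def select_residential_blockgroups(
    blockgroups: pd.DataFrame, min_density: float
) -> pd.DataFrame:
    """Block groups whose household density reaches ``min_density`` per hectare.

    Records with a nonpositive ``area_ha`` are rejected with a logged
    diagnostic rather than treated as infinitely dense.
    """
    if min_density <= 0:
        raise ValueError("min_density must be positive")
    bad = blockgroups["area_ha"] <= 0
    if bad.any():
        log.warning(
            "dropping %d block groups with nonpositive area: %s",
            bad.sum(),
            blockgroups.loc[bad, "id"].tolist(),
        )
        blockgroups = blockgroups[~bad]
    density = blockgroups["households"] / blockgroups["area_ha"]
    return blockgroups[density >= min_density]


def build_boundary(world, scheme: str) -> BoundarySet:
    """Construct one boundary scheme for every county of ``world``.

    All geometries are clipped to their county before exposure
    extraction; the residential-density schemes dissolve the selected
    block groups per county.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")

    counties = world.counties
    geoms: dict[str, BaseGeometry] = {}

    if scheme == "county":
        for _, row in counties.iterrows():
            geoms[row["id"]] = row["geometry"]
        prov = "county layer (identity)"
    elif scheme in DENSITY_THRESHOLDS:
        thr = DENSITY_THRESHOLDS[scheme]
        selected = select_residential_blockgroups(world.blockgroups, thr)
        grouped = selected.groupby("county_id")["geometry"]
        merged = {cid: union_all(list(gs)) for cid, gs in grouped}
        for cid in counties["id"]:
            geoms[cid] = merged.get(cid, _EMPTY)
        prov = f"block groups with >= {thr} households/ha, dissolved per county"
    else:
        if scheme == "place":
            layers = [world.places]
        elif scheme == "urban_area":
            layers = [world.urban_areas]
        else:  # combined
            layers = [world.places, world.urban_areas]
        parts = [g for layer in layers for g in layer["geometry"] if not g.is_empty]
        overlay = union_all(parts) if parts else _EMPTY
        for _, row in counties.iterrows():
            geoms[row["id"]] = overlay.intersection(row["geometry"])
        prov = f"{scheme} layer(s) intersected per county"

    empty = [cid for cid, g in geoms.items() if g.is_empty]
    if empty:
        log.info("scheme %s: %d counties with empty geometry: %s", scheme, len(empty), empty)
    return BoundarySet(
        scheme=scheme,
        buffer_m=0,
        geometries=geoms,
        clipped_to_county=True,
        provenance=prov,
    )


def apply_buffer(boundary: BoundarySet, buffer_m: float) -> BoundarySet:
    """Euclidean-buffer every county geometry; 0 is the identity."""
    if buffer_m < 0:
        raise ValueError("buffer_m must be nonnegative")
    if buffer_m == 0:
        return boundary
    geoms = {
        cid: (g if g.is_empty else g.buffer(buffer_m, quad_segs=BUFFER_QUAD_SEGS))
        for cid, g in boundary.geometries.items()
    }
    return replace(
        boundary,
        buffer_m=buffer_m,
        geometries=geoms,
        clipped_to_county=False,
        provenance=f"{boundary.provenance}; buffered {buffer_m} m",
    )


def coverage_stats(boundaries: list[BoundarySet], world) -> dict[str, pd.DataFrame]:
    """Area accounting of the boundary schemes over the study region.

    Returns ``{"schemes": ..., "pairwise": ...}``:

    * ``schemes`` — per scheme (plus the union of all schemes): absolute
      area (km^2) and percent of the total region (county union) area;
    * ``pairwise`` — for every ordered scheme pair (a, b): the fraction
      of a's area overlapped by b (1.0 on a row means a is a subset of b).
    """
    region = union_all(list(world.counties["geometry"]))
    total = region.area

    unions = {b.scheme: b.union() for b in boundaries}
    rows = [
        {
            "scheme": name,
            "area_km2": geom.area / 1e6,
            "percent_of_region": 100.0 * geom.area / total,
        }
        for name, geom in unions.items()
    ]
    overall = union_all(list(unions.values()))
    rows.append(
        {
            "scheme": "any_scheme",
            "area_km2": overall.area / 1e6,
            "percent_of_region": 100.0 * overall.area / total,
        }
    )
    schemes_df = pd.DataFrame(rows)

    pair_rows = []
    names = list(unions)
    for a in names:
        for b in names:
            if a == b:
                continue
            ga, gb = unions[a], unions[b]
            inter = ga.intersection(gb).area
            frac = inter / ga.area if ga.area > 0 else np.nan
            pair_rows.append(
                {
                    "scheme_a": a,
                    "scheme_b": b,
                    "overlap_fraction_of_a": frac,
                    "a_subset_of_b": bool(ga.area > 0 and frac > 1 - 1e-9),
                }
            )
    return {"schemes": schemes_df, "pairwise": pd.DataFrame(pair_rows)}
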