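"""Readers and writers for the pipeline's on-disk formats.

Vector layers travel as GeoJSON FeatureCollections (planar meter
coordinates, declared by a ``crs`` tag in the collection), rasters as
multi-band GeoTIFFs whose grid metadata is a JSON document in the
ImageDescription tag, and tables as CSV with ``#``-prefixed provenance
header lines.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from shapely.geometry import mapping, shape

from .grids import CRS_TAG, RasterGrid


# ---------------------------------------------------------------- vector

def write_vector(df: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame with a shapely ``geometry`` column as GeoJSON."""
    features = []
    props_cols = [c for c in df.columns if c != "geometry"]
    for _, row in df.iterrows():
        props = {}
        for c in props_cols:
            v = row[c]
            if isinstance(v, (np.integer,)):
                v = int(v)
            elif isinstance(v, (np.floating,)):
                v = float(v)
            elif isinstance(v, (np.bool_,)):
                v = bool(v)
            props[c] = v
        features.append(
            {
                "type": "Feature",
                "properties": props,
                "geometry": mapping(row["geometry"]),
            }
        )
    doc = {"type": "FeatureCollection", "crs": CRS_TAG, "features": features}
    Path(path).write_text(json.dumps(doc))


def read_vector(path: str | Path) -> pd.DataFrame:
    doc = json.loads(Path(path).read_text())
    crs = doc.get("crs", CRS_TAG)
    if crs != CRS_TAG:
        raise ValueError(f"{path}: unsupported CRS tag {crs!r}")
    rows = []
    for feat in doc["features"]:
        row = dict(feat.get("properties") or {})
        row["geometry"] = shape(feat["geometry"])
        rows.append(row)
    df = pd.DataFrame(rows)
    cols = [c for c in df.columns if c != "geometry"] + ["geometry"]
    return df[cols]


# ---------------------------------------------------------------- raster

def write_raster(
    path: str | Path,
    grid: RasterGrid,
    values: np.ndarray,
    band_names: list[str] | None = None,
    nodata: float = float("nan"),
) -> None:
    """Write a (bands, rows, cols) or (rows, cols) array as a tagged TIFF."""
    values = np.asarray(values)
    if values.ndim == 2:
        values = values[None]
    if values.shape[1:] != grid.shape:
        raise ValueError("raster shape does not match the grid")
    meta = grid.to_dict()
    meta["band_names"] = band_names or [f"band{i + 1}" for i in range(len(values))]
    meta["nodata"] = None if np.isnan(nodata) else float(nodata)
    tifffile.imwrite(
        str(path),
        values,
        description=json.dumps(meta),
        photometric="minisblack",
    )


def read_raster(path: str | Path) -> tuple[RasterGrid, np.ndarray, list[str]]:
    with tifffile.TiffFile(str(path)) as tif:
        desc = tif.pages[0].description
        values = tif.asarray()
    meta = json.loads(desc)
    grid = RasterGrid.from_dict(meta)
    if values.ndim == 2:
        values = values[None]
    return grid, values, list(meta.get("band_names", []))


# ---------------------------------------------------------------- tables

def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def write_table(
    df: pd.DataFrame, path: str | Path, provenance: dict | None = None
) -> None:
    """CSV with ``# key: value`` provenance header lines."""
    buf = _io.StringIO()
    for k, v in (provenance or {}).items():
        buf.write(f"# {k}: {v}\n")
    df.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------- config

def write_config(config, path: str | Path) -> None:
    """Serialize a config dataclass to YAML (documented key/value schema)."""
    from dataclasses import asdict

    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=True))


def load_world_config(path: str | Path):
    """Read a WorldConfig from YAML, rejecting unknown keys."""
    from dataclasses import fields

    from .synthetic import WorldConfig

    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(WorldConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return WorldConfig(**raw)
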