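"""Synthetic study region generator with known ground truth.

Emulates the data a county-level green-space exposure study consumes:

* nested vector layers — counties on a rectangular grid, block groups
  tiling each county, census-place polygons around settlements, and
  urban-area polygons around contiguous dense cores only (so small rural
  villages appear in the place layer but rarely in the urban-area layer);
* a land-cover raster (urban core / residential / agricultural / forest /
  water) driving both household densities and NDVI phenology;
* a seasonal NDVI stack whose baseline, amplitude and season length are
  land-cover-specific double-logistic curves plus Gaussian noise;
* a county health table produced by a linear model with *planted*
  coefficients (returned in a truth sidecar), so the downstream
  regression machinery can be tested for exact and statistical recovery.

Everything is deterministic given ``WorldConfig.seed``; each stage draws
from its own child generator so the stages can be re-run independently.

Coordinates are planar Cartesian meters (no geodesy); county squares are
laid out row-major from the top-left of the region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import Point, box

from .grids import RasterGrid

__all__ = [
    "LANDCOVER_CLASSES",
    "WorldConfig",
    "Landcover",
    "SyntheticWorld",
    "generate_region",
    "generate_ndvi_stack",
    "generate_health",
]

#: Land-cover class order; raster codes index into this list.
LANDCOVER_CLASSES = ["water", "urban_core", "residential", "agricultural", "forest"]
_CODE = {name: i for i, name in enumerate(LANDCOVER_CLASSES)}

#: Household-density law: class -> (median households/ha, log-normal sigma).
#: A block group's expected count sums the per-pixel class medians over
#: its footprint; one log-normal multiplier per block group (sigma
#: area-weighted over its classes) adds realistic dispersion.
DEFAULT_DENSITY_LAW = {
    "water": (0.0, 0.0),
    "urban_core": (25.0, 0.4),
    "residential": (12.0, 0.5),
    "agricultural": (0.05, 0.8),
    "forest": (0.02, 0.8),
}

#: NDVI phenology per class: (baseline %, amplitude %, season onset,
#: season offset as fractions of the year, logistic steepness).
CLASS_PHENOLOGY = {
    "water": (0.0, 0.0, 0.0, 0.0, 1.0),
    "urban_core": (26.0, 22.0, 0.30, 0.80, 7.0),
    "residential": (30.0, 32.0, 0.28, 0.82, 7.0),
    "agricultural": (18.0, 54.0, 0.42, 0.78, 8.0),
    "forest": (32.0, 44.0, 0.24, 0.86, 6.0),
}


@dataclass(frozen=True)
class WorldConfig:
    """Knobs of the synthetic study region.

    The defaults mirror the scale of a midwestern U.S. state study:
    94 county units of which ~20 are urban, monthly NDVI composites on a
    250 m grid, and a planted greenness-on-exercise coefficient of 0.8
    percentage points of exercising population per TIN percent.
    """

    n_counties: int = 94
    counties_urban_fraction: float = 20 / 94
    blockgroups_per_county: int = 24
    county_size_m: float = 16000.0
    pixel_size_m: float = 250.0
    periods_per_year: int = 12
    household_density_law: dict = field(
        default_factory=lambda: dict(DEFAULT_DENSITY_LAW)
    )
    effect_beta_tin_on_exercise: float = 0.8
    ndvi_noise_sd: float = 2.0
    health_noise_sd: float = 4.0
    rural_urban_cluster_prob: float = 0.9
    health_exposure_scheme: str = "combined"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_counties < 2:
            raise ValueError("need at least 2 counties")
        if not 0.0 <= self.counties_urban_fraction <= 1.0:
            raise ValueError("counties_urban_fraction must be in [0, 1]")
        if self.pixel_size_m <= 0:
            raise ValueError("pixel_size_m must be positive")
        if self.periods_per_year < 4:
            raise ValueError("periods_per_year must be at least 4")
        if self.blockgroups_per_county < 1:
            raise ValueError("blockgroups_per_county must be at least 1")
        p = self.county_size_m / self.pixel_size_m
        if abs(p - round(p)) > 1e-9 or round(p) < 8:
            raise ValueError(
                "county_size_m must be an integer multiple (>= 8) of pixel_size_m"
            )
        p = int(round(p))
        rows = max(1, int(math.isqrt(self.blockgroups_per_county)))
        cols = math.ceil(self.blockgroups_per_county / rows)
        if rows > p or cols > p:
            raise ValueError(
                f"{self.blockgroups_per_county} block groups do not fit a "
                f"{p}x{p}-pixel county"
            )
        missing = set(LANDCOVER_CLASSES) - set(self.household_density_law)
        if missing:
            raise ValueError(f"household_density_law missing classes: {sorted(missing)}")
        # normalize (YAML round-trips tuples as lists)
        object.__setattr__(
            self,
            "household_density_law",
            {k: tuple(map(float, v)) for k, v in self.household_density_law.items()},
        )

    @property
    def pixels_per_county(self) -> int:
        return int(round(self.county_size_m / self.pixel_size_m))


@dataclass
class Landcover:
    """Integer-coded land-cover raster (codes index LANDCOVER_CLASSES)."""

    grid: RasterGrid
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.shape != self.grid.shape:
            raise ValueError("land-cover codes do not match the grid")


@dataclass
class SyntheticWorld:
    """Vector layers + land cover of one synthetic region.

    counties : DataFrame(id, geometry, population, urban)
    blockgroups : DataFrame(id, county_id, geometry, households, area_ha)
    places, urban_areas : DataFrame(id, geometry)
    """

    counties: pd.DataFrame
    blockgroups: pd.DataFrame
    places: pd.DataFrame
    urban_areas: pd.DataFrame
    landcover: Landcover
    config: WorldConfig


def _disk_mask(p: int, cx: float, cy: float, radius: float) -> np.ndarray:
    """Boolean PxP mask of pixels within ``radius`` of (cx, cy), in pixel units."""
    yy, xx = np.mgrid[0:p, 0:p]
    return (xx + 0.5 - cx) ** 2 + (yy + 0.5 - cy) ** 2 <= radius**2


def _split_lengths(total: int, parts: int) -> list[int]:
    """Split ``total`` pixels into ``parts`` near-equal positive lengths."""
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def generate_region(config: WorldConfig) -> SyntheticWorld:
    """Generate the vector layers and the land-cover raster.

    Urban counties get a dense urban core with a residential annulus;
    rural counties get one to three residential hamlets in an
    agricultural/forest matrix, occasionally with a small dense cluster.
    Places cover every settlement; urban areas cover only dense cores.
    Block groups tile each county exactly (rectangles snapped to pixel
    edges), and household counts follow the class-specific log-normal
    density law of the block group's dominant land cover.
    """
    rng = np.random.default_rng([config.seed, 11])
    n = config.n_counties
    grid_cols = math.ceil(math.sqrt(n))
    grid_rows = math.ceil(n / grid_cols)
    L = config.county_size_m
    P = config.pixels_per_county
    px = config.pixel_size_m

    region_grid = RasterGrid(
        origin_x=0.0,
        origin_y=grid_rows * L,
        pixel_size=px,
        n_rows=grid_rows * P,
        n_cols=grid_cols * P,
    )
    codes = np.full(region_grid.shape, _CODE["water"], dtype=np.int8)

    n_urban = int(round(n * config.counties_urban_fraction))
    urban_idx = set(rng.choice(n, size=n_urban, replace=False).tolist())

    county_rows, bg_rows, place_rows, ua_rows = [], [], [], []
    bg_grid_slices = []  # (global row slice, col slice) per block group
    n_bg_rows = max(1, math.isqrt(config.blockgroups_per_county))

    for k in range(n):
        gj, gi = divmod(k, grid_cols)
        minx, maxy = gi * L, (grid_rows - gj) * L
        county_geom = box(minx, maxy - L, minx + L, maxy)
        county_id = f"C{k:03d}"
        is_urban = k in urban_idx

        local = np.full((P, P), _CODE["agricultural"], dtype=np.int8)
        for _ in range(rng.integers(1, 4)):  # forest patches
            fx, fy = rng.uniform(0.1 * P, 0.9 * P, size=2)
            local[_disk_mask(P, fx, fy, rng.uniform(0.08, 0.20) * P)] = _CODE["forest"]
        if rng.random() < 0.5:  # pond
            wx, wy = rng.uniform(0.15 * P, 0.85 * P, size=2)
            local[_disk_mask(P, wx, wy, rng.uniform(0.03, 0.07) * P)] = _CODE["water"]

        settlements = []  # (cx_m, cy_m, place_radius_m, (ua_cx, ua_cy, ua_r) or None)
        if is_urban:
            cx = cy = 0.5 * P
            local[_disk_mask(P, cx, cy, 0.36 * P)] = _CODE["residential"]
            local[_disk_mask(P, cx, cy, 0.22 * P)] = _CODE["urban_core"]
            # the urban area tracks dense development, not the place
            # boundary: offset it so it reaches past the place polygon
            ang = rng.uniform(0, 2 * np.pi)
            ua_c = (
                minx + 0.5 * L + 0.08 * L * np.cos(ang),
                maxy - 0.5 * L + 0.08 * L * np.sin(ang),
            )
            settlements.append(
                (minx + 0.5 * L, maxy - 0.5 * L, 0.34 * L, (*ua_c, 0.30 * L))
            )
        else:
            n_hamlets = int(rng.integers(1, 4))
            dense = rng.random() < config.rural_urban_cluster_prob
            for h in range(n_hamlets):
                hx, hy = rng.uniform(0.15 * P, 0.85 * P, size=2)
                r = rng.uniform(0.04, 0.08) * P
                local[_disk_mask(P, hx, hy, r)] = _CODE["residential"]
                sx, sy = minx + hx * px, maxy - hy * px
                ua = None
                if h == 0 and dense:
                    local[_disk_mask(P, hx, hy, 0.5 * r)] = _CODE["urban_core"]
                    ua = (sx, sy, 0.6 * r * px)
                settlements.append((sx, sy, 1.5 * r * px, ua))

        r0, c0 = gj * P, gi * P
        codes[r0 : r0 + P, c0 : c0 + P] = local

        for s_i, (sx, sy, pr, ua) in enumerate(settlements):
            place_geom = Point(sx, sy).buffer(pr, quad_segs=16).intersection(county_geom)
            place_rows.append({"id": f"{county_id}-P{s_i}", "geometry": place_geom})
            if ua is not None:
                ux, uy, ua_r = ua
                ua_geom = (
                    Point(ux, uy).buffer(ua_r, quad_segs=16).intersection(county_geom)
                )
                ua_rows.append({"id": f"{county_id}-U{s_i}", "geometry": ua_geom})

        # block groups: a rows x cols rectangle partition snapped to pixels
        nbg = config.blockgroups_per_county
        cols_per_row = _split_lengths(nbg, n_bg_rows)
        heights = _split_lengths(P, n_bg_rows)
        bg_n = 0
        row_top_px = 0
        for r_i in range(n_bg_rows):
            widths = _split_lengths(P, cols_per_row[r_i])
            col_left_px = 0
            for w in widths:
                h = heights[r_i]
                g = box(
                    minx + col_left_px * px,
                    maxy - (row_top_px + h) * px,
                    minx + (col_left_px + w) * px,
                    maxy - row_top_px * px,
                )
                bg_rows.append(
                    {
                        "id": f"{county_id}-BG{bg_n:03d}",
                        "county_id": county_id,
                        "geometry": g,
                        "area_ha": w * h * px * px / 1e4,
                    }
                )
                bg_grid_slices.append(
                    (
                        slice(r0 + row_top_px, r0 + row_top_px + h),
                        slice(c0 + col_left_px, c0 + col_left_px + w),
                    )
                )
                col_left_px += w
                bg_n += 1
            row_top_px += heights[r_i]

        county_rows.append(
            {"id": county_id, "geometry": county_geom, "urban": is_urban}
        )

    # households from the land-cover composition of each block group
    px_ha = px * px / 1e4
    medians = np.array([config.household_density_law[c][0] for c in LANDCOVER_CLASSES])
    sigmas = np.array([config.household_density_law[c][1] for c in LANDCOVER_CLASSES])
    for row, (rs, cs) in zip(bg_rows, bg_grid_slices):
        counts = np.bincount(codes[rs, cs].ravel(), minlength=len(LANDCOVER_CLASSES))
        base = float(counts @ medians) * px_ha
        sigma = float(counts @ sigmas) / counts.sum()
        factor = rng.lognormal(mean=0.0, sigma=sigma) if sigma > 0 else 1.0
        row["households"] = int(round(base * factor))

    blockgroups = pd.DataFrame(bg_rows)[
        ["id", "county_id", "geometry", "households", "area_ha"]
    ]
    counties = pd.DataFrame(county_rows)
    hh_by_county = blockgroups.groupby("county_id")["households"].sum()
    counties["population"] = (
        counties["id"].map(hh_by_county).fillna(0).astype(int) * 5 // 2
    )
    counties = counties[["id", "geometry", "population", "urban"]]

    return SyntheticWorld(
        counties=counties,
        blockgroups=blockgroups,
        places=pd.DataFrame(place_rows, columns=["id", "geometry"]),
        urban_areas=pd.DataFrame(ua_rows, columns=["id", "geometry"]),
        landcover=Landcover(grid=region_grid, codes=codes),
        config=config,
    )


def _class_curves(config: WorldConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(baseline, amplitude, normalized seasonal curve) lookup per class code.

    The seasonal shape is a double logistic g(t) = s(k(t-on)) + s(k(off-t)) - 1
    normalized so that its maximum over the sampled periods is exactly 1;
    the sampled peak of a noise-free pixel therefore equals
    baseline + amplitude exactly.
    """
    t = (np.arange(config.periods_per_year) + 0.5) / config.periods_per_year
    baselines = np.zeros(len(LANDCOVER_CLASSES))
    amplitudes = np.zeros(len(LANDCOVER_CLASSES))
    curves = np.zeros((len(LANDCOVER_CLASSES), config.periods_per_year))
    for name, (base, amp, on, off, steep) in CLASS_PHENOLOGY.items():
        i = _CODE[name]
        baselines[i], amplitudes[i] = base, amp
        if amp <= 0:
            continue
        g = (
            1.0 / (1.0 + np.exp(-steep * (t - on)))
            + 1.0 / (1.0 + np.exp(-steep * (off - t)))
            - 1.0
        )
        g = np.clip(g, 0.0, None)
        peak = g.max()
        curves[i] = g / peak if peak > 0 else 0.0
    return baselines, amplitudes, curves


def generate_ndvi_stack(world: SyntheticWorld, config: WorldConfig | None = None):
    """Synthesize the T-period NDVI stack from the land-cover raster.

    Per pixel: NDVI(t) = baseline + amplitude * g(t) with class-specific
    parameters, plus N(0, ndvi_noise_sd) noise, clipped to [0, 100].
    Water pixels are flat zero before noise.
    """
    from .greenness import NDVIStack  # local import to avoid a cycle

    config = config or world.config
    rng = np.random.default_rng([config.seed, 22])
    codes = world.landcover.codes
    baselines, amplitudes, curves = _class_curves(config)

    per_pixel = curves[codes]  # (rows, cols, T)
    values = np.moveaxis(per_pixel, -1, 0) * amplitudes[codes][None]
    values += baselines[codes][None]
    if config.ndvi_noise_sd > 0:
        values = values + rng.normal(0.0, config.ndvi_noise_sd, size=values.shape)
    values = np.clip(values, 0.0, 100.0)

    periods = [f"P{i + 1:02d}" for i in range(config.periods_per_year)]
    return NDVIStack(grid=world.landcover.grid, periods=periods, values=values)


#: Covariate sampling ranges: name -> ((rural lo, hi), (urban lo, hi)), percent.
COVARIATE_RANGES = {
    "female": ((47.0, 56.0), (47.0, 56.0)),
    "elderly": ((17.0, 28.0), (12.0, 22.0)),
    "white": ((88.0, 100.0), (65.0, 95.0)),
    "poverty": ((3.0, 15.0), (3.0, 15.0)),
    "employed": ((45.0, 68.0), (48.0, 68.0)),
    "education": ((44.0, 65.0), (55.0, 80.0)),
    "smoking": ((35.0, 56.0), (32.0, 52.0)),
    "alcohol": ((1.0, 12.0), (1.0, 9.0)),
    "obesity": ((22.0, 42.0), (20.0, 40.0)),
}

#: Planted coefficients of the three outcome models. "greenspace" is the
#: TIN exposure of the configured scheme; effect_beta_tin_on_exercise
#: overrides the exercise/greenspace entry at generation time.
TRUE_COEFFICIENTS = {
    "exercise": {
        "intercept": 74.0,
        "greenspace": 0.8,
        "urban": 0.5,
        "female": 0.16,
        "elderly": -0.39,
        "white": 0.02,
        "poverty": -0.27,
        "employed": -0.04,
        "education": -0.02,
        "smoking": -0.07,
        "alcohol": 0.08,
        "obesity": -0.17,
    },
    "physical_health": {
        "intercept": 32.0,
        "greenspace": 0.0,
        "urban": 0.3,
        "female": 0.62,
        "elderly": -0.38,
        "white": 0.0,
        "poverty": 0.38,
        "employed": 0.02,
        "education": -0.2,
        "smoking": 0.05,
        "alcohol": -0.3,
        "obesity": 0.08,
        "exercise": -0.2,
    },
    "mental_health": {
        "intercept": 12.0,
        "greenspace": 0.0,
        "urban": 0.2,
        "female": 0.75,
        "elderly": -0.92,
        "white": 0.01,
        "poverty": 0.34,
        "employed": -0.15,
        "education": -0.06,
        "smoking": 0.08,
        "alcohol": 0.04,
        "obesity": 0.03,
        "exercise": 0.1,
    },
}


def generate_health(
    world: SyntheticWorld,
    exposure: pd.DataFrame,
    config: WorldConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Generate the county health table from planted linear models.

    ``exposure`` is a tidy exposure table (county_id, scheme, buffer_m,
    metric, value); the TIN column of ``config.health_exposure_scheme``
    at buffer 0 is the greenspace regressor. Covariates are uniform
    draws with urban/rural range shifts; each outcome adds Gaussian
    noise with sd ``health_noise_sd`` and is clipped to [0, 100].

    Returns ``(table, truth)`` where ``truth`` maps each outcome to its
    planted coefficients (the exercise/greenspace entry reflecting
    ``effect_beta_tin_on_exercise``) plus the noise sd.
    """
    config = config or world.config
    rng = np.random.default_rng([config.seed, 33])

    tin = exposure[
        (exposure["scheme"] == config.health_exposure_scheme)
        & (exposure["buffer_m"] == 0)
        & (exposure["metric"] == "TIN")
    ].set_index("county_id")["value"]
    if tin.empty:
        raise ValueError(
            f"exposure table has no TIN values for scheme "
            f"{config.health_exposure_scheme!r} at buffer 0"
        )

    counties = world.counties.sort_values("id").reset_index(drop=True)
    n = len(counties)
    urban = counties["urban"].to_numpy().astype(int)

    table = pd.DataFrame({"county_id": counties["id"], "urban": urban})
    for name, (rural_rng, urban_rng) in COVARIATE_RANGES.items():
        lo = np.where(urban == 1, urban_rng[0], rural_rng[0])
        hi = np.where(urban == 1, urban_rng[1], rural_rng[1])
        table[name] = lo + (hi - lo) * rng.uniform(size=n)

    table["greenspace"] = counties["id"].map(tin).to_numpy()

    truth = {
        out: dict(coefs) for out, coefs in TRUE_COEFFICIENTS.items()
    }
    truth["exercise"]["greenspace"] = config.effect_beta_tin_on_exercise
    truth["noise_sd"] = config.health_noise_sd

    for outcome in ["exercise", "physical_health", "mental_health"]:
        coefs = truth[outcome]
        y = np.full(n, coefs["intercept"], dtype=float)
        for name, b in coefs.items():
            if name == "intercept":
                continue
            y += b * table[name].to_numpy()
        if config.health_noise_sd > 0:
            y += rng.normal(0.0, config.health_noise_sd, size=n)
        table[outcome] = np.clip(y, 0.0, 100.0)

    table = table.drop(columns=["greenspace"])
    return table, truth
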