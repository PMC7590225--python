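"""End-to-end synthetic pipeline assembly.

The library counterpart of the CLI: generate a world, derive greenness,
build every boundary scheme (plus the buffered variants of one scheme),
extract exposure, generate the health table, and run the full
statistical battery. Each stage is an ordinary function so callers can
rerun any slice with modified inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import boundaries as bnd
from . import stats as st
from .exposure import build_exposure_table, exposure_wide
from .greenness import GreennessRaster, PhenologyConfig, compute_greenness
from .synthetic import SyntheticWorld, WorldConfig, generate_health, generate_ndvi_stack, generate_region

log = logging.getLogger(__name__)


@dataclass
class AnalysisBundle:
    """Everything one synthetic end-to-end run produces."""

    world: SyntheticWorld
    greenness: GreennessRaster
    boundary_sets: list
    exposure: pd.DataFrame
    health: pd.DataFrame
    truth: dict
    table1: pd.DataFrame
    correlation: pd.DataFrame
    boundary_grid: pd.DataFrame
    buffer_grid: dict
    health_models: dict
    coverage: dict


def build_boundaries(
    world: SyntheticWorld,
    schemes: list[str] | None = None,
    buffered_scheme: str = "combined",
    buffers: list[float] = bnd.BUFFERS_M,
) -> list[bnd.BoundarySet]:
    """All requested schemes at buffer 0 plus buffered variants of one scheme."""
    schemes = schemes or bnd.SCHEMES
    sets = []
    for scheme in schemes:
        base = bnd.build_boundary(world, scheme)
        sets.append(base)
        if scheme == buffered_scheme:
            for buf in buffers:
                if buf > 0:
                    sets.append(bnd.apply_buffer(base, buf))
        dropped = base.empty_counties()
        log.info(
            "scheme %-10s counties kept=%d dropped=%d",
            scheme,
            len(base.geometries) - len(dropped),
            len(dropped),
        )
    return sets


def run_synthetic(
    config: WorldConfig,
    phenology: PhenologyConfig | None = None,
    schemes: list[str] | None = None,
    buffers: list[float] = bnd.BUFFERS_M,
) -> AnalysisBundle:
    """Run the whole synthetic-mode pipeline deterministically."""
    log.info("generating region: %d counties, seed=%d", config.n_counties, config.seed)
    world = generate_region(config)
    stack = generate_ndvi_stack(world, config)
    green = compute_greenness(stack, phenology)
    bsets = build_boundaries(world, schemes, buffers=buffers)
    exposure = build_exposure_table(green, bsets)
    health, truth = generate_health(world, exposure, config)
    return analyze(world, green, bsets, exposure, health, truth)


def analyze(
    world: SyntheticWorld,
    green: GreennessRaster,
    bsets: list,
    exposure: pd.DataFrame,
    health: pd.DataFrame,
    truth: dict | None = None,
) -> AnalysisBundle:
    """The statistical battery over prepared inputs."""
    wide = exposure_wide(exposure[exposure["buffer_m"] == 0])
    table1_input = health.merge(wide, on="county_id", how="left")
    table1 = st.urban_rural_compare(table1_input)
    correlation = st.pearson_matrix(wide)
    bgrid = st.boundary_grid(health, exposure)
    bufgrid = st.buffer_grid(health, exposure)
    hmodels = st.health_models(health, exposure)
    coverage = bnd.coverage_stats([b for b in bsets if b.buffer_m == 0], world)
    return AnalysisBundle(
        world=world,
        greenness=green,
        boundary_sets=bsets,
        exposure=exposure,
        health=health,
        truth=truth or {},
        table1=table1,
        correlation=correlation,
        boundary_grid=bgrid,
        buffer_grid=bufgrid,
        health_models=hmodels,
        coverage=coverage,
    )
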