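"""Assembly of the six explanatory variables for every species-by-site row.

The individual constructions live in :mod:`beeland.grids` (landscape natural
habitat), :mod:`beeland.landuse` (modification duration),
:mod:`beeland.pesticides` (toxic load) and :mod:`beeland.niche` (thermal
niche position and its climate-change shift); this module wires them to a
world bundle and a survey, producing the covariate table the dataset module
joins onto outcomes.  Sensitivity settings mirror the published robustness
checks: landscape grain 1/2/5 km, conversion thresholds 10/30/50 % and
low/high pesticide application estimates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .climate import BASELINE_PERIOD, RECENT_PERIOD
from .grids import aggregate_fraction, natural_habitat_at, resample_equal_area
from .landuse import modification_duration
from .niche import ThermalNiche, delta_position, niche_position
from .pesticides import toxic_load_map
from .synthetic import Survey, World

__all__ = ["build_covariate_table", "site_covariates", "species_site_positions"]


def site_covariates(
    world: World,
    sites: pd.DataFrame,
    *,
    grain_km: float = 2.0,
    threshold: float = 0.30,
    estimate: str = "low",
    reference_year: float = 2005.0,
) -> pd.DataFrame:
    """Per-site covariates: natural habitat, toxic load, duration, elevation."""
    x = sites["x_km"].to_numpy(float)
    y = sites["y_km"].to_numpy(float)

    nh1 = resample_equal_area(world.natural_src, world.config.fine_grain_km)
    factor = int(round(grain_km / world.config.fine_grain_km))
    nh_grid = aggregate_fraction(nh1, factor) if factor > 1 else nh1
    nh = natural_habitat_at(nh_grid, x, y)

    cells = world.history.cell_containing(x, y, world.config.coarse_cell_km)
    dur = np.array(
        [
            modification_duration(
                world.history.years, world.history.human_fraction[c],
                threshold, reference_year,
            )
            for c in cells
        ]
    )

    tox_map = toxic_load_map(world.pesticides, estimate)
    ix, iy = world.pesticides.cell_index(x, y)
    tox = tox_map[iy, ix]

    elev = world.elevation.value_at(x, y)
    out = sites[["study_id", "site_id", "x_km", "y_km", "land_use_class"]].copy()
    out["natural_habitat"] = nh
    out["toxic_load"] = tox
    out["modification_duration"] = dur
    out["elevation"] = elev
    out["climate_cell"] = world.climate.nearest_cell(x, y)
    return out


def species_site_positions(
    world: World,
    sites: pd.DataFrame,
    species: pd.DataFrame,
    *,
    baseline: tuple[int, int] = BASELINE_PERIOD,
    recent: tuple[int, int] = RECENT_PERIOD,
) -> pd.DataFrame:
    """Baseline niche position and its recent shift for each species x climate cell.

    Positions depend only on the climate cell, so they are computed once per
    unique cell and broadcast to the sites within it.
    """
    cells = np.unique(world.climate.nearest_cell(
        sites["x_km"].to_numpy(float), sites["y_km"].to_numpy(float)))
    rows = []
    for _, srow in species.iterrows():
        niche = ThermalNiche(srow["species"], srow["niche_min"], srow["niche_max"])
        for c in cells:
            base = niche_position(int(c), baseline, niche, world.climate)
            rows.append(
                {
                    "species": srow["species"],
                    "climate_cell": int(c),
                    "baseline_position": base,
                    "delta_position": delta_position(
                        int(c), niche, world.climate, baseline, recent
                    ),
                }
            )
    return pd.DataFrame(rows)


def build_covariate_table(
    world: World,
    survey: Survey,
    *,
    grain_km: float = 2.0,
    threshold: float = 0.30,
    estimate: str = "low",
    reference_year: float = 2005.0,
) -> pd.DataFrame:
    """Species-by-site covariate table for every targeted species x site row."""
    per_site = site_covariates(
        world, survey.sites, grain_km=grain_km, threshold=threshold,
        estimate=estimate, reference_year=reference_year,
    )
    positions = species_site_positions(world, survey.sites, survey.species)
    rows = survey.targets.merge(per_site, on="study_id", how="inner")
    rows = rows.merge(positions, on=["species", "climate_cell"], how="left")
    return rows.drop(columns=["climate_cell"])
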