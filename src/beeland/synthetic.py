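"""Synthetic study system: landscapes, histories, climate, pesticides and surveys.

This module generates a self-contained world on an equal-area km plane —
fractional natural-habitat cover, a land-use history per coarse cell, a
monthly min/max temperature series (1901-2015) with a post-1960 warming ramp,
per-crop pesticide application surfaces with an LD50 lookup, and elevation —
and a multi-study survey whose species' presence/absence outcomes are drawn
from the same hierarchical logistic model the inference modules fit, with
known ground-truth coefficients.  Everything is driven by a single integer
seed and is bit-reproducible.

Default scale (40 studies x 15 sites x 8 species, ~4800 species-by-site rows)
keeps a full 4-chain MCMC fit to a few minutes on one CPU while leaving
enough information to recover all fifteen fixed effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .climate import BASELINE_PERIOD, ClimateSeries
from .grids import Grid, aggregate_fraction, resample_equal_area, write_ascii_grid
from .landuse import LandUseHistory
from .pesticides import PesticideTable

__all__ = [
    "WorldConfig",
    "TrueParameters",
    "World",
    "Survey",
    "ConfigError",
    "SimulationDataError",
    "generate_world",
    "generate_survey",
    "simulate_occurrence",
    "records_from_outcomes",
]

LAND_USE_NATURAL = "natural"
LAND_USE_HUMAN = "human_modified"

HISTORY_CLASSES = ("primary", "secondary", "cropland", "pasture", "urban")


class ConfigError(ValueError):
    pass


class SimulationDataError(ValueError):
    pass


@dataclass(frozen=True)
class WorldConfig:
    """Extent, resolution and dynamic rates of the synthetic world.

    The landscape spans ``extent_km`` squared.  Source land-cover is generated
    at ``source_grain_km`` (resampled to 1 km by the covariate pipeline, as
    for the real 30-arc-second product), coarse history/climate cells are
    ``coarse_cell_km`` squared (the 0.5° analogue) and pesticide application
    cells ``pesticide_cell_km`` (the 5-arc-minute analogue).
    ``conversion_rate`` scales the logistic human-conversion dynamics; zero
    freezes every history series at its initial fraction.
    """

    extent_km: float = 400.0
    source_grain_km: float = 1.25
    fine_grain_km: float = 1.0
    coarse_cell_km: float = 50.0
    pesticide_cell_km: float = 10.0
    history_years: tuple[int, int] = (1500, 2005)
    climate_years: tuple[int, int] = (1901, 2015)
    n_crops: int = 10
    n_ingredients: int = 20
    conversion_rate: float = 1.0
    warming_degC: float = 1.3     # mean cell warming reached by the final year
    seed: int = 0

    def __post_init__(self) -> None:
        if self.extent_km <= 0 or self.source_grain_km <= 0:
            raise ConfigError("extent and grains must be positive")
        if self.history_years[0] >= self.history_years[1]:
            raise ConfigError("history year range must be increasing")
        if self.climate_years[0] >= self.climate_years[1]:
            raise ConfigError("climate year range must be increasing")
        if self.n_crops < 1 or self.n_crops > 10 or self.n_ingredients < 1 or self.n_ingredients > 20:
            raise ConfigError("crops must be 1-10 and ingredients 1-20")


# design-matrix column order shared with beeland.design
FIXED_EFFECT_LABELS = (
    "intercept",
    "landuse_human",
    "natural_habitat",
    "log_toxic_load",
    "modification_duration",
    "baseline_position",
    "baseline_position_sq",
    "delta_position",
    "log_elevation",
    "landuse_human:natural_habitat",
    "landuse_human:log_toxic_load",
    "landuse_human:modification_duration",
    "landuse_human:baseline_position",
    "landuse_human:baseline_position_sq",
    "landuse_human:delta_position",
)


@dataclass(frozen=True)
class TrueParameters:
    """Ground-truth generative parameters on the centred/scaled covariate scale."""

    beta: dict[str, float]
    sigma_study: float = 0.8
    sigma_site: float = 0.5
    sigma_species: float = 0.6

    def __post_init__(self) -> None:
        if min(self.sigma_study, self.sigma_site, self.sigma_species) < 0:
            raise ConfigError("random-effect standard deviations must be >= 0")
        unknown = set(self.beta) - set(FIXED_EFFECT_LABELS)
        if unknown:
            raise ConfigError(f"unknown coefficient labels: {sorted(unknown)}")

    def vector(self, labels=FIXED_EFFECT_LABELS) -> np.ndarray:
        return np.array([self.beta.get(lab, 0.0) for lab in labels])

    @classmethod
    def default(cls) -> "TrueParameters":
        """Effects qualitatively mirroring the field system being emulated:
        pressures harm occurrence, natural habitat helps (especially in human
        land uses), pesticide toxicity bites hardest in natural habitat, the
        niche response is hump-shaped and flatter under human land use, and
        warming-driven niche shifts hurt in natural but help in human habitat."""
        return cls(
            beta={
                "intercept": -0.3,
                "landuse_human": -0.4,
                "natural_habitat": 0.5,
                "log_toxic_load": -0.45,
                "modification_duration": -0.35,
                "baseline_position": 0.3,
                "baseline_position_sq": -0.45,
                "delta_position": -0.3,
                "log_elevation": -0.25,
                "landuse_human:natural_habitat": 0.35,
                "landuse_human:log_toxic_load": 0.3,
                "landuse_human:modification_duration": -0.25,
                "landuse_human:baseline_position": 0.3,
                "landuse_human:baseline_position_sq": 0.35,
                "landuse_human:delta_position": 0.45,
            }
        )

    @classmethod
    def null(cls) -> "TrueParameters":
        return cls(beta={}, sigma_study=0.0, sigma_site=0.0, sigma_species=0.0)


@dataclass
class World:
    config: WorldConfig
    natural_src: Grid            # fractional natural cover at source grain
    elevation: Grid              # metres, 1-km grain
    history: LandUseHistory
    class_fractions: np.ndarray  # (n_cells, T, 5) for HISTORY_CLASSES
    climate: ClimateSeries
    pesticides: PesticideTable

    def write(self, directory: str | Path) -> None:
        """Serialise the bundle in plain-text formats (.asc rasters + CSV tables)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_ascii_grid(self.natural_src, directory / "natural_cover_source.asc")
        write_ascii_grid(self.elevation, directory / "elevation_m.asc")
        self.history.write_csv(directory / "landuse_history.csv")
        self.climate.write_csv(directory / "climate_monthly.csv")
        self.pesticides.write_csv(directory)


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Unit-variance Gaussian random field with correlation length ~sigma cells."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    return (f - f.mean()) / (f.std() + 1e-12)


def generate_world(config: WorldConfig | None = None, seed: int | None = None) -> World:
    """Build the full synthetic world bundle for a configuration."""
    config = config or WorldConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ext = config.extent_km

    # --- fractional natural-habitat cover on the source grid -------------
    n_src = int(round(ext / config.source_grain_km))
    trend_y, trend_x = np.meshgrid(
        np.linspace(-0.5, 0.5, n_src), np.linspace(-0.5, 0.5, n_src), indexing="ij"
    )
    nat = expit(
        1.6 * _smooth_field(rng, (n_src, n_src), sigma=8)
        + 1.2 * trend_y - 0.6 * trend_x + 0.1
    )
    natural_src = Grid(nat, 0.0, 0.0, config.source_grain_km)

    # --- elevation (1-km, metres) ----------------------------------------
    n_fine = int(round(ext / config.fine_grain_km))
    elev = 420.0 * _smooth_field(rng, (n_fine, n_fine), sigma=25) + 450.0
    elev += 500.0 * np.meshgrid(
        np.linspace(0, 1, n_fine), np.linspace(0, 1, n_fine), indexing="ij"
    )[0] ** 2
    elevation = Grid(np.clip(elev, 0.0, None), 0.0, 0.0, config.fine_grain_km)

    # --- coarse cells shared by history and climate -----------------------
    n_coarse = int(round(ext / config.coarse_cell_km))
    cx, cy = np.meshgrid(
        (np.arange(n_coarse) + 0.5) * config.coarse_cell_km,
        (np.arange(n_coarse) + 0.5) * config.coarse_cell_km,
    )
    cell_x, cell_y = cx.ravel(), cy.ravel()
    n_cells = cell_x.size

    # end-state human fraction consistent with the fine natural map
    block = int(round(config.coarse_cell_km / config.source_grain_km))
    human_end = 1.0 - nat.reshape(n_coarse, block, n_coarse, block).mean(axis=(1, 3))
    human_end = human_end.ravel()

    # --- land-use history: logistic conversion with varying onset ---------
    y0, y1 = config.history_years
    years = np.array(
        sorted(set(range(y0, min(1700, y1) + 1, 100))
               | set(range(1700, y1 + 1, 10)) | {y1})
    )
    h_max = np.clip(human_end + rng.normal(0, 0.05, n_cells), 0.02, 0.97)
    onset = rng.uniform(1600, 1980, n_cells)
    rate = rng.uniform(0.04, 0.20, n_cells) * config.conversion_rate
    if config.conversion_rate == 0:
        human = np.repeat(
            (h_max / (1 + np.exp(0.0)))[:, None], years.size, axis=1
        )  # frozen at the initial fraction
    else:
        human = h_max[:, None] / (1 + np.exp(-rate[:, None] * (years[None, :] - onset[:, None])))
    human = np.clip(human, 0.0, 1.0)

    # split into the five reconstruction classes, summing to 1 per cell/time
    crop_w = rng.dirichlet(np.array([4.0, 2.5, 1.0]), size=n_cells)  # crop/pasture/urban
    q_primary = np.clip(rng.beta(4, 2, n_cells), 0.05, 0.98)
    class_frac = np.empty((n_cells, years.size, 5))
    natural_part = 1.0 - human
    class_frac[:, :, 0] = natural_part * q_primary[:, None]
    class_frac[:, :, 1] = natural_part * (1 - q_primary[:, None])
    for k in range(3):
        class_frac[:, :, 2 + k] = human * crop_w[:, k][:, None]
    history = LandUseHistory(years.astype(float), human, cell_x, cell_y)

    # --- monthly climate with post-1960 warming ramp ----------------------
    cy0, cy1 = config.climate_years
    cyears = np.arange(cy0, cy1 + 1)
    months = np.arange(12)
    base = 16.0 + 12.0 * (1.0 - cell_y / ext) + 1.5 * rng.standard_normal(n_cells)
    amp = 9.0 + rng.normal(0, 1.0, n_cells)
    warm = np.clip(rng.normal(config.warming_degC, 0.2, n_cells), 0.0, None)
    season = -np.cos(2 * np.pi * (months + 0.5) / 12.0)
    ramp = np.clip((cyears - 1960) / (cy1 - 1960), 0.0, 1.0)
    tmax = (
        base[:, None, None]
        + amp[:, None, None] * season[None, None, :]
        + warm[:, None, None] * ramp[None, :, None]
        + rng.normal(0, 0.6, (n_cells, cyears.size, 12))
    )
    gap = np.clip(6.0 + 2.0 * np.abs(rng.standard_normal((n_cells, cyears.size, 12)))
                  + rng.normal(0, 0.5, (n_cells, cyears.size, 12)), 2.0, None)
    climate = ClimateSeries(cyears, tmax - gap, tmax, cell_x, cell_y)

    # --- pesticide application surfaces + LD50 lookup ---------------------
    n_app = int(round(ext / config.pesticide_cell_km))
    # cropland intensity at application resolution, tied to the human end-state
    crop_end = (class_frac[:, -1, 2]).reshape(n_coarse, n_coarse)
    rep = int(round(config.coarse_cell_km / config.pesticide_cell_km))
    crop_fine = np.kron(crop_end, np.ones((rep, rep)))
    crop_fine = np.clip(crop_fine + 0.15 * _smooth_field(rng, crop_fine.shape, 2.0), 0.0, 1.0)

    crops = tuple(f"crop_{i + 1}" for i in range(config.n_crops))
    ingredients = tuple(f"ai_{i + 1}" for i in range(config.n_ingredients))
    dens = np.zeros((config.n_crops, config.n_ingredients, n_app, n_app))
    for c in range(config.n_crops):
        occupied = crop_fine > rng.uniform(0.15, 0.45)
        use_rate = rng.uniform(0.1, 0.9, config.n_ingredients)  # fraction of cells treated
        for i in range(config.n_ingredients):
            treated = occupied & (rng.random((n_app, n_app)) < use_rate[i])
            level = rng.lognormal(mean=-3.0, sigma=1.0)
            dens[c, i] = np.where(treated, level * crop_fine
                                  * rng.lognormal(0.0, 0.5, (n_app, n_app)), 0.0)
    high = dens * rng.uniform(1.2, 2.5, (config.n_crops, config.n_ingredients))[:, :, None, None]
    ld50 = np.exp(rng.normal(0.0, 2.0, config.n_ingredients))
    n_missing = max(1, round(0.1 * config.n_ingredients))
    ld50[rng.choice(config.n_ingredients, n_missing, replace=False)] = np.nan
    pesticides = PesticideTable(crops, ingredients, dens, high, ld50,
                                0.0, 0.0, config.pesticide_cell_km)

    return World(config, natural_src, elevation, history, class_frac, climate, pesticides)


@dataclass
class Survey:
    """Study-structured survey skeleton: sites, targeted species and true niches."""

    sites: pd.DataFrame        # study_id, site_id, x_km, y_km, land_use_class
    targets: pd.DataFrame      # study_id, species
    species: pd.DataFrame      # species, niche_min, niche_max

    def skeleton_rows(self) -> pd.DataFrame:
        """All targeted species x site rows per study (outcomes not yet drawn)."""
        return self.sites.merge(self.targets, on="study_id", how="inner")


def generate_survey(
    world: World,
    n_studies: int = 40,
    sites_per_study: int = 15,
    species_pool: int = 8,
    seed: int = 1,
    *,
    force_class: str | None = None,
    nh_grain_km: float = 2.0,
) -> Survey:
    """Place studies and sites, assign local land-use classes and target species.

    Sites cluster around study centres (sd 10 km).  The local class is drawn
    with a probability weakly tied to surrounding natural habitat, emulating
    the deliberately loose association between local land use and landscape
    habitat; ``force_class`` pins every site to one class for tests.
    """
    if n_studies < 1 or species_pool < 1:
        raise ConfigError("n_studies and species_pool must be >= 1")
    if species_pool == 0:
        raise ConfigError("species pool must not be empty")
    if sites_per_study < 2:
        raise ConfigError("each study needs at least 2 sites")
    rng = np.random.default_rng(seed)
    ext = world.config.extent_km
    margin = 35.0

    nh1 = resample_equal_area(world.natural_src, world.config.fine_grain_km)
    nh = aggregate_fraction(nh1, int(round(nh_grain_km / world.config.fine_grain_km)))

    rows = []
    for s in range(n_studies):
        cx0, cy0 = rng.uniform(margin, ext - margin, 2)
        xs = np.clip(cx0 + rng.normal(0, 10.0, sites_per_study), 0.5, ext - 0.5)
        ys = np.clip(cy0 + rng.normal(0, 10.0, sites_per_study), 0.5, ext - 0.5)
        for k in range(sites_per_study):
            rows.append((f"study_{s + 1:03d}", f"study_{s + 1:03d}_site_{k + 1:03d}",
                         xs[k], ys[k]))
    sites = pd.DataFrame(rows, columns=["study_id", "site_id", "x_km", "y_km"])

    nh_site = nh.value_at(sites["x_km"].to_numpy(), sites["y_km"].to_numpy())
    if force_class is not None:
        sites["land_use_class"] = force_class
    else:
        # coupling 0.45 keeps the class/habitat ANOVA R² weak (~0.05-0.08),
        # the regime the emulated survey structure exhibits
        p_human = np.clip(0.5 - 0.45 * (nh_site - float(np.mean(nh_site))), 0.05, 0.95)
        sites["land_use_class"] = np.where(
            rng.random(len(sites)) < p_human, LAND_USE_HUMAN, LAND_USE_NATURAL
        )

    # targeted species per study: a subset of the pool, always non-empty
    species_names = [f"species_{i + 1:02d}" for i in range(species_pool)]
    tgt = []
    lo = max(1, int(round(0.75 * species_pool)))
    for s in range(n_studies):
        k = int(rng.integers(lo, species_pool + 1))
        chosen = rng.choice(species_names, size=k, replace=False)
        tgt.extend((f"study_{s + 1:03d}", sp) for sp in sorted(chosen))
    targets = pd.DataFrame(tgt, columns=["study_id", "species"])

    # true realised niches spanning baseline positions ~0.1-0.9
    ymask = world.climate.year_mask(BASELINE_PERIOD)
    cell_mean_tmax = world.climate.tmax[:, ymask, :].mean(axis=(1, 2))
    t_ref = float(cell_mean_tmax.mean())
    targets_pos = rng.permutation(np.linspace(0.1, 0.9, species_pool))
    width = rng.uniform(16.0, 26.0, species_pool)
    species = pd.DataFrame(
        {
            "species": species_names,
            "niche_min": t_ref - targets_pos * width,
            "niche_max": t_ref - targets_pos * width + width,
        }
    )
    return Survey(sites, targets, species)


REQUIRED_DESIGN_COLUMNS = (
    "z_natural_habitat",
    "z_log_toxic_load",
    "z_modification_duration",
    "z_baseline_position",
    "z_delta_position",
    "z_log_elevation",
)


def simulate_occurrence(
    model_table: pd.DataFrame,
    params: TrueParameters,
    seed: int = 2,
    *,
    return_effects: bool = False,
    spatial_noise_sd: float = 0.0,
    spatial_range_km: float = 15.0,
):
    """Draw presence/absence for every species-by-site row of a model table.

    The table must already carry the centred/scaled covariates (see
    ``beeland.dataset``).  Study, site and species intercepts are drawn once
    per level from centred normals with the configured standard deviations;
    outcomes are Bernoulli draws on the inverse-logit of the linear predictor.
    ``spatial_noise_sd`` optionally injects spatially correlated site noise
    (exponential correlation over inter-site distance) so residual
    autocorrelation diagnostics have signal to find.
    """
    from .design import build_design_matrix  # deferred: avoids import cycle

    for col in ("study_id", "site_id", "species") + REQUIRED_DESIGN_COLUMNS:
        if col not in model_table.columns:
            raise SimulationDataError(f"model table lacks required column {col!r}")
        bad = model_table[col].isna()
        if bad.any():
            row = model_table.loc[bad.idxmax()]
            raise SimulationDataError(
                f"missing covariate {col!r} for row "
                f"(site={row['site_id']!r}, species={row['species']!r})"
            )

    rng = np.random.default_rng(seed)
    X, labels = build_design_matrix(model_table)
    beta = params.vector(labels)

    studies, study_idx = np.unique(model_table["study_id"], return_inverse=True)
    sites_u, site_idx = np.unique(model_table["site_id"], return_inverse=True)
    species_u, sp_idx = np.unique(model_table["species"], return_inverse=True)
    u_study = rng.normal(0.0, params.sigma_study, studies.size)
    u_site = rng.normal(0.0, params.sigma_site, sites_u.size)
    u_species = rng.normal(0.0, params.sigma_species, species_u.size)

    if spatial_noise_sd > 0:
        site_xy = (
            model_table.drop_duplicates("site_id").set_index("site_id")
            .loc[sites_u, ["x_km", "y_km"]].to_numpy(float)
        )
        d = np.hypot(site_xy[:, None, 0] - site_xy[None, :, 0],
                     site_xy[:, None, 1] - site_xy[None, :, 1])
        cov = spatial_noise_sd**2 * np.exp(-d / spatial_range_km)
        cov[np.diag_indices_from(cov)] += 1e-9
        u_site = u_site + np.linalg.cholesky(cov) @ rng.standard_normal(sites_u.size)

    eta = X @ beta + u_study[study_idx] + u_site[site_idx] + u_species[sp_idx]
    p = expit(eta)
    out = model_table.copy()
    out["outcome"] = (rng.random(len(out)) < p).astype(int)
    if return_effects:
        effects = {
            "p": p,
            "u_study": dict(zip(studies, u_study)),
            "u_site": dict(zip(sites_u, u_site)),
            "u_species": dict(zip(species_u, u_species)),
        }
        return out, effects
    return out


def records_from_outcomes(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Presence records only (the raw-survey view the absence-inference step sees)."""
    keep = [c for c in ("study_id", "site_id", "species", "x_km", "y_km",
                        "land_use_class") if c in outcomes.columns]
    return outcomes.loc[outcomes["outcome"] == 1, keep].reset_index(drop=True)
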