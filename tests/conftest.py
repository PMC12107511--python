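"""Shared fixtures: a small synthetic world and a fast end-to-end fitted study.

Everything is generated at test time from fixed seeds; nothing is read from
disk.  The `small_study` fixture runs the entire chain (world -> survey ->
covariates -> absences -> MCMC -> diagnostics -> counterfactual) once per
session at a reduced scale so that many tests can share the fitted object.
"""

import numpy as np
import pandas as pd
import pytest

from beeland.design import ModelSpec
from beeland.experiments import run_full_study
from beeland.synthetic import (
    TrueParameters,
    WorldConfig,
    generate_survey,
    generate_world,
)


@pytest.fixture(scope="session")
def small_config():
    return WorldConfig(extent_km=200.0, seed=11)


@pytest.fixture(scope="session")
def small_world(small_config):
    return generate_world(small_config)


@pytest.fixture(scope="session")
def small_survey(small_world):
    return generate_survey(small_world, n_studies=8, sites_per_study=10,
                           species_pool=6, seed=12)


@pytest.fixture(scope="session")
def small_study():
    """A complete fitted study at reduced scale (seconds, not minutes)."""
    return run_full_study(
        seed=20240611,
        n_studies=8,
        sites_per_study=10,
        species_pool=6,
        spec=ModelSpec(chains=2, warmup=300, samples=300),
        config=WorldConfig(extent_km=200.0, seed=0),
        n_counterfactual_draws=200,
        moran_permutations=199,
    )


def random_model_table(n_rows: int, seed: int, n_studies: int = 10,
                       sites_per_study: int = 10, n_species: int = 6,
                       land_use=None) -> pd.DataFrame:
    """Model-ready table with random scaled covariates (no world needed)."""
    rng = np.random.default_rng(seed)
    study = rng.integers(0, n_studies, n_rows)
    site_within = rng.integers(0, sites_per_study, n_rows)
    rows = pd.DataFrame(
        {
            "study_id": [f"s{j:03d}" for j in study],
            "site_id": [f"s{j:03d}_k{k:03d}" for j, k in zip(study, site_within)],
            "species": [f"sp{j:02d}" for j in rng.integers(0, n_species, n_rows)],
            "land_use_class": rng.choice(["natural", "human_modified"], n_rows)
            if land_use is None else land_use,
            "x_km": rng.uniform(0, 100, n_rows),
            "y_km": rng.uniform(0, 100, n_rows),
        }
    )
    for col in ("z_natural_habitat", "z_log_toxic_load", "z_modification_duration",
                "z_baseline_position", "z_delta_position", "z_log_elevation"):
        rows[col] = rng.standard_normal(n_rows)
    return rows
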