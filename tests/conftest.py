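"""Shared fixtures: small synthetic worlds and a ready-made SDM problem.

Everything is generated in-process from seeded generators; no data files.
The SDM problem is deliberately small (40×40 grid, 150 presences, 400
pseudo-absences per set) so the full learner × PA-set × run grid stays fast.
"""

import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")

from hydrotherm import indexes, sdm, synthetic_world as sw
from hydrotherm.grids import GridSpec, Raster


@pytest.fixture(scope="session")
def flat_world():
    """Noise-free world with a pure latitudinal temperature gradient.

    The DEM is flat and precipitation varies only with longitude, so WI is
    uniform over rows and the occurrence-sampling kernel's symmetry makes the
    species-mean WI an unbiased estimator of the planted optimum.
    """
    cfg = sw.WorldConfig(
        seed=5, noise_sd_temp=0.0, noise_sd_precip=0.0,
        alt_base=0.0, alt_lon_slope=0.0, alt_lat_slope=0.0, lat_gradient=1.2,
    )
    dem = sw.generate_dem(cfg)
    wi, ci, hi = sw.generate_true_index_surfaces(cfg, dem)
    return {"cfg": cfg, "dem": dem, "wi": wi, "ci": ci, "hi": hi}


def _suitability_layers(cfg: sw.WorldConfig, seed: int = 11):
    """Environmental stack derived from the world's climate fields."""
    dem = sw.generate_dem(cfg)
    lon, lat = cfg.grid.center_mesh()
    temps = cfg.monthly_temperature(lon, lat, dem.values)
    bio1 = temps.mean(axis=-1)
    bio12 = cfg.annual_precip(lon)
    rng = np.random.default_rng(seed)
    layers = {
        "bio1": Raster(cfg.grid, bio1, "bio1"),
        "bio12": Raster(cfg.grid, bio12, "bio12"),
        "elev": Raster(cfg.grid, dem.values, "elev"),
        # near-duplicate of bio1: must fall to the Pearson pass
        "bio1_dup": Raster(cfg.grid, bio1 * 0.97 + rng.normal(0, 0.05, bio1.shape),
                           "bio1_dup"),
        # independent noise layer: should survive screening
        "noise": Raster(cfg.grid, rng.normal(0, 1, bio1.shape), "noise"),
    }
    return layers


@pytest.fixture(scope="session")
def sdm_problem():
    """A strongly structured virtual-species niche on a 40×40 grid."""
    cfg = sw.WorldConfig(
        lon_min=100.0, lon_max=105.0, lat_min=35.0, lat_max=40.0,
        resolution_arcmin=7.5, seed=2, noise_sd_temp=0.0, noise_sd_precip=0.0,
        lat_gradient=1.6, alt_base=800.0, alt_lon_slope=-60.0, alt_lat_slope=30.0,
        precip_base=150.0, precip_lon_gradient=60.0,
    )
    dem = sw.generate_dem(cfg)
    wi, ci, hi = sw.generate_true_index_surfaces(cfg, dem)
    species = sw.SpeciesSpec(
        "virtualis", wi_optimum=float(np.median(wi.values)), wi_tolerance=2.0,
        hi_optimum=float(np.nanmedian(hi.values)), hi_tolerance=1.0,
        n_occurrences=150, seed=9,
    )
    occ = sw.generate_occurrences(species, wi, hi)
    stack = sdm.EnvStack(_suitability_layers(cfg))
    scenario = sdm.EnvStack(
        sw.generate_scenario_climate(
            stack.layers, delta_t=2.0, delta_p_fraction=0.1,
            temperature_keys=("bio1",), precipitation_keys=("bio12",),
        )
    )
    return {
        "cfg": cfg, "wi": wi, "ci": ci, "hi": hi, "species": species,
        "occ": occ, "stack": stack, "scenario": scenario,
    }


@pytest.fixture(scope="session")
def sdm_config():
    return sdm.SdmConfig(
        learners=("glm", "rf", "gbm"), n_runs=10, n_pa_sets=2,
        n_pa_per_set=400, tss_min=0.55, seed=13,
    )


@pytest.fixture(scope="session")
def sdm_result(sdm_problem, sdm_config):
    occ = sdm_problem["occ"]
    return sdm.run_sdm_pipeline(
        sdm_problem["stack"], occ["lon"], occ["lat"], sdm_config,
        scenarios={"warmed": sdm_problem["scenario"]},
    )


@pytest.fixture()
def unit_grid():
    """A tiny 4×4 grid over 1°×1° for geometry-level tests."""
    return GridSpec(0.0, 0.0, 1.0, 1.0, resolution_arcmin=15.0)


def station_table_from_world(cfg):
    return indexes.station_indexes(sw.generate_station_network(cfg))
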