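import numpy as np
import pytest

from strikerisk.core import load_species_defaults
from strikerisk.pipeline import RunConfig, compute_surfaces, prepare_inputs
from strikerisk.synthetic import default_scenario, write_fixtures


@pytest.fixture(scope="session")
def species():
    return load_species_defaults()


@pytest.fixture(scope="session")
def scenario():
    return default_scenario(seed=7)


def config_for(manifest, spec, out_dir):
    return RunConfig(
        ais_csv=manifest["ais"],
        density_csvs={sp: manifest[f"density_{sp}"] for sp in ("blue", "humpback", "fin")},
        dive_csvs={sp: manifest[f"dives_{sp}"] for sp in ("blue", "humpback", "fin")},
        strandings_csv=manifest["strandings"],
        jurisdictions_geojson=manifest["jurisdictions"],
        bathymetry_csv=manifest["bathymetry"],
        grid_x0=spec.grid_x0, grid_y0=spec.grid_y0,
        grid_nx=spec.grid_nx, grid_ny=spec.grid_ny, cell_size_m=spec.cell_size_m,
        months=spec.months, seed=spec.seed,
        output_dir=str(out_dir),
    )


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory, scenario):
    out = tmp_path_factory.mktemp("fixtures")
    manifest = write_fixtures(scenario, out)
    return manifest, out


@pytest.fixture(scope="session")
def run_config(fixture_paths, scenario):
    manifest, out = fixture_paths
    return config_for(manifest, scenario, out / "results")


@pytest.fixture(scope="session")
def processed_inputs(run_config):
    return prepare_inputs(run_config)


@pytest.fixture(scope="session")
def run_result(processed_inputs, run_config):
    return compute_surfaces(processed_inputs, run_config)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
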