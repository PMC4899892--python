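import pytest

from taxevo.synthetic_data import (
    SimulationConfig,
    generate_stage_series,
    write_fixture_bundle,
    write_pipeline_config,
)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(random_seed=1)


@pytest.fixture(scope="session")
def default_output(default_config):
    return generate_stage_series(default_config)


@pytest.fixture(scope="session")
def bundle_dir(default_output, tmp_path_factory):
    directory = tmp_path_factory.mktemp("bundle")
    write_fixture_bundle(default_output, directory)
    write_pipeline_config(default_output, directory)
    return directory
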