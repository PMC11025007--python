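import pytest

from paralogsl import SyntheticConfig, generate_panel


@pytest.fixture(scope="session")
def panel7():
    """Default synthetic panel, seed 7 (53 lines, 200 families, 3 SL pairs)."""
    return generate_panel(SyntheticConfig(rng_seed=7))


@pytest.fixture(scope="session")
def bundle7(panel7, tmp_path_factory):
    from paralogsl import write_fixture_bundle

    directory = tmp_path_factory.mktemp("bundle7")
    paths = write_fixture_bundle(panel7, directory)
    return directory, paths
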