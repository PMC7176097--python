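import warnings

import pytest
from hypothesis import settings

from deltacarbon.synth import ARCHETYPES, GeneratorConfig, write_fixture_set

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A full synthetic fixture set at the default study conditions, seed 1."""
    outdir = tmp_path_factory.mktemp("fixtures")
    write_fixture_set(outdir, GeneratorConfig(seed=1))
    return outdir


@pytest.fixture(scope="session")
def pipeline_results(fixture_dir):
    """End-to-end pipeline output on the seed-1 fixtures."""
    from deltacarbon.pipeline import run_pipeline

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(fixture_dir)


@pytest.fixture
def noiseless_config():
    return GeneratorConfig(seed=3, cv=0.0)


@pytest.fixture(params=sorted(ARCHETYPES))
def archetype(request):
    return ARCHETYPES[request.param]
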