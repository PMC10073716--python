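import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "upm", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("upm")

from upmprofiler.cli import PipelineConfig
from upmprofiler.synthetic_data import make_toy_data, make_toy_fixture


@pytest.fixture(scope="session")
def toy_data():
    """In-memory hand-checkable bundle (46 PSMs, 3 proteins)."""
    return make_toy_data()


@pytest.fixture(scope="session")
def toy_bundle(tmp_path_factory):
    """The toy bundle written to disk: (paths dict, ground truth)."""
    out = tmp_path_factory.mktemp("toy_bundle")
    return make_toy_fixture(out)


@pytest.fixture(scope="session")
def toy_pipeline_config(toy_bundle):
    paths, _ = toy_bundle
    return PipelineConfig(
        psm=str(paths["psm"]), fasta=str(paths["fasta"]),
        domains=str(paths["domains"]), markers=str(paths["markers"]),
        clinical=str(paths["clinical"]), categories=str(paths["categories"]),
        exosome_markers=str(paths["exosome_markers"]),
        microvesicle_markers=str(paths["microvesicle_markers"]),
        seed=7)
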