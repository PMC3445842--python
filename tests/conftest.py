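import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from homeolocus.fixture import build_paper_fixture
from homeolocus.params import AnalysisParams
from homeolocus.pipeline import run_pipeline

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def params():
    return AnalysisParams()


@pytest.fixture(scope="session")
def paper_fixture():
    return build_paper_fixture(seed=11)


@pytest.fixture(scope="session")
def paper_result(paper_fixture):
    return run_pipeline(
        paper_fixture.loci,
        ests=paper_fixture.ests,
        reference_db=paper_fixture.reference_db,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
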