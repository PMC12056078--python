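import pytest
from hypothesis import settings

from megatx import pipelines

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def scenario():
    """The default synthetic case-study scenario, shared across tests."""
    return pipelines.default_scenario(seed=1)


@pytest.fixture(scope="session")
def error_free_reads(scenario):
    reads, truth = pipelines.scenario_reads(scenario, seed=1)
    return reads, truth


@pytest.fixture(scope="session")
def chromosome_only_reads(scenario):
    """Reads drawn from the chromosome alone (circle weight zero)."""
    reads, truth = pipelines.scenario_reads(
        scenario, seed=2, circle_weight=0.0, total_bases=400_000
    )
    return reads, truth
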