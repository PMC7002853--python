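import pytest
from hypothesis import HealthCheck, settings

from meandiff import SampleSummary, TwoSampleDesign, summarize

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# The two five-element worked-example vectors used throughout the docs.
DATA1 = (0.0, 1.0, 2.0, 3.0, 4.0)
DATA2 = (0.0, 0.0, 1.0, 2.0, 2.0)


@pytest.fixture
def example_design() -> TwoSampleDesign:
    return TwoSampleDesign.from_data(DATA1, DATA2)


@pytest.fixture
def example_param_design() -> TwoSampleDesign:
    # Summary-parameter entry: N(1, 2) with n=5 vs N(0, 1) with n=10.
    return TwoSampleDesign.from_params(1.0, 0.0, 2.0, 1.0, 5, 10)


@pytest.fixture
def example_one_sample() -> SampleSummary:
    return summarize(DATA2)
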