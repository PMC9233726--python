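import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def design4x3():
    """4 timepoints x 3 replicates, single series."""
    from passomics.core import Sample, SampleDesign

    samples = [
        Sample(f"P{t}_r{r}", t, r, "s1") for t in range(4) for r in range(1, 4)
    ]
    return SampleDesign(samples, ["P1", "P3", "P5", "P7"])


@pytest.fixture
def design4x4():
    from passomics.core import Sample, SampleDesign

    samples = [
        Sample(f"P{t}_r{r}", t, r, "s1") for t in range(4) for r in range(1, 5)
    ]
    return SampleDesign(samples, ["P1", "P3", "P5", "P7"])
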