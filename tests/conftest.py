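import numpy as np
import pytest

from growthcurve.growthcurve_io import FixtureSpec, generate_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def fixture_dataset():
    """Small two-arm study emulating the worked example's layout (4 + 4 animals)."""
    return generate_fixture(FixtureSpec(seed=42))


@pytest.fixture(scope="session")
def fixture_dataset_log():
    return generate_fixture(FixtureSpec(seed=42, scale="log"))
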