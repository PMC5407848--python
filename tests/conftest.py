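import pytest
from hypothesis import HealthCheck, settings

from kdrkit.seqcall import default_reference
from kdrkit.simulate import bioassay_fixture

settings.register_profile(
    "kdrkit",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("kdrkit")


@pytest.fixture(scope="session")
def fixture_df():
    """Pseudo-specimen expansion of the published bioassay counts."""
    return bioassay_fixture()


@pytest.fixture(scope="session")
def reference():
    return default_reference()
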