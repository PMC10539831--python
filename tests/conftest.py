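import pytest
from hypothesis import HealthCheck, settings

from ccrq import PhysicalConstants, build_peptide_plane

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def plane():
    return build_peptide_plane()


@pytest.fixture(scope="session")
def consts():
    return PhysicalConstants()
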