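import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "minichrom",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("minichrom")

from minichrom import STRAINS, build_dt40_genome, make_strain_karyotype  # noqa: E402


@pytest.fixture(scope="session")
def genome():
    return build_dt40_genome()


@pytest.fixture(scope="session")
def karyotypes(genome):
    return {name: make_strain_karyotype(name, genome) for name in STRAINS}
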