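import pytest
from hypothesis import settings

from varclass import presets

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def replica():
    """Replica study inputs for both candidate variants."""
    return presets.paper_replica()


@pytest.fixture(scope="session")
def phe83leu(replica):
    return replica["p.Phe83Leu"]


@pytest.fixture(scope="session")
def gly187glu(replica):
    return replica["p.Gly187Glu"]
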