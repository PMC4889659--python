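import pytest

from imlocus import simulate


@pytest.fixture(scope="session")
def genome():
    """One default miniature genome shared across tests (read-only)."""
    return simulate.simulate_genome(seed=1)
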