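import pytest

from splicerescue.simdata import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_bundle():
    """A small default-condition dataset shared by read-only tests."""
    return simulate_dataset(SimConfig(n_events=50, frac_affected=0.5, seed=7))
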