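import pytest

from crowdnn import load_decomposition, load_parameter_set


@pytest.fixture(scope="session")
def table1():
    """Bundled full parameter set (40 wt% PEG200, 100 mM NaCl)."""
    return load_parameter_set("peg200_40wt_100mM_Na")


@pytest.fixture(scope="session")
def decomp():
    """Bundled four-component decomposition of the same condition."""
    return load_decomposition()
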