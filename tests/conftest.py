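import numpy as np
import pytest

from memelastic import default_parameter_set


@pytest.fixture(scope="session")
def params():
    """One shared parameter set so scan-level memoization works across tests."""
    return default_parameter_set()


@pytest.fixture(scope="session")
def joint_minima(params):
    from memelastic.scans import joint_minimum_peptide_shift

    return joint_minimum_peptide_shift(params)


@pytest.fixture(scope="session")
def fig1_profile(params):
    from memelastic.scans import line_tension_vs_shift

    return line_tension_vs_shift(np.arange(-5.0, 5.0001, 0.05), params)
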