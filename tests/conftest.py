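"""Shared fixtures.

The two expensive simulations (the pacemaker limit cycle and the
interneuron current-clamp response) are session-scoped so that the
membrane, analysis and acceptance tests all reuse one integration.
"""

import pytest

from thermoflux import Constants, FSModel, SANModel


@pytest.fixture(scope="session")
def constants():
    return Constants()  # 310 K


@pytest.fixture(scope="session")
def san_trajectory():
    """Default pacemaker run: 7 s, of which the first 2 s are transient."""
    return SANModel().simulate(t_max=7000.0)


@pytest.fixture(scope="session")
def fs_trajectory_80pA():
    """Interneuron response to the 80 pA step used for upstroke metrics."""
    return FSModel().simulate(stim_amplitude=80.0)
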