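import numpy as np
import pytest

from axoplasmon.dispersion import ChainGeometry

#: the worked-example chain: a = 50 um, d/a = 2.01, water permittivity
PAPER_OMEGA1 = 4e6  # rad/s


@pytest.fixture(scope="session")
def myelinated_chain():
    return ChainGeometry(segment_radius=50e-6, period=2.01 * 50e-6, eps=80.0)


@pytest.fixture(scope="session")
def solved_branch(myelinated_chain):
    """Longitudinal branch of the worked-example chain, solved once."""
    from axoplasmon.dispersion import group_velocity, solve_dispersion

    branch = solve_dispersion(myelinated_chain, PAPER_OMEGA1, n_points=2001)
    group_velocity(branch)
    return branch


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
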