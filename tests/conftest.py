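import numpy as np
import pytest

from axdiam.scheme import AcquisitionScheme, PGSE, STEAM
from axdiam.synthetic import scheme_preset


@pytest.fixture(scope="session")
def human_scheme():
    return scheme_preset("human_connectom")


@pytest.fixture(scope="session")
def rat_scheme():
    return scheme_preset("rat_stim_echo")


@pytest.fixture
def tiny_scheme():
    """Small PGSE scheme: 2 Delta blocks x (1 b0 + 6 directions x 2 shells)."""
    dirs = np.array(
        [
            [1.0, 0, 0],
            [0, 1.0, 0],
            [0, 0, 1.0],
            [1, 1, 0] / np.sqrt(2),
            [1, 0, 1] / np.sqrt(2),
            [0, 1, 1] / np.sqrt(2),
        ]
    )
    bvals, bvecs, bigd = [], [], []
    for D in (15.0, 45.0):
        bvals.append(0.0)
        bvecs.append([0.0, 0.0, 0.0])
        bigd.append(D)
        for b in (2.0, 4.0):
            for u in dirs:
                bvals.append(b)
                bvecs.append(u)
                bigd.append(D)
    return AcquisitionScheme(np.array(bvals), np.array(bvecs), np.array(bigd), 5.0, PGSE)


@pytest.fixture
def tiny_steam_scheme(tiny_scheme):
    return AcquisitionScheme(
        tiny_scheme.bvals,
        tiny_scheme.bvecs,
        tiny_scheme.big_delta,
        tiny_scheme.small_delta,
        STEAM,
        tiny_scheme.big_delta - tiny_scheme.small_delta,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
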