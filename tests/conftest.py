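import numpy as np
import pytest

from uwheel import default_params, mca_network
from uwheel.network import Junction, Network, check_network


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def mca():
    return mca_network("branch1")


@pytest.fixture(scope="session")
def toy_net():
    """Two-turn toy network with one parallel channel at the second turn."""
    mm = 1e-3
    junctions = {
        "J0": Junction("J0", 0.0, 0.0),
        "T1": Junction("T1", 5 * mm, 10.0, kind="turn",
                       children=("mA", "sideA")),
        "EA": Junction("EA", 7 * mm, 20.0, kind="terminal"),
        "T2": Junction("T2", 9 * mm, 5.0, kind="turn",
                       children=("tgt", "sideB"),
                       parallel_offsets=(10.5 * mm,)),
        "EB": Junction("EB", 11 * mm, 10.0, kind="terminal"),
        "E": Junction("E", 12 * mm, 0.0, kind="terminal"),
    }
    branches = {
        "trunk": ("J0", "T1"),
        "sideA": ("T1", "EA"),
        "mA": ("T1", "T2"),
        "sideB": ("T2", "EB"),
        "tgt": ("T2", "E"),
    }
    return check_network(
        Network(junctions=junctions, branches=branches, root="trunk",
                target="tgt", channel_diameter=0.6e-3)
    )


@pytest.fixture(scope="session")
def straight_net():
    """Flat, turn-free single-branch network."""
    junctions = {
        "J0": Junction("J0", 0.0, 0.0),
        "E0": Junction("E0", 20e-3, 0.0, kind="terminal"),
    }
    return check_network(
        Network(junctions=junctions, branches={"trunk": ("J0", "E0")},
                root="trunk", target="trunk")
    )
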