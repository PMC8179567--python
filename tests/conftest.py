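import numpy as np
import pytest

from macpep.closure import sample_closed_backbones
from macpep.energy import TargetContext
from macpep.fixtures import make_ideal_macrocycle, make_toy_complex, make_toy_target
from macpep.hotspot import extend_polygly, rotamer_scan_place


@pytest.fixture(scope="session")
def toy_target():
    structure, site = make_toy_target(0)
    return structure, site


@pytest.fixture(scope="session")
def toy_ctx(toy_target):
    return TargetContext(toy_target[0])


@pytest.fixture(scope="session")
def trp_anchor(toy_target):
    structure, site = toy_target
    anchor, _ = rotamer_scan_place(structure, "TRP", site["site"], site["normal"])
    return anchor


@pytest.fixture(scope="session")
def anchored_pose(trp_anchor):
    return extend_polygly(trp_anchor, 4, 4)


@pytest.fixture(scope="session")
def sampled_solutions(anchored_pose, toy_ctx):
    """A batch of closed, clash-screened, scored ring conformers."""
    return sample_closed_backbones(anchored_pose, toy_ctx, 150, seed=11)


@pytest.fixture(scope="session")
def hexacycle():
    return make_ideal_macrocycle(6, "alternating", seed=0)


@pytest.fixture(scope="session")
def octacycle():
    return make_ideal_macrocycle(8, "alternating", seed=0, attempts=250,
                                 refine=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
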