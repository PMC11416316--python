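import numpy as np
import pytest

from npcbasket.assembly import AssemblyState
from npcbasket.synthetic import make_bundle, make_ground_truth, yeast_params


@pytest.fixture(scope="session")
def yeast_truth():
    return make_ground_truth(yeast_params(seed=7))


@pytest.fixture(scope="session")
def yeast_bundle():
    """Noiseless synthetic study bundle (shared, read-only)."""
    return make_bundle(yeast_params(seed=7), n_true=60, fp_rate=0.0, jitter=0.0)


@pytest.fixture()
def toy_state():
    """Three flexible beads in one chain plus a lone second chain."""
    return AssemblyState.from_chains(
        [
            {
                "subunit": "A",
                "copy_index": 0,
                "centers": np.array([[0.0, 0, 0], [20.0, 0, 0], [40.0, 0, 0]]),
                "radii": np.array([5.0, 5.0, 5.0]),
                "resranges": np.array([[1, 10], [11, 20], [21, 30]]),
            },
            {
                "subunit": "B",
                "copy_index": 0,
                "centers": np.array([[0.0, 50.0, 0]]),
                "radii": np.array([5.0]),
                "resranges": np.array([[1, 10]]),
            },
        ]
    )


def two_copy_state(shift=(0.0, 0.0, 0.0)):
    """Two equivalent copies of a 2-bead subunit; helper for RMSD tests."""
    shift = np.asarray(shift)
    return AssemblyState.from_chains(
        [
            {
                "subunit": "X",
                "copy_index": 0,
                "centers": np.array([[0.0, 0, 0], [10.0, 0, 0]]) + shift,
                "radii": np.array([3.0, 3.0]),
                "resranges": np.array([[1, 10], [11, 20]]),
            },
            {
                "subunit": "X",
                "copy_index": 1,
                "centers": np.array([[0.0, 30.0, 0], [10.0, 30.0, 0]]) + shift,
                "radii": np.array([3.0, 3.0]),
                "resranges": np.array([[1, 10], [11, 20]]),
            },
        ]
    )
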