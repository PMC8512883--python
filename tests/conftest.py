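import numpy as np
import pytest

from dimerfes.toysystems import DimerState, Pose, make_ring_template, random_unit_quaternion


@pytest.fixture(scope="session")
def hexagon():
    return make_ring_template(1)


@pytest.fixture(scope="session")
def tetra():
    return make_ring_template(4)


def random_dimer_state(rng, box_edge=5.0, min_sep=0.35, max_sep=1.9):
    """A random non-overlapping dimer pose inside the wall region."""
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    sep = rng.uniform(min_sep, max_sep)
    return DimerState(
        pose_a=Pose(np.zeros(3), random_unit_quaternion(rng)),
        pose_b=Pose(sep * direction, random_unit_quaternion(rng)),
        box_edge=box_edge,
    )
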