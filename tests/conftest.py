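import numpy as np
import pytest

from straintwin.body import build_capsule_body, build_two_bone_body
from straintwin.motion import DEFAULT_JOINT_RANGES
from straintwin.placement import GeodesicSolver, design_suit


@pytest.fixture(scope="session")
def body():
    """Default 13-joint capsule body (skeleton, mesh)."""
    return build_capsule_body()


@pytest.fixture(scope="session")
def skeleton(body):
    return body[0]


@pytest.fixture(scope="session")
def mesh(body):
    return body[1]


@pytest.fixture(scope="session")
def solver(body):
    return GeodesicSolver(body[1].vertices, body[1].faces)


@pytest.fixture(scope="session")
def suit(body, solver):
    """Default 38-sensor suit design, shared across tests."""
    skeleton, mesh = body
    return design_suit(skeleton, mesh, DEFAULT_JOINT_RANGES, solver=solver)


@pytest.fixture(scope="session")
def hinge():
    """Two-capsule single-hinge test body."""
    return build_two_bone_body()


@pytest.fixture(scope="session")
def hinge_ranges():
    return {
        "base_X": (0.0, 0.0), "base_Y": (0.0, 0.0), "base_Z": (0.0, 0.0),
        "hinge_X": (0.0, 90.0), "hinge_Y": (0.0, 0.0), "hinge_Z": (0.0, 0.0),
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
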