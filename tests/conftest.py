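import numpy as np
import pytest

from exogait.model import (InertialSegment, JointSpec, MultibodyModel,
                           build_exoskeleton_model, build_human_model,
                           couple_models, default_subject,
                           lump_exoskeleton_inertia, scale_model)


@pytest.fixture(scope="session")
def human():
    return build_human_model()


@pytest.fixture(scope="session")
def exo():
    return build_exoskeleton_model()


@pytest.fixture(scope="session")
def scaled_human(human):
    return scale_model(human, default_subject())


@pytest.fixture(scope="session")
def coupled(scaled_human, exo):
    return couple_models(scaled_human, exo)


@pytest.fixture(scope="session")
def lumped(scaled_human, exo):
    return lump_exoskeleton_inertia(scaled_human, exo)


def make_pendulum(mass=2.0, com_offset=0.5, axis=(0, 1, 0)):
    """Single pin pendulum about the origin, rod along -Z."""
    seg = InertialSegment("rod", mass, [0.0, 0.0, -com_offset],
                          np.diag([mass * com_offset ** 2 / 3] * 2 + [1e-4]))
    joint = JointSpec("pin0", "pin", "ground", "rod", axes=[list(axis)],
                      coordinates=["theta"])
    return MultibodyModel([seg], [joint])


def make_chain(n, rng, link_range=(0.6, 0.9)):
    """Random serial pin chain hanging from the origin (alternating axes)."""
    lengths = rng.uniform(*link_range, size=n)
    masses = rng.uniform(1.0, 3.0, size=n)
    segs, joints = [], []
    parent = "ground"
    for i in range(n):
        L, mass = lengths[i], masses[i]
        segs.append(InertialSegment(
            f"link{i}", mass, [0, 0, -L / 2],
            np.diag([mass * L ** 2 / 12] * 2 + [1e-3]), length=L))
        axis = [0, 1, 0] if i % 2 == 0 else [1, 0, 0]
        offset = [0, 0, 0.0] if i == 0 else [0, 0, -lengths[i - 1]]
        joints.append(JointSpec(f"j{i}", "pin", parent, f"link{i}",
                                parent_offset=offset, axes=[axis]))
        parent = f"link{i}"
    return MultibodyModel(segs, joints)
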