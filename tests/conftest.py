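import numpy as np
import pytest

from synflow.infoflow import JointDistribution

_VARS = ("target_t", "src_a_past", "src_b_past", "target_past")


def gate_joint(fn, p_past=0.5):
    """Joint (I_t, J, K, I_past) for I_t = fn(J, K), J/K uniform iid,
    I_past an independent coin."""
    p = np.zeros((2, 2, 2, 2))
    for a in range(2):
        for b in range(2):
            for ip in range(2):
                p[fn(a, b), a, b, ip] += 0.25 * (p_past if ip else 1 - p_past)
    return JointDistribution(_VARS, p)


def duplicated_source_joint():
    """J == K == I_t (fully redundant copy), I_past independent."""
    p = np.zeros((2, 2, 2, 2))
    for a in range(2):
        for ip in range(2):
            p[a, a, a, ip] += 0.25
    return JointDistribution(_VARS, p)


@pytest.fixture(scope="session")
def xor_joint():
    return gate_joint(lambda a, b: a ^ b)


@pytest.fixture(scope="session")
def and_joint():
    return gate_joint(lambda a, b: a & b)


@pytest.fixture(scope="session")
def unq_joint():
    return gate_joint(lambda a, b: a)


@pytest.fixture(scope="session")
def dup_joint():
    return duplicated_source_joint()


def random_joint(rng, concentration=0.5):
    """A random 16-state joint over (I_t, J, K, I_past)."""
    p = rng.dirichlet(np.full(16, concentration)).reshape(2, 2, 2, 2)
    return JointDistribution(_VARS, p)
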