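import numpy as np
import pytest

from masskf import networks
from masskf.statespace import build_state_space


@pytest.fixture(scope="session")
def single_spec():
    return networks.single_region()


@pytest.fixture(scope="session")
def four_spec():
    return networks.four_region()


@pytest.fixture(scope="session")
def single_model(single_spec):
    return build_state_space(single_spec)


@pytest.fixture(scope="session")
def four_model(four_spec):
    return build_state_space(four_spec)


def loop_rhs(spec, xi, u):
    """Independent per-connection oracle for the augmented drift.

    Evaluates the second-order synaptic ODE connection by connection with
    plain dictionaries and scalar arithmetic; no matrix machinery shared
    with the implementation under test.
    """
    from scipy.special import erf

    nc = len(spec.connections)
    v = {c.index: xi[2 * c.index] for c in spec.connections}
    z = {c.index: xi[2 * c.index + 1] for c in spec.connections}
    a = {c.index: xi[2 * nc + c.index] for c in spec.connections}

    def sigmoid(x):
        return 0.5 * (erf((x - spec.v0) / (np.sqrt(2) * spec.sigma_slope)) + 1)

    def potential(pid):
        return sum(v[c.index] for c in spec.connections if c.target == pid)

    out = np.zeros_like(xi)
    for c in spec.connections:
        phi = u if c.kind == "input" else sigmoid(potential(c.source))
        out[2 * c.index] = z[c.index]
        out[2 * c.index + 1] = (a[c.index] / c.tau * phi
                                - 2.0 / c.tau * z[c.index]
                                - 1.0 / c.tau**2 * v[c.index])
    return out
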