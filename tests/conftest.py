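import numpy as np
import pytest

from multifib import network as nw


@pytest.fixture(scope="session")
def small_network():
    """A seeded 60-100 fibre network used across tests."""
    return nw.generate_random_network(7, (60, 100))


@pytest.fixture(scope="session")
def cross_network():
    """Five-node cross: one free central node joined to four boundary
    nodes, small enough for brute-force oracles."""
    nodes = np.array([
        [0.5, 0.5, 0.5],
        [0.0, 0.5, 0.5],
        [1.0, 0.5, 0.5],
        [0.5, 0.0, 0.5],
        [0.5, 1.0, 0.45],
    ])
    fibres = np.array([[0, 1], [0, 2], [0, 3], [0, 4]])
    l0 = np.linalg.norm(nodes[fibres[:, 1]] - nodes[fibres[:, 0]], axis=1)
    boundary = np.array([1, 2, 3, 4])
    normals = np.array([[-1, 0, 0], [1, 0, 0], [0, -1, 0], [0, 1, 0]],
                       dtype=float)
    return nw.FibreNetwork(nodes, fibres, l0, boundary, normals,
                           theta_s=0.003, a_f=2.5e-5, e_f=5.0e5, c0=2.0,
                           side_length=20.0)


def make_two_fibre_network(dirs=((1, 0, 0), (0, 1, 0))):
    """Straight fibres spanning the cube through its centre; every node is
    a boundary node."""
    dirs = [np.asarray(d, float) / np.linalg.norm(d) for d in dirs]
    nodes, fibres, nrm = [], [], []
    for d in dirs:
        i = len(nodes)
        nodes += [0.5 - 0.5 * d, 0.5 + 0.5 * d]
        fibres.append((i, i + 1))
        nrm += [-d, d]
    nodes = np.array(nodes)
    fibres = np.array(fibres)
    l0 = np.linalg.norm(nodes[fibres[:, 1]] - nodes[fibres[:, 0]], axis=1)
    return nw.FibreNetwork(nodes, fibres, l0, np.arange(len(nodes)),
                           np.array(nrm), theta_s=0.003, a_f=2.5e-5,
                           e_f=5.0e5, c0=2.0, side_length=20.0)
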