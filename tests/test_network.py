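import h5py
import numpy as np
import pytest
from scipy.optimize import minimize

from multifib import network as nw

from conftest import make_two_fibre_network


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def test_generated_network_meets_invariants():
    net = nw.generate_random_network(1, (200, 300))
    assert 200 <= net.n_fibres <= 300
    # all nodes inside the cube, boundary nodes exactly on faces
    assert np.all(net.nodes >= -1e-12) and np.all(net.nodes <= 1 + 1e-12)
    on_face = np.any((net.nodes[net.boundary_nodes] == 0.0)
                     | (net.nodes[net.boundary_nodes] == 1.0), axis=1)
    assert np.all(on_face)
    # interior pin joints join at least two fibres
    deg = np.zeros(net.n_nodes, dtype=int)
    for a, b in net.fibres:
        deg[a] += 1
        deg[b] += 1
    interior = ~net.is_boundary
    assert np.all(deg[interior] >= 2)
    # single connected component (independent union-find check)
    parent = list(range(net.n_nodes))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in net.fibres:
        parent[find(a)] = find(b)
    used = {find(i) for i in range(net.n_nodes) if deg[i] > 0}
    assert len(used) == 1
    # eta identity
    assert np.isclose(net.eta,
                      net.theta_s * 1.0 / (net.a_f * net.total_length))


def test_generation_is_deterministic():
    a = nw.generate_random_network(11, (60, 100))
    b = nw.generate_random_network(11, (60, 100))
    assert np.array_equal(a.nodes, b.nodes)
    assert np.array_equal(a.fibres, b.fibres)
    assert np.array_equal(a.l0, b.l0)


def test_random_networks_are_near_isotropic():
    diags = [np.diag(nw.orientation_tensor(
        nw.generate_random_network(100 + s, (60, 100))))
        for s in range(30)]
    mean = np.mean(diags, axis=0)
    assert np.all(np.abs(mean - 1.0 / 3.0) < 0.03)


def test_generation_rejects_bad_arguments():
    with pytest.raises(ValueError):
        nw.generate_random_network(1, (10, 20))
    with pytest.raises(ValueError):
        nw.generate_random_network(1, (60, 100), theta_s=0.5)


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def test_identity_stretch_equals_random():
    a = nw.generate_random_network(5, (60, 100))
    b = nw.generate_aligned_network(5, (1.0, 1.0, 1.0),
                                    count_bounds=(60, 100))
    assert np.array_equal(a.nodes, b.nodes)
    assert np.array_equal(a.fibres, b.fibres)


def test_planar_stretch_orders_diagonals():
    diags = np.mean([np.diag(nw.orientation_tensor(
        nw.generate_aligned_network(40 + s, (1.6, 0.8, 1.6),
                                    count_bounds=(60, 100))))
        for s in range(6)], axis=0)
    assert diags[0] > diags[1] and diags[2] > diags[1]
    assert abs(diags[0] - diags[2]) < 0.12


def test_strong_stretch_aligns_networks():
    omega = nw.orientation_tensor(
        nw.generate_aligned_network(3, (10.0, 1.0, 1.0),
                                    count_bounds=(200, 300)))
    assert omega[0, 0] > 0.9


def test_default_prealignment_matches_target():
    """The documented prealigned-stroma stretch gives orientation-tensor
    diagonals near (0.39, 0.23, 0.38)."""
    diags = np.mean([np.diag(nw.orientation_tensor(
        nw.generate_aligned_network(60 + s, (1.246, 1.0, 1.231),
                                    count_bounds=(200, 300))))
        for s in range(8)], axis=0)
    assert np.allclose(diags, [0.39, 0.23, 0.38], atol=0.05)


def test_stretch_monotonicity():
    base = np.mean([np.diag(nw.orientation_tensor(
        nw.generate_aligned_network(80 + s, (1.0, 1.0, 1.0),
                                    count_bounds=(60, 100))))[0]
        for s in range(5)])
    more = np.mean([np.diag(nw.orientation_tensor(
        nw.generate_aligned_network(80 + s, (1.5, 1.0, 1.0),
                                    count_bounds=(60, 100))))[0]
        for s in range(5)])
    assert more > base


# ---------------------------------------------------------------------------
# constitutive law
# ---------------------------------------------------------------------------

def test_fibre_force_examples():
    assert nw.fibre_force(0.0, 1.0, 1.0, 2.0) == 0.0
    # exponential law at a_f = e_f = 1, c0 = 2, eps = 0.1
    assert np.isclose(nw.fibre_force(0.1, 1.0, 1.0, 2.0),
                      0.5 * np.expm1(0.2), rtol=1e-12)
    # c0 -> 0 linear limit
    assert np.isclose(nw.fibre_force(0.05, 2.0, 3.0, 1e-12), 2.0 * 3.0 * 0.05)
    assert np.isclose(nw.fibre_force(0.05, 2.0, 3.0, 1e-6),
                      2.0 * 3.0 * 0.05, rtol=1e-6)


def test_fibre_force_sign_and_monotonicity():
    eps = np.linspace(-0.5, 0.5, 41)
    f = nw.fibre_force(eps, 1.0, 1.0, 2.0)
    assert np.all(np.sign(f[eps != 0]) == np.sign(eps[eps != 0]))
    assert np.all(np.diff(f) > 0)


# ---------------------------------------------------------------------------
# orientation tensor
# ---------------------------------------------------------------------------

def test_orientation_tensor_examples():
    one = nw.orientation_tensor(np.array([[1.0, 0, 0]]), np.array([1.0]))
    assert np.allclose(one, np.diag([1.0, 0, 0]))
    two = nw.orientation_tensor(np.array([[1.0, 0, 0], [0, 1.0, 0]]),
                                np.array([1.0, 1.0]))
    assert np.allclose(two, np.diag([0.5, 0.5, 0.0]))


def test_orientation_tensor_properties(small_network):
    omega = nw.orientation_tensor(small_network)
    assert np.allclose(omega, omega.T)
    assert np.isclose(np.trace(omega), 1.0, atol=1e-12)
    assert np.all(np.linalg.eigvalsh(omega) >= -1e-14)


def test_orientation_tensor_rotation_equivariance(small_network):
    rng = np.random.default_rng(2)
    A = rng.normal(size=(3, 3))
    R, _ = np.linalg.qr(A)
    dirs, lens = small_network.directions()
    omega = nw.orientation_tensor(dirs, lens)
    omega_rot = nw.orientation_tensor(dirs @ R.T, lens)
    assert np.allclose(omega_rot, R @ omega @ R.T, atol=1e-12)


def test_orientation_tensor_empty_errors():
    with pytest.raises(nw.NetworkError):
        nw.orientation_tensor(np.zeros((0, 3)), np.zeros(0))


# ---------------------------------------------------------------------------
# micro equilibrium
# ---------------------------------------------------------------------------

def test_zero_boundary_displacement_is_equilibrium(small_network):
    nb = len(small_network.boundary_nodes)
    st = nw.solve_micro_equilibrium(small_network, np.zeros((nb, 3)))
    assert np.abs(st.u).max() == 0.0
    assert np.abs(st.eps).max() == 0.0
    assert np.abs(st.force).max() == 0.0


def test_rigid_translation_is_strain_free(small_network):
    t = np.array([0.2, -0.1, 0.05])
    nb = len(small_network.boundary_nodes)
    st = nw.solve_micro_equilibrium(small_network, np.tile(t, (nb, 1)))
    assert np.allclose(st.u, t, atol=1e-9)
    assert np.abs(st.eps).max() < 1e-10


def test_micro_equilibrium_matches_energy_minimisation(cross_network):
    """Newton equilibrium equals brute-force minimisation of the exact
    strain energy on a tiny network (independent optimiser, tol 1e-8)."""
    net = cross_network
    bu = net.nodes[net.boundary_nodes] @ np.diag([0.15, -0.05, 0.0])
    st = nw.solve_micro_equilibrium(net, bu, tol=1e-11)

    def energy(x):
        u = np.zeros((net.n_nodes, 3))
        u[net.boundary_nodes] = bu
        u[0] = x
        return nw.strain_energy(net, u)

    res = minimize(energy, np.zeros(3), method="Nelder-Mead",
                   options=dict(xatol=1e-12, fatol=1e-18, maxiter=50000))
    assert np.linalg.norm(st.u[0] - res.x) < 1e-8


def test_equilibrium_energy_below_affine(small_network):
    net = small_network
    A = np.diag([-0.1, 0.02, 0.03])
    bu = net.nodes[net.boundary_nodes] @ A.T
    st = nw.solve_micro_equilibrium(net, bu)
    e_eq = nw.strain_energy(net, st.u)
    e_affine = nw.strain_energy(net, net.nodes @ A.T)
    assert e_eq <= e_affine + 1e-12


def test_micro_solve_deterministic(small_network):
    net = small_network
    bu = net.nodes[net.boundary_nodes] @ np.diag([-0.08, 0.01, 0.02])
    a = nw.solve_micro_equilibrium(net, bu)
    b = nw.solve_micro_equilibrium(net, bu)
    assert np.array_equal(a.u, b.u)


def test_micro_solve_requires_full_boundary(small_network):
    with pytest.raises(ValueError, match="boundary"):
        nw.solve_micro_equilibrium(small_network, np.zeros((3, 3)))


def test_pressure_enters_without_micro_pressure_solve():
    """Interpolated pressure shifts the equilibrium but no pressure unknown
    is solved for: output pressures equal the input."""
    net = make_two_fibre_network()
    p = np.full(net.n_nodes, 100.0)
    bu = np.zeros((len(net.boundary_nodes), 3))
    st = nw.solve_micro_equilibrium(net, bu, nodal_p=p)
    assert np.array_equal(st.p, p)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def test_hdf5_round_trip(tmp_path, small_network):
    path = tmp_path / "net.h5"
    with h5py.File(path, "w") as fh:
        nw.save_network(small_network, fh.create_group("rve"))
    with h5py.File(path) as fh:
        loaded = nw.load_network(fh["rve"])
    assert np.array_equal(loaded.nodes, small_network.nodes)
    assert np.array_equal(loaded.fibres, small_network.fibres)
    assert loaded.seed == small_network.seed
    assert loaded.theta_s == small_network.theta_s
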