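import numpy as np
import pytest

from multifib import homogenise as hm
from multifib import network as nw

from conftest import make_two_fibre_network


# ---------------------------------------------------------------------------
# drag matrix
# ---------------------------------------------------------------------------

def test_drag_ratio_dilute_limit():
    c = hm.drag_matrix(1e-8, 1.0)
    assert abs(c[1, 1] / c[0, 0] - 2.0) < 1e-6
    assert c[1, 1] == c[2, 2]


def test_drag_direct_evaluation():
    # parallel drag at theta_s = 0.05, unit length
    c = hm.drag_matrix(0.05, 1.0)
    den = -np.log(0.05) - 1.476 + 2 * 0.05 - 0.5 * 0.05**2
    assert np.isclose(c[0, 0], 4 * np.pi / den, rtol=1e-12)
    assert np.isclose(c[0, 0], 7.7643, atol=1e-4)


def test_drag_linear_in_length():
    assert np.allclose(hm.drag_matrix(0.05, 2.0), 2 * hm.drag_matrix(0.05, 1.0))


def test_drag_invalid_regimes():
    with pytest.raises(hm.HomogenisationError):
        hm.drag_matrix(0.0, 1.0)
    with pytest.raises(hm.HomogenisationError):
        hm.drag_matrix(1.2, 1.0)
    with pytest.raises(hm.HomogenisationError, match="solid fraction"):
        hm.drag_matrix(0.5, 1.0)  # denominator of the expansion goes negative
    with pytest.raises(hm.HomogenisationError):
        hm.drag_matrix(0.05, -1.0)


# ---------------------------------------------------------------------------
# fibre permeability
# ---------------------------------------------------------------------------

def test_fibre_permeability_axis_aligned():
    k = hm.fibre_permeability([1, 0, 0], np.diag([1.0, 2.0, 2.0]))
    assert np.allclose(k, np.diag([1.0, 0.5, 0.5]))


def test_fibre_permeability_eigenstructure():
    n_f = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
    k = hm.fibre_permeability(n_f, np.diag([1.0, 2.0, 2.0]))
    w, v = np.linalg.eigh(k)
    assert np.isclose(w[-1], 1.0)
    assert abs(v[:, -1] @ n_f) > 1 - 1e-12
    assert np.allclose(w[:2], 0.5)


def test_fibre_permeability_rotation_equivariance():
    rng = np.random.default_rng(3)
    R, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    n_f = np.array([0.3, -0.5, 0.8])
    n_f /= np.linalg.norm(n_f)
    c = np.diag([1.0, 2.0, 2.0])
    assert np.allclose(hm.fibre_permeability(R @ n_f, c),
                       R @ hm.fibre_permeability(n_f, c) @ R.T, atol=1e-13)


# ---------------------------------------------------------------------------
# dimensionalisation factor
# ---------------------------------------------------------------------------

def test_eta_examples():
    assert np.isclose(hm.dimensionalisation_factor(0.05, 1.0, 0.005, 10.0),
                      1.0)
    base = hm.dimensionalisation_factor(0.003, 1.0, 2.5e-5, 60.0)
    assert np.isclose(base, 2.0)
    assert np.isclose(hm.dimensionalisation_factor(0.003, 1.0, 2.5e-5, 120.0),
                      base / 2.0)
    with pytest.raises(ValueError):
        hm.dimensionalisation_factor(0.003, 1.0, 2.5e-5, 0.0)


# ---------------------------------------------------------------------------
# upscaling
# ---------------------------------------------------------------------------

def _solved(net, strain=None, tol=1e-9):
    A = np.zeros((3, 3)) if strain is None else np.asarray(strain, float)
    bu = net.nodes[net.boundary_nodes] @ A.T
    return nw.solve_micro_equilibrium(net, bu, tol=tol)


def test_permeability_hand_sum(small_network):
    """K equals the manual per-fibre sum (r^T c r)^-1 / V to 1e-12."""
    net = small_network
    st = _solved(net)
    K = hm.upscale_permeability(net, st)
    manual = np.zeros((3, 3))
    dirs, lens = net.directions()
    for f in range(net.n_fibres):
        c = hm.drag_matrix(net.theta_s, lens[f])
        manual += hm.fibre_permeability(dirs[f], c)
    assert np.allclose(K, manual / net.volume, atol=1e-12 * np.abs(manual).max())
    assert np.all(np.linalg.eigvalsh(K) > 0)


def test_mixing_and_fluid_source_trivial_cases(small_network):
    net = small_network
    st = _solved(net, np.diag([-0.05, 0.01, 0.0]))
    zeros = np.zeros((net.n_nodes, 3))
    assert np.allclose(hm.upscale_mixing(net, st, zeros), 0.0)
    # V^S equal to the fibre velocities at every crossing -> zero source
    v = np.tile([0.1, -0.2, 0.3], (net.n_nodes, 1))
    VS = np.tile([0.1, -0.2, 0.3], (len(net.boundary_nodes), 1))
    assert abs(hm.upscale_fluid_source(net, st, VS, v)) < 1e-15
    # v^S = 0 reduces to (a_f/V) sum V^S . n over crossings
    VS_const = np.array([0.2, 0.0, 0.0])
    manual = net.a_f * sum(
        float(VS_const @ nrm)
        for _, _, _, nrm in hm.boundary_crossings(net))
    assert np.isclose(hm.upscale_fluid_source(net, st, VS_const, zeros),
                      manual, rtol=1e-12)


def test_stress_single_spanning_fibre():
    """One fibre along x under stretch: S11 matches the hand evaluation of
    the boundary-crossing sum; every other component vanishes."""
    net = make_two_fibre_network(dirs=((1, 0, 0),))
    stretch = 0.1
    bu = net.nodes[net.boundary_nodes] @ np.diag([stretch, 0, 0])
    st = nw.solve_micro_equilibrium(net, bu)
    S = hm.upscale_stress(net, st)
    eps = (((1 + stretch) ** 2 - 1.0) / 2.0)
    f = nw.fibre_force(eps, net.a_f, net.e_f, net.c0)
    assert np.isclose(S[0, 0], 2 * f / net.volume, rtol=1e-9)
    S_other = S.copy()
    S_other[0, 0] = 0.0
    assert np.abs(S_other).max() < 1e-14


def test_stress_and_body_source_vanish_at_rest(small_network):
    net = small_network
    st = _solved(net)
    S = hm.upscale_stress(net, st)
    assert np.abs(S).max() == 0.0
    assert np.abs(hm.upscale_body_source(net, st, S)).max() == 0.0


def test_body_source_hand_sum(small_network):
    """Q equals the manual crossing-by-crossing evaluation of the
    (s - S) . u' . n sum."""
    net = small_network
    st = _solved(net, np.diag([-0.08, 0.02, 0.01]))
    S = hm.upscale_stress(net, st)
    x = net.nodes + st.u
    manual = np.zeros(3)
    for f, bnode, onode, nrm in hm.boundary_crossings(net):
        d_out = x[bnode] - x[onode]
        d_out /= np.linalg.norm(d_out)
        s_end = st.force[f] * np.outer(d_out, nrm)
        d_ref = net.nodes[bnode] - net.nodes[onode]
        l_ref = np.linalg.norm(d_ref)
        u_grad = np.outer(st.u[bnode] - st.u[onode], d_ref / l_ref) / l_ref
        manual += ((s_end - S) @ u_grad) @ nrm
    Q = hm.upscale_body_source(net, st, S)
    assert np.allclose(Q, manual, atol=1e-14)


def test_mean_permeability_is_isotropic():
    """Averaged over many random networks, K has small off-diagonals and
    comparable diagonals."""
    Ks = []
    for s in range(40):
        net = nw.generate_random_network(700 + s, (60, 100))
        st = _solved(net, tol=1e-8)
        Ks.append(hm.upscale_permeability(net, st))
    K = np.mean(Ks, axis=0)
    diag = np.diag(K)
    off = K - np.diag(diag)
    assert np.abs(off).max() < 0.05 * diag.mean()
    assert diag.max() / diag.min() < 1.10


def test_compression_reduces_physical_permeability(small_network):
    """Uniaxial compression lowers the dimensionalised permeability in the
    compression direction (network compaction raises eta)."""
    net = small_network
    st0 = _solved(net)
    st1 = _solved(net, np.diag([-0.15, 0.0, 0.0]))
    K0 = hm.upscale_permeability(net, st0) / hm.current_eta(net, st0) ** 4
    K1 = hm.upscale_permeability(net, st1) / hm.current_eta(net, st1) ** 4
    assert K1[0, 0] < K0[0, 0]


def test_aligned_network_permeability_follows_orientation():
    """For a strongly aligned network the principal axes of K and of the
    orientation tensor are within 30 degrees."""
    net = nw.generate_aligned_network(9, (3.0, 1.0, 1.0),
                                      count_bounds=(60, 100))
    st = _solved(net, tol=1e-8)
    K = hm.upscale_permeability(net, st)
    omega = nw.orientation_tensor(net)
    _, vK = np.linalg.eigh(K)
    _, vO = np.linalg.eigh(omega)
    cosang = abs(vK[:, -1] @ vO[:, -1])
    assert cosang > np.cos(np.deg2rad(30))


def test_upscale_all_units_and_dimensionalisation(small_network):
    net = small_network
    st = _solved(net, np.diag([-0.05, 0.0, 0.0]))
    v0 = np.zeros((net.n_nodes, 3))
    ups = hm.upscale_all(net, st, v0, np.zeros(3),
                         viscosity_scale=6e-5, rve_side_mm=0.02)
    eta = hm.current_eta(net, st)
    assert np.allclose(ups.S, hm.upscale_stress(net, st) / eta)
    assert np.allclose(ups.K,
                       hm.upscale_permeability(net, st) * 6e-5 / eta**4)
    assert np.allclose(ups.d, 0.0)
    assert np.all(np.isfinite(ups.Q))
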