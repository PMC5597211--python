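import numpy as np
import pytest

from multifib import macro as mc
from multifib import mesh as mm


# ---------------------------------------------------------------------------
# growth law
# ---------------------------------------------------------------------------

def test_growth_raw_examples():
    g = mc.GrowthLaw(alpha=1.35, beta=5.0, gamma=0.1)
    assert np.isclose(g.raw(0.0), 1.35 * np.exp(-5.0))
    assert np.isclose(g.raw(1e9), 1.35)
    t = np.linspace(0, 100, 200)
    assert np.all(np.diff(g.raw(t)) >= 0)


def test_growth_normalised_stretch():
    g = mc.GrowthLaw.from_plateau(1.35, 0.08)
    assert g.stretch(0.0) == 1.0
    assert np.isclose(g.stretch(1e9), 1.35)
    assert np.allclose(g.tensor(0.0), np.eye(3))


def test_growth_rate_parameter_speeds_saturation():
    slow = mc.GrowthLaw.from_plateau(1.35, 0.05)
    fast = mc.GrowthLaw.from_plateau(1.35, 0.10)
    target = 0.5 * (1.0 + 1.35)
    t = np.linspace(0, 200, 20001)

    def t_half(g):
        return t[np.searchsorted(g.stretch(t), target)]

    assert t_half(fast) < t_half(slow)


def test_growth_rejects_negative_time():
    g = mc.GrowthLaw.from_plateau(1.35)
    with pytest.raises(ValueError):
        g.stretch(-1.0)


# ---------------------------------------------------------------------------
# tumour constitutive model
# ---------------------------------------------------------------------------

def test_tumour_stress_free_reference():
    assert np.abs(mc.tumour_pk2_stress(np.eye(3), 200.0, 1000.0)).max() == 0.0


def test_tumour_stress_matches_energy_derivative():
    """Analytic S equals 2 dW/dC by central finite differences (1e-6)."""
    mu, kappa = 200.0, 1000.0
    rng = np.random.default_rng(3)
    F = np.eye(3) + 0.1 * rng.normal(size=(3, 3))
    C = F.T @ F

    def W(C):
        J = np.sqrt(np.linalg.det(C))
        return (0.5 * mu * (J ** (-2 / 3) * np.trace(C) - 3)
                + 0.5 * kappa * (J - 1) ** 2)

    S_fd = np.zeros((3, 3))
    h = 1e-7
    for i in range(3):
        for j in range(3):
            dC = np.zeros((3, 3))
            dC[i, j] += 0.5 * h
            dC[j, i] += 0.5 * h
            S_fd[i, j] = 2 * (W(C + dC) - W(C - dC)) / (2 * h)
    S = mc.tumour_pk2_stress(F, mu, kappa)
    assert np.abs(S - S_fd).max() / np.abs(S).max() < 1e-6


def test_tumour_stress_small_strain_slope():
    """The stress-strain slope at small strain matches the linear-elastic
    tensor built from (mu, kappa)."""
    mu, kappa = 200.0, 1000.0
    C_lin = mc.isotropic_stiffness(mu, kappa)
    d = 1e-6
    for i, j in [(0, 0), (0, 1), (1, 2)]:
        eps = np.zeros((3, 3))
        eps[i, j] = eps[j, i] = d
        F = np.eye(3) + eps
        S = mc.tumour_pk2_stress(F, mu, kappa)
        S_lin = np.einsum("ijkl,kl->ij", C_lin, eps)
        assert np.abs(S - S_lin).max() < 1e-4 * np.abs(S_lin).max() + 1e-12


def test_tumour_stress_rejects_inverted_state():
    F = np.diag([1.0, 1.0, -0.5])
    with pytest.raises(mc.MacroSolverError):
        mc.tumour_pk2_stress(F, 200.0, 1000.0)


def test_darcy_velocity():
    assert np.allclose(mc.darcy_velocity(np.eye(3), 1.0, [0, 0, 0]), 0)
    assert np.allclose(mc.darcy_velocity(np.eye(3), 1.0, [1, 0, 0]),
                       [-1, 0, 0])
    v1 = mc.darcy_velocity(np.diag([2.0, 1, 1]), 0.9, [1.0, 0, 0])
    v2 = mc.darcy_velocity(np.eye(3), 0.9, [1.0, 0, 0])
    assert np.isclose(v1[0], 2 * v2[0])
    # mixing vector shifts the driving gradient
    v3 = mc.darcy_velocity(np.eye(3), 1.0, [1.0, 0, 0], d=[-1.0, 0, 0])
    assert np.allclose(v3, 0.0)


# ---------------------------------------------------------------------------
# coupled stepping
# ---------------------------------------------------------------------------

def _octant_solver(growth_plateau=1.35, gamma=0.08, mu_s=150.0,
                   kappa_s=400.0, mesh_args=(0.1, 0.5, 2, 2, 3)):
    mesh = mm.build_octant_mesh(*mesh_args)
    tum = mc.TumourMaterial(growth=mc.GrowthLaw.from_plateau(growth_plateau,
                                                            gamma))
    stroma = mc.LinearStroma(mu=mu_s, kappa=kappa_s, k_iso=1e-5,
                             theta_s=0.003)
    return mesh, mc.MacroSolver(mesh, tum, stroma)


def test_zero_growth_preserves_zero_state():
    _, sol = _octant_solver(growth_plateau=1.0,
                            mesh_args=(0.1, 0.5, 1, 1, 1))
    for _ in range(3):
        sol.step(1.0)
    assert np.abs(sol.U).max() == 0.0
    assert np.abs(sol.P).max() == 0.0


def test_sealed_growth_conserves_fluid_mass():
    """All boundaries sealed: the global discrete mass balance closes to
    well below 0.5% each step."""
    _, sol = _octant_solver(mesh_args=(0.1, 0.5, 1, 1, 2))
    for _ in range(6):
        out = sol.step(2.0)
        assert out["mass_residual"] < 5e-3
        assert out["grad_norm"] < 1e-6


def test_terzaghi_consolidation_matches_series():
    """1D consolidation of a loaded, top-drained poroelastic column agrees
    with the classical series solution to < 2% of the initial excess
    pressure."""
    mu_s, kappa_s = 100.0, 300.0
    E_oed = (kappa_s - 2 * mu_s / 3) + 2 * mu_s
    theta_s, M, k, q, H = 0.5, 1.0e4, 1.0e-3, 1.0, 1.0
    stroma = mc.LinearStroma(mu=mu_s, kappa=kappa_s, k_iso=k,
                             theta_s=theta_s)
    mesh = mm.build_box_mesh((0.1, 0.1, H), (1, 1, 10))
    sol = mc.MacroSolver(mesh, None, stroma, biot_modulus=M,
                         fix_normal_tags=("x0", "x1", "y0", "y1", "z0"),
                         drained_tags=("z1",), tractions={"z1": [0, 0, -q]})
    c_v = k * (1 - theta_s) ** 2 / (1.0 / M + theta_s / E_oed)
    P0 = q * (theta_s / E_oed) / (1.0 / M + theta_s / E_oed)

    def series(z, t, nterms=400):
        total = np.zeros_like(z)
        for m in range(nterms):
            Mm = 0.5 * np.pi * (2 * m + 1)
            total += (2.0 / Mm * np.sin(Mm * (H - z) / H)
                      * np.exp(-Mm**2 * c_v * t / H**2))
        return P0 * total

    dt = 0.025
    z = mesh.nodes[mesh.pressure_nodes][:, 2]
    checked = 0
    while sol.t < 2.0 + 1e-9:
        sol.step(dt)
        for t_ref in (0.5, 1.0, 2.0):
            if abs(sol.t - t_ref) < 1e-9:
                err = np.abs(sol.P - series(z, t_ref)).max() / P0
                assert err < 0.02, f"t={t_ref}: {err:.3f}"
                checked += 1
    assert checked == 3


def test_spherical_shell_displacement_decay():
    """A small growth increment inflates the tumour like a pressurised
    cavity; the stromal radial displacement follows the thick-shell
    (A r + B / r^2) solution within 5% at mid-shell."""
    mesh, sol = _octant_solver(growth_plateau=1.02, gamma=1.0,
                               mesh_args=(0.1, 0.5, 2, 2, 3))
    for _ in range(8):
        sol.step(1.0)  # gamma = 1/h: effectively at the plateau
    r_nodes = np.linalg.norm(mesh.nodes, axis=1)
    u_rad = np.einsum("ni,ni->n", sol.U,
                      np.divide(mesh.nodes, r_nodes[:, None],
                                out=np.zeros_like(mesh.nodes),
                                where=r_nodes[:, None] > 0))

    def shell_mean(r0, tol=1e-3):
        sel = np.abs(r_nodes - r0) < tol
        assert sel.any()
        return u_rad[sel].mean()

    r_i, r_e, r_mid = 0.1, 0.6, 0.35
    u_i = shell_mean(r_i)
    # A r + B/r^2 with u(r_i) = u_i and u(r_e) = 0
    M = np.array([[r_i, 1 / r_i**2], [r_e, 1 / r_e**2]])
    A, B = np.linalg.solve(M, [u_i, 0.0])
    predicted = A * r_mid + B / r_mid**2
    measured = shell_mean(r_mid)
    assert abs(measured - predicted) < 0.05 * abs(u_i)


def test_incompressible_limit_reduces_volume_change():
    """Raising kappa/mu makes the confined tumour response more
    volume-preserving."""
    vols = []
    for kappa in (500.0, 5000.0):
        mesh = mm.build_octant_mesh(0.1, 0.5, 1, 1, 1)
        tum = mc.TumourMaterial(mu=200.0, kappa=kappa,
                                growth=mc.GrowthLaw.from_plateau(1.2, 1.0))
        stroma = mc.LinearStroma(mu=500.0, kappa=1500.0, k_iso=1e-5,
                                 theta_s=0.003)
        sol = mc.MacroSolver(mesh, tum, stroma)
        for _ in range(6):
            sol.step(1.0)
        F, _ = sol.qp_state()
        tum_el = mesh.region == mm.REGION_TUMOUR
        f = tum.growth.stretch(sol.t)
        J_e = np.linalg.det(F[tum_el] / f)
        vols.append(abs(np.mean(J_e) - 1.0))
    assert vols[1] < vols[0]
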