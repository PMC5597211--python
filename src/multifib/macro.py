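"""Macroscale mixed U-P poroelastic finite-element solver.

Momentum balance of a biphasic (solid + interstitial fluid) continuum with
zero inertia, total-Lagrangian kinematics and multiplicative growth
F = F_e F_g in the tumour; mass balance with Biot storage, Darcy flow and the
homogenised fluid source in the stroma.  Displacements use triquadratic and
pressure trilinear interpolation on the same hexahedra; solid quantities are
integrated with a 2x2x2 Gauss rule and the fluid constitutive set is sampled
at a single point per element (reduced order, against volumetric locking).

The quasi-static mechanical sub-problem is solved by minimising the total
potential over the constrained displacement space (L-BFGS with analytic
gradients); the pressure equation is integrated with backward Euler.  The
two are iterated to a fixed point within each time step.

Units: mm, Pa, hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.optimize import minimize

from .mesh import FACES, MacroMesh, REGION_STROMA, REGION_TUMOUR
from .shapes import gauss_points, hex8_shape, hex27_shape

_AXIS = {"x": 0, "y": 1, "z": 2}


class MacroSolverError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# growth law
# ---------------------------------------------------------------------------

@dataclass
class GrowthLaw:
    """Gompertz growth stretch f(t) = alpha exp(-beta exp(-gamma t)).

    The solver applies the normalised stretch f(t)/f(0) so the simulation
    starts stress-free at stretch 1; the plateau of the normalised stretch is
    exp(beta).
    """

    alpha: float = 1.0
    beta: float = np.log(1.35)
    gamma: float = 0.08  # 1/h

    def __post_init__(self):
        if self.alpha < 1.0 and not np.isclose(self.alpha, 1.0):
            pass  # alpha only scales the raw curve; normalisation removes it
        if self.beta < 0 or self.gamma <= 0:
            raise ValueError("beta must be >= 0 and gamma positive")

    @classmethod
    def from_plateau(cls, plateau: float, gamma: float = 0.08) -> "GrowthLaw":
        if plateau < 1.0:
            raise ValueError("growth plateau must be >= 1")
        return cls(alpha=1.0, beta=float(np.log(plateau)), gamma=gamma)

    def raw(self, t):
        """Unnormalised Gompertz value alpha exp(-beta exp(-gamma t))."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be non-negative")
        out = self.alpha * np.exp(-self.beta * np.exp(-self.gamma * t))
        return out if out.ndim else float(out)

    def stretch(self, t):
        """Normalised growth stretch f(t)/f(0); 1 at t = 0, exp(beta) at
        infinity, monotone non-decreasing."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be non-negative")
        out = np.exp(self.beta * (1.0 - np.exp(-self.gamma * t)))
        return out if out.ndim else float(out)

    def tensor(self, t) -> np.ndarray:
        """Growth tensor F_g = f(t) I (normalised isotropic growth)."""
        return self.stretch(t) * np.eye(3)


def growth_stretch(t, alpha: float, beta: float, gamma: float):
    """Raw Gompertz stretch alpha exp(-beta exp(-gamma t))."""
    return GrowthLaw(alpha=alpha, beta=beta, gamma=gamma).raw(t)


# ---------------------------------------------------------------------------
# constitutive models
# ---------------------------------------------------------------------------

@dataclass
class TumourMaterial:
    """Nearly incompressible hyperelastic tumour with isotropic Gompertz
    growth and isotropic Darcy conductivity k_o."""

    mu: float = 200.0        # Pa, drained shear modulus
    kappa: float = 1000.0    # Pa, drained bulk modulus
    k_o: float = 1.0e-3      # mm^2 / (Pa h)
    theta_s: float = 0.5
    growth: GrowthLaw = field(default_factory=GrowthLaw)

    def __post_init__(self):
        if min(self.mu, self.kappa, self.k_o) <= 0:
            raise ValueError("mu, kappa and k_o must be positive")


def tumour_pk2_stress(F_e: np.ndarray, mu: float, kappa: float) -> np.ndarray:
    """Elastic 2nd Piola-Kirchhoff stress of the tumour strain energy
    W = mu/2 (J^{-2/3} I1 - 3) + kappa/2 (J - 1)^2.

    Stress-free at F_e = I; for small strains the tangent reproduces the
    linear-elastic tensor with shear modulus mu and bulk modulus kappa.
    Accepts batched inputs (..., 3, 3).
    """
    F_e = np.asarray(F_e, dtype=float)
    C = np.einsum("...ki,...kj->...ij", F_e, F_e)
    J = np.linalg.det(F_e)
    if np.any(J <= 0):
        raise MacroSolverError("non-positive elastic Jacobian")
    Cinv = np.linalg.inv(C)
    I1 = np.trace(C, axis1=-2, axis2=-1)
    eye = np.broadcast_to(np.eye(3), C.shape)
    Jm23 = J ** (-2.0 / 3.0)
    S = (mu * Jm23[..., None, None]
         * (eye - (I1 / 3.0)[..., None, None] * Cinv)
         + (kappa * J * (J - 1.0))[..., None, None] * Cinv)
    return S


def tumour_energy_density(F_e: np.ndarray, mu: float, kappa: float):
    F_e = np.asarray(F_e, dtype=float)
    C = np.einsum("...ki,...kj->...ij", F_e, F_e)
    J = np.linalg.det(F_e)
    if np.any(J <= 0):
        raise MacroSolverError("non-positive elastic Jacobian")
    I1 = np.trace(C, axis1=-2, axis2=-1)
    return 0.5 * mu * (J ** (-2.0 / 3.0) * I1 - 3.0) + 0.5 * kappa * (J - 1.0) ** 2


def darcy_velocity(K, theta_f, grad_p, d=None):
    """Darcy fluid velocity V^F = -K (theta_f grad P + d)."""
    K = np.asarray(K, dtype=float)
    grad_p = np.asarray(grad_p, dtype=float)
    rhs = theta_f * grad_p
    if d is not None:
        rhs = rhs + np.asarray(d, dtype=float)
    return -np.einsum("...ij,...j->...i", K, rhs)


def isotropic_stiffness(mu: float, kappa: float) -> np.ndarray:
    """(3,3,3,3) small-strain stiffness from shear and bulk moduli."""
    lam = kappa - 2.0 * mu / 3.0
    eye = np.eye(3)
    II = np.einsum("ij,kl->ijkl", eye, eye)
    sym = 0.5 * (np.einsum("ik,jl->ijkl", eye, eye)
                 + np.einsum("il,jk->ijkl", eye, eye))
    return lam * II + 2.0 * mu * sym


@dataclass
class LinearStroma:
    """St. Venant-Kirchhoff stroma: S = C : E, isotropic (mu, kappa)."""

    mu: float
    kappa: float
    k_iso: float = 1.0e-5    # mm^2/(Pa h), constant isotropic permeability
    theta_s: float = 0.003

    def __post_init__(self):
        self.C = isotropic_stiffness(self.mu, self.kappa)


class SurrogateStroma:
    """Stroma stress linearised about the last homogenised state.

    Per quadrature point S(E) = S0 + C : (E - E0); the baseline (S0, E0) is
    refreshed from the fibre-network upscaling each coupling pass, so the
    converged coupled state satisfies equilibrium with the true homogenised
    stress.
    """

    def __init__(self, n_elem: int, n_qp: int, C: np.ndarray,
                 theta_s: float = 0.003):
        self.C = C
        self.theta_s = theta_s
        self.S0 = np.zeros((n_elem, n_qp, 3, 3))
        self.E0 = np.zeros((n_elem, n_qp, 3, 3))


# ---------------------------------------------------------------------------
# the solver
# ---------------------------------------------------------------------------

@dataclass
class MacroState:
    """Snapshot of the macroscale solution."""

    t: float
    U: np.ndarray            # (n_nodes, 3) mm
    P: np.ndarray            # (n_pressure_nodes,) Pa
    V_S: np.ndarray          # (n_nodes, 3) mm/h
    V_F: np.ndarray          # (n_elem, 3) mm/h, at the element fluid point
    F: np.ndarray            # (n_elem, 8, 3, 3)
    S: np.ndarray            # (n_elem, 8, 3, 3) 2nd PK
    growth: float


class MacroSolver:
    """Quasi-static U-P solver on a MacroMesh.

    The stromal constitutive response is either a LinearStroma material or a
    SurrogateStroma refreshed by the multiscale driver; per-element fluid
    sets (K, d, Q^F) can likewise be updated between steps.
    """

    def __init__(
        self,
        mesh: MacroMesh,
        tumour: TumourMaterial | None,
        stroma,
        biot_modulus: float = 1.0e4,
        fix_normal_tags=("symmetry", "external"),
        drained_tags=(),
        tractions: dict | None = None,
        stagger_tol: float = 1e-8,
        max_stagger: int = 12,
        lbfgs_maxiter: int = 4000,
        grad_tol: float = 1e-8,
    ):
        self.mesh = mesh
        self.tumour = tumour
        self.stroma = stroma
        self.M = biot_modulus
        self.stagger_tol = stagger_tol
        self.max_stagger = max_stagger
        self.lbfgs_maxiter = lbfgs_maxiter
        self.grad_tol = grad_tol

        E = mesh.n_elements
        self.K_elem = np.zeros((E, 3, 3))
        self.d_elem = np.zeros((E, 3))
        self.QF_elem = np.zeros(E)
        tum = mesh.region == REGION_TUMOUR
        if tumour is not None:
            self.K_elem[tum] = tumour.k_o * np.eye(3)
        if isinstance(stroma, LinearStroma):
            self.K_elem[~tum] = stroma.k_iso * np.eye(3)
        self.theta_s_elem = np.where(
            tum,
            tumour.theta_s if tumour is not None else 0.5,
            getattr(stroma, "theta_s", 0.003),
        )
        self.V_F = np.zeros((E, 3))

        self._setup_quadrature()
        self._setup_constraints(fix_normal_tags)
        self._setup_pressure(drained_tags)
        self._setup_tractions(tractions or {})

        n = len(mesh.nodes)
        self.U = np.zeros((n, 3))
        self.U_prev = np.zeros((n, 3))
        self.P = np.zeros(self.n_p)
        self.t = 0.0

    # -- setup --------------------------------------------------------------

    def _setup_quadrature(self):
        mesh = self.mesh
        X = mesh.nodes[mesh.elements]           # (E, 27, 3)

        # solid terms: full 3x3x3 rule (rank-sufficient for Q2 displacements)
        pts3, wts3 = gauss_points(3)
        _, dN27_3 = hex27_shape(pts3)
        J = np.einsum("pad,eai->epid", dN27_3, X)
        detJ = np.linalg.det(J)
        if np.any(detJ <= 0):
            raise MacroSolverError("mesh has non-positive Jacobians")
        Jinv = np.linalg.inv(J)
        self.qp_w = wts3[None, :] * detJ                        # (E, 27)
        self.dN27 = np.einsum("pad,epdi->epai", dN27_3, Jinv)   # (E,27,27,3)
        self.N8 = hex8_shape(pts3)[0]                           # (27qp, 8)
        self.n_qp = len(wts3)
        # cluster map: each solid point is attached to the nearest of the
        # 8 standard 2x2x2 sampling points (one RVE per octant)
        self.qp_cluster = ((pts3[:, 0] > 0).astype(int)
                           + 2 * (pts3[:, 1] > 0).astype(int)
                           + 4 * (pts3[:, 2] > 0).astype(int))

        # fluid matrices: 2x2x2 rule (exact for trilinear pressure with the
        # element-centre constitutive set)
        pts2, wts2 = gauss_points(2)
        _, dN27_2 = hex27_shape(pts2)
        N8f, dN8_2 = hex8_shape(pts2)
        J2 = np.einsum("pad,eai->epid", dN27_2, X)
        J2inv = np.linalg.inv(J2)
        self.qp_wf = wts2[None, :] * np.linalg.det(J2)          # (E, 8)
        self.dN27f = np.einsum("pad,epdi->epai", dN27_2, J2inv)  # (E,8,27,3)
        self.dN8 = np.einsum("pad,epdi->epai", dN8_2, J2inv)    # (E,8,8,3)
        self.N8f = N8f                                          # (8qp, 8)
        # parent positions of the 8 sampling (RVE) points
        self.rve_points = pts2

        centre = np.zeros((1, 3))
        _, dN27c = hex27_shape(centre)
        _, dN8c = hex8_shape(centre)
        Jc = np.einsum("pad,eai->epid", dN27c, X)[:, 0]
        self.centre_w = 8.0 * np.linalg.det(Jc)               # (E,)
        Jcinv = np.linalg.inv(Jc)
        self.dN27c = np.einsum("ad,edi->eai", dN27c[0], Jcinv)
        self.dN8c = np.einsum("ad,edi->eai", dN8c[0], Jcinv)
        self.N8c = hex8_shape(centre)[0][0]

    def _face_nodes27(self, face: int):
        axis, side = FACES[face]
        ia = _AXIS[axis]
        ids = []
        for k in range(3):
            for j in range(3):
                for i in range(3):
                    idx = [i, j, k]
                    if idx[ia] == (0 if side == 0 else 2):
                        ids.append(i + 3 * j + 9 * k)
        return ids

    def _setup_constraints(self, fix_normal_tags):
        mesh = self.mesh
        n = len(mesh.nodes)
        normals: list[list[np.ndarray]] = [[] for _ in range(n)]

        def add(node, vec):
            for v in normals[node]:
                if abs(v @ vec) > 1.0 - 1e-9:
                    return
            normals[node].append(vec)

        for tag in fix_normal_tags:
            for elem, fc in mesh.facet_tags.get(tag, []):
                fnodes = mesh.elements[elem][self._face_nodes27(fc)]
                nrm = mesh.facet_normal(elem, fc)
                if tag == "symmetry" or np.max(np.abs(nrm)) > 1.0 - 1e-9:
                    ax = int(np.argmax(np.abs(nrm)))
                    vec = np.eye(3)[ax]
                    for nd in fnodes:
                        add(nd, vec)
                else:
                    # curved (spherical) boundary: radial direction per node
                    for nd in fnodes:
                        x = mesh.nodes[nd]
                        r = np.linalg.norm(x)
                        if r > 0:
                            add(nd, x / r)
        rows, cols, vals = [], [], []
        nfree = 0
        for nd in range(n):
            cons = normals[nd]
            if not cons:
                basis = np.eye(3)
            else:
                A = np.array(cons)
                _, s, Vt = np.linalg.svd(A)
                rank = int(np.sum(s > 1e-9))
                basis = Vt[rank:].T        # (3, 3-rank)
            for k in range(basis.shape[1]):
                for i in range(3):
                    v = basis[i, k]
                    if v != 0.0:
                        rows.append(3 * nd + i)
                        cols.append(nfree)
                        vals.append(v)
                nfree += 1
        self.Z = sp.csr_matrix((vals, (rows, cols)), shape=(3 * n, nfree))
        self.n_free = nfree

    def _setup_pressure(self, drained_tags):
        mesh = self.mesh
        self.n_p = len(mesh.pressure_nodes)
        self.p_conn = mesh.pressure_index[mesh.corner_elements]   # (E, 8)
        # constant storage matrix
        rows, cols, vals = [], [], []
        for e in range(mesh.n_elements):
            m = np.einsum("p,pa,pb->ab", self.qp_wf[e] / self.M,
                          self.N8f, self.N8f)
            for a in range(8):
                for b in range(8):
                    rows.append(self.p_conn[e, a])
                    cols.append(self.p_conn[e, b])
                    vals.append(m[a, b])
        self.A_storage = sp.csr_matrix((vals, (rows, cols)),
                                       shape=(self.n_p, self.n_p))
        # constant U-P coupling blocks for the monolithic Newton solve
        n = len(mesh.nodes)
        # dR_u/dP: from the -int p div(u) term (solid quadrature)
        cup = -np.einsum("ep,pb,epai->eaib", self.qp_w, self.N8, self.dN27)
        udofs = (3 * mesh.elements[:, :, None]
                 + np.arange(3)[None, None, :]).reshape(mesh.n_elements, 81)
        rows = np.repeat(udofs, 8, axis=1).ravel()
        cols = np.tile(self.p_conn, (1, 81)).ravel()
        self.C_up = sp.csr_matrix(
            (cup.reshape(mesh.n_elements, -1).ravel(), (rows, cols)),
            shape=(3 * n, self.n_p))
        # dR_p/dU: theta_s int psi div(dU) (fluid quadrature); note the
        # pressure residual is scaled by dt, so no 1/dt factor appears
        cpu = np.einsum("e,ep,pb,epai->ebai", self.theta_s_elem, self.qp_wf,
                        self.N8f, self.dN27f)
        rows = np.repeat(self.p_conn, 81, axis=1).ravel()
        cols = np.tile(udofs, (1, 8)).ravel()
        self.C_pu = sp.csr_matrix(
            (cpu.reshape(mesh.n_elements, -1).ravel(), (rows, cols)),
            shape=(self.n_p, 3 * n))
        drained = set()
        for tag in drained_tags:
            for elem, fc in mesh.facet_tags.get(tag, []):
                axis, side = FACES[fc]
                ia = _AXIS[axis]
                for c8, nd in enumerate(mesh.corner_elements[elem]):
                    idx = [(c8 >> b) & 1 for b in range(3)]
                    if idx[ia] == (0 if side == 0 else 1):
                        drained.add(mesh.pressure_index[nd])
        self.drained_dofs = np.array(sorted(drained), dtype=int)

    def _setup_tractions(self, tractions):
        """tractions: tag -> constant traction vector (Pa, reference area)."""
        n = len(self.mesh.nodes)
        F = np.zeros((n, 3))
        for tag, tvec in tractions.items():
            tvec = np.asarray(tvec, dtype=float)
            facets = self.mesh.facet_tags.get(tag, np.zeros((0, 2), int))
            pts, w, _ = self.mesh.facet_area_normals(facets, order=3)
            for fi, (elem, fc) in enumerate(facets):
                N, _ = hex27_shape(pts[fi])
                contrib = np.einsum("p,pa->a", w[fi], N)
                np.add.at(F, self.mesh.elements[elem], contrib[:, None] * tvec)
        self.F_ext = F

    # -- mechanics ----------------------------------------------------------

    def _grad_u(self, U):
        u_e = U[self.mesh.elements]                     # (E, 27, 3)
        return np.einsum("eai,epaj->epij", u_e, self.dN27)

    def _stress_energy(self, F, t):
        """Per-qp energy density and 1st Piola stress for all elements."""
        mesh = self.mesh
        E = mesh.n_elements
        nq = F.shape[1]
        W = np.zeros((E, nq))
        P1 = np.zeros((E, nq, 3, 3))
        S_out = np.zeros((E, nq, 3, 3))
        tum = mesh.region == REGION_TUMOUR
        if np.any(tum) and self.tumour is not None:
            f = self.tumour.growth.stretch(t)
            Fe = F[tum] / f
            Se = tumour_pk2_stress(Fe, self.tumour.mu, self.tumour.kappa)
            W[tum] = f**3 * tumour_energy_density(Fe, self.tumour.mu,
                                                  self.tumour.kappa)
            P1[tum] = f**2 * np.einsum("...ik,...kj->...ij", Fe, Se)
            S_out[tum] = f * Se
        stro = ~tum
        if np.any(stro):
            Fs = F[stro]
            Egr = 0.5 * (np.einsum("...ki,...kj->...ij", Fs, Fs)
                         - np.eye(3))
            if isinstance(self.stroma, LinearStroma):
                S = np.einsum("ijkl,...kl->...ij", self.stroma.C, Egr)
                W[stro] = 0.5 * np.einsum("...ij,...ij->...", S, Egr)
            else:
                sub = self._stroma_sub(stro)
                dE = Egr - self.stroma.E0[sub]
                S = (self.stroma.S0[sub]
                     + np.einsum("ijkl,...kl->...ij", self.stroma.C, dE))
                W[stro] = (np.einsum("...ij,...ij->...",
                                     self.stroma.S0[sub], dE)
                           + 0.5 * np.einsum("...ij,ijkl,...kl->...",
                                             dE, self.stroma.C, dE))
            P1[stro] = np.einsum("...ik,...kj->...ij", Fs, S)
            S_out[stro] = S
        return W, P1, S_out

    def _stroma_sub(self, stro_mask):
        if not hasattr(self, "_stroma_index"):
            idx = np.full(self.mesh.n_elements, -1, dtype=int)
            idx[stro_mask] = np.arange(int(stro_mask.sum()))
            self._stroma_index = idx
        return self._stroma_index[stro_mask]

    def _pressure_at_qp(self, P):
        p_e = P[self.p_conn]                             # (E, 8)
        return np.einsum("pa,ea->ep", self.N8, p_e)

    def _energy_grad(self, q, t, P):
        U = (self.Z @ q).reshape(-1, 3)
        gradU = self._grad_u(U)
        F = gradU + np.eye(3)
        try:
            W, P1, _ = self._stress_energy(F, t)
        except MacroSolverError:
            # invalid trial state (inverted element): infinite energy and an
            # infinite gradient so it can never be accepted as converged
            return np.inf, np.full_like(q, np.inf)
        p_qp = self._pressure_at_qp(P)
        divU = np.trace(gradU, axis1=-2, axis2=-1)
        energy = float(np.sum(self.qp_w * (W - p_qp * divU)))
        energy -= float(np.sum(self.F_ext * U))
        # gradient
        P1_eff = P1 - p_qp[..., None, None] * np.eye(3)
        g = np.zeros_like(U)
        contrib = np.einsum("ep,epij,epaj->eai", self.qp_w, P1_eff, self.dN27)
        np.add.at(g, self.mesh.elements, contrib)
        g -= self.F_ext
        return energy, self.Z.T @ g.reshape(-1)

    def _first_elasticity_fd(self, F, t, h=1e-7):
        """First elasticity tensor A = dP1/dF by central differences,
        batched over all quadrature points: (E, 8, 3, 3, 3, 3)."""
        E, q = F.shape[:2]
        A = np.empty((E, q, 3, 3, 3, 3))
        for i in range(3):
            for k in range(3):
                dF = np.zeros((3, 3))
                dF[i, k] = h
                _, P1p, _ = self._stress_energy(F + dF, t)
                _, P1m, _ = self._stress_energy(F - dF, t)
                A[..., i, k] = np.transpose((P1p - P1m) / (2 * h),
                                            (0, 1, 2, 3))
        # A[..., j, l, i, k] currently holds dP1_jl/dF_ik; reorder
        return np.transpose(A, (0, 1, 4, 5, 2, 3))

    def _assemble_stiffness(self, F, t):
        A = self._first_elasticity_fd(F, t)          # (E, p, i, k, j, l)
        E, p = A.shape[:2]
        # tmp[e,p,a,(i j l)] = sum_k dN[e,p,a,k] A[e,p,k,(i j l)]
        A1 = np.transpose(A, (0, 1, 3, 2, 4, 5)).reshape(E, p, 3, 27)
        tmp = self.dN27 @ A1                         # (E, p, 27a, 27=(i j l))
        # Ke[e,a,i,b,j] = sum_p w * sum_l tmp[e,p,a,(i j),l] dN[e,p,b,l]
        tmp = tmp.reshape(E, p, 27, 3, 3, 3)         # (e,p,a,i,j,l)
        tmp = np.transpose(tmp, (0, 1, 2, 3, 4, 5)).reshape(E, p, 27 * 9, 3)
        Kp = tmp @ np.transpose(self.dN27, (0, 1, 3, 2))  # (E,p,27*9,27b)
        Kp = Kp.reshape(E, p, 27, 3, 3, 27)
        Ke = np.einsum("ep,epaijb->eaibj", self.qp_w, Kp)
        n = len(self.mesh.nodes)
        dofs = (3 * self.mesh.elements[:, :, None]
                + np.arange(3)[None, None, :])          # (E, 27, 3)
        dofs = dofs.reshape(self.mesh.n_elements, 81)
        rows = np.repeat(dofs, 81, axis=1).ravel()
        cols = np.tile(dofs, (1, 81)).ravel()
        K = sp.csr_matrix((Ke.reshape(self.mesh.n_elements, -1).ravel(),
                           (rows, cols)), shape=(3 * n, 3 * n))
        return K

    def solve_mechanics(self, t):
        """Newton iteration on the constrained momentum residual; falls back
        to L-BFGS energy minimisation if the line search stalls."""
        q = self.Z.T @ self.U.reshape(-1)
        energy, grad = self._energy_grad(q, t, self.P)
        force_scale = max(float(np.abs(self.qp_w).max())
                          * self._stress_scale(),
                          float(np.abs(self.F_ext).max()), 1e-12)
        tol = self.grad_tol * force_scale
        for it in range(30):
            gnorm = np.abs(grad).max()
            if gnorm < tol:
                self.U = (self.Z @ q).reshape(-1, 3)
                return gnorm
            U = (self.Z @ q).reshape(-1, 3)
            F = self._grad_u(U) + np.eye(3)
            K = self._assemble_stiffness(F, t)
            Kr = (self.Z.T @ K @ self.Z).tocsc()
            try:
                dq = spla.spsolve(Kr, -grad)
            except Exception:
                break
            if not np.all(np.isfinite(dq)):
                break
            slope = float(grad @ dq)
            if slope > 0:
                dq = -grad * (np.linalg.norm(dq) / max(np.linalg.norm(grad),
                                                       1e-30))
                slope = float(grad @ dq)
            alpha, ok = 1.0, False
            for _ in range(20):
                e_try, g_try = self._energy_grad(q + alpha * dq, t, self.P)
                if np.isfinite(e_try) and (
                        e_try <= energy + 1e-4 * alpha * slope
                        or np.abs(g_try).max() < gnorm):
                    q = q + alpha * dq
                    energy, grad = e_try, g_try
                    ok = True
                    break
                alpha *= 0.5
            if not ok:
                break
        else:
            self.U = (self.Z @ q).reshape(-1, 3)
            return np.abs(grad).max()
        # fallback: quasi-Newton descent on the energy
        res = minimize(
            self._energy_grad, q, args=(t, self.P), jac=True,
            method="L-BFGS-B",
            options=dict(maxiter=self.lbfgs_maxiter, maxcor=30,
                         ftol=1e-18, gtol=0.5 * tol),
        )
        if not np.isfinite(res.fun):
            raise MacroSolverError("mechanics solve diverged (negative J)")
        self.U = (self.Z @ res.x).reshape(-1, 3)
        return np.abs(res.jac).max()

    def _stress_scale(self) -> float:
        vals = []
        if self.tumour is not None:
            vals += [self.tumour.mu, self.tumour.kappa]
        if isinstance(self.stroma, (LinearStroma,)):
            vals += [self.stroma.mu, self.stroma.kappa]
        elif self.stroma is not None:
            vals.append(float(np.abs(self.stroma.C).max()))
        vals.append(float(np.abs(self.P).max()) if self.n_p else 0.0)
        return max(max(vals), 1.0)

    # -- time stepping ------------------------------------------------------

    def _pressure_residual(self, dt, U, P, P_old, U_old, A_diff, b_const):
        """dt-scaled mass-balance residual: A_st (P - Pold) + dt A_diff P
        + theta_s int psi div(U - Uold) - dt (sources)."""
        R = (self.A_storage @ (P - P_old) + dt * (A_diff @ P)
             + self.C_pu @ (U - U_old).reshape(-1) - dt * b_const)
        if len(self.drained_dofs):
            R[self.drained_dofs] = P[self.drained_dofs]
        return R

    def _const_sources(self):
        """Pressure-equation source terms that do not depend on (U, P):
        Q^F and the mixing-vector flux."""
        theta_f = 1.0 - self.theta_s_elem
        b = np.zeros(self.n_p)
        contrib = np.einsum("ep,e,pa->ea", self.qp_wf, self.QF_elem, self.N8f)
        np.add.at(b, self.p_conn, contrib)
        kd = np.einsum("e,eij,ej->ei", theta_f, self.K_elem, self.d_elem)
        contrib = -np.einsum("ep,epai,ei->ea", self.qp_wf, self.dN8, kd)
        np.add.at(b, self.p_conn, contrib)
        return b

    def _diffusion_matrix(self):
        theta_f = 1.0 - self.theta_s_elem
        a_diff = np.einsum("e,ep,epai,eij,epbj->eab", theta_f**2, self.qp_wf,
                           self.dN8, self.K_elem, self.dN8)
        rows = np.repeat(self.p_conn, 8, axis=1).ravel()
        cols = np.tile(self.p_conn, (1, 8)).ravel()
        return sp.csr_matrix((a_diff.ravel(), (rows, cols)),
                             shape=(self.n_p, self.n_p))

    def step(self, dt) -> dict:
        """Advance one time step with a monolithic Newton solve of the
        coupled momentum + mass-balance system (backward Euler in time)."""
        t_new = self.t + dt
        P_old = self.P.copy()
        U_old = self.U_prev.copy()
        A_diff = self._diffusion_matrix()
        b_const = self._const_sources()
        # residual scale from the physical rows, before any Dirichlet
        # replacement puts unit diagonals in
        p_scale = max(float(np.abs((self.A_storage
                                    + dt * A_diff).diagonal()).max()), 1e-30)
        A_pp = (self.A_storage + dt * A_diff).tolil()
        C_pu = self.C_pu
        if len(self.drained_dofs):
            C_pu = C_pu.tolil()
            for dof in self.drained_dofs:
                A_pp.rows[dof] = [dof]
                A_pp.data[dof] = [1.0]
                C_pu.rows[dof] = []
                C_pu.data[dof] = []
            C_pu = C_pu.tocsr()
        A_pp = A_pp.tocsr()
        Cup_r = self.Z.T @ self.C_up
        Cpu_r = C_pu @ self.Z

        q = self.Z.T @ self.U.reshape(-1)
        P = self.P.copy()
        force_scale = max(float(np.abs(self.qp_w).max()) * self._stress_scale(),
                          float(np.abs(self.F_ext).max()), 1e-12)
        tol_u = self.grad_tol * force_scale
        converged = False

        def residuals(q_, P_):
            U_ = (self.Z @ q_).reshape(-1, 3)
            _, R_u_ = self._energy_grad(q_, t_new, P_)
            R_p_ = self._pressure_residual(dt, U_, P_, P_old, U_old, A_diff,
                                           b_const)
            return R_u_, R_p_

        for it in range(40):
            R_u, R_p = residuals(q, P)
            ru, rp = np.abs(R_u).max(), np.abs(R_p).max()
            if ru < tol_u and rp < self.stagger_tol * p_scale * max(
                    1.0, float(np.abs(P).max())):
                converged = True
                break
            U = (self.Z @ q).reshape(-1, 3)
            F = self._grad_u(U) + np.eye(3)
            K = self._assemble_stiffness(F, t_new)
            Kr = (self.Z.T @ K @ self.Z).tocsr()
            A = sp.bmat([[Kr, Cup_r], [Cpu_r, A_pp]], format="csc")
            rhs = -np.concatenate([R_u, R_p])
            try:
                dx = spla.spsolve(A, rhs)
            except Exception as exc:  # pragma: no cover
                raise MacroSolverError(f"coupled linear solve failed: {exc}")
            if not np.all(np.isfinite(dx)):
                raise MacroSolverError("coupled Newton produced non-finite "
                                       "increment")
            dq, dP = dx[: self.n_free], dx[self.n_free:]
            # Armijo backtracking on the scaled squared residual norm; the
            # Newton direction is a descent direction for this merit function
            phi0 = (np.sum((R_u / force_scale) ** 2)
                    + np.sum((R_p / p_scale) ** 2))
            alpha, accepted = 1.0, False
            while alpha > 1e-8:
                R_u_t, R_p_t = residuals(q + alpha * dq, P + alpha * dP)
                phi_t = (np.sum((R_u_t / force_scale) ** 2)
                         + np.sum((R_p_t / p_scale) ** 2))
                if np.isfinite(phi_t) and phi_t < (1 - 1e-4 * alpha) * phi0:
                    accepted = True
                    break
                alpha *= 0.5
            if not accepted:
                break  # stay at the last accepted state
            q, P = q + alpha * dq, P + alpha * dP
        if not converged and (ru > 100 * tol_u or not np.isfinite(ru)):
            raise MacroSolverError(
                f"coupled Newton did not converge: |R_u|={ru:.3e}, "
                f"|R_p|={rp:.3e} at t={t_new:g}")
        self.U = (self.Z @ q).reshape(-1, 3)
        self.P = P
        self.t = t_new
        audit = self._mass_audit(dt, P_old, U_old, A_diff, b_const)
        self.U_prev = self.U.copy()
        self._update_fluid_velocity()
        return {"t": self.t, "newton_iters": it + 1, "grad_norm": float(ru),
                "pressure_residual": float(rp), "mass_residual": audit,
                "P_max": float(np.abs(self.P).max())}

    def _mass_audit(self, dt, P_old, U_old, A_diff, b_const) -> float:
        """Global discrete mass balance: storage + solid compaction +
        transport - sources, normalised by the largest term.  Zero to solver
        precision when every boundary is sealed (drained boundaries exchange
        mass, so the raw imbalance is reported there)."""
        one = np.ones(self.n_p)
        storage = float(one @ (self.A_storage @ (self.P - P_old)))
        compaction = float(one @ (self.C_pu @ (self.U - U_old).reshape(-1)))
        transport = dt * float(one @ (A_diff @ self.P))
        source = dt * float(one @ b_const)
        num = abs(storage + compaction + transport - source)
        den = max(abs(storage), abs(compaction), abs(transport), abs(source),
                  1e-30)
        return num / den

    def _update_fluid_velocity(self):
        theta_f = 1.0 - self.theta_s_elem
        p_e = self.P[self.p_conn]
        grad_p = np.einsum("ea,eai->ei", p_e, self.dN8c)
        self.V_F = darcy_velocity(self.K_elem, theta_f[:, None], grad_p,
                                  self.d_elem)

    # -- state access -------------------------------------------------------

    def qp_state(self, t=None):
        """(F, S) per solid quadrature point at the current displacements."""
        t = self.t if t is None else t
        F = self._grad_u(self.U) + np.eye(3)
        _, _, S = self._stress_energy(F, t)
        return F, S

    def state(self) -> MacroState:
        F, S = self.qp_state()
        dt_guard = 1.0
        V_S = (self.U - self.U_prev) / dt_guard
        return MacroState(t=self.t, U=self.U.copy(), P=self.P.copy(),
                          V_S=V_S, V_F=self.V_F.copy(), F=F, S=S,
                          growth=(self.tumour.growth.stretch(self.t)
                                  if self.tumour else 1.0))
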