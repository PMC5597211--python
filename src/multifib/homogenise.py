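"""Upscaling of microscale fibre-network equilibria to macroscale fields.

Volume averaging turns each RVE equilibrium into the macroscale constitutive
set for its quadrature point: the 2nd Piola-Kirchhoff stress S (a surface sum
of boundary-crossing fibre forces), the body-force correction Q, the
permeability K (a sum of per-fibre permeabilities built from cylinder-array
drag coefficients), the mixing vector d and the fluid source Q^F.  All sums
are over the deformed configuration; results are parametric and are mapped to
physical units with the dimensionalisation factor eta = theta_s V / (a_f L).

Per-fibre permeability follows the square-array-of-cylinders drag model:
parallel flow sees drag c11 and perpendicular flow c22 = c33, with
c22/c11 -> 2 in the dilute limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import FibreNetwork, MicroState, dimensionalisation_factor  # noqa: F401


class HomogenisationError(ValueError):
    pass


@dataclass
class UpscaledSet:
    """Homogenised macroscale quantities at one stromal quadrature point."""

    S: np.ndarray        # (3,3) 2nd PK stress, Pa
    Q: np.ndarray        # (3,) body-force/source vector, Pa/mm
    K: np.ndarray        # (3,3) permeability, mm^2 / (Pa h)
    d: np.ndarray        # (3,) mixing vector, Pa/mm
    QF: float            # fluid source, 1/h
    eta: float           # dimensionalisation factor (current frame)


# ---------------------------------------------------------------------------
# drag and per-fibre permeability
# ---------------------------------------------------------------------------

def drag_matrix(theta_s: float, length: float) -> np.ndarray:
    """Diagonal fibre drag matrix for steady flow past a square cylinder
    array: parallel (c11) and perpendicular (c22 = c33) components.

    ``length`` is the fibre length in the current frame; both components are
    linear in it.
    """
    if not 0.0 < theta_s < 1.0:
        raise HomogenisationError("theta_s must lie in (0, 1)")
    if length <= 0:
        raise HomogenisationError("fibre length must be positive")
    log = -np.log(theta_s)
    den_par = log - 1.476 + 2.0 * theta_s - 0.5 * theta_s**2
    den_perp = log - 1.476 + 2.0 * theta_s - 1.774 * theta_s**2
    if den_par <= 0 or den_perp <= 0:
        raise HomogenisationError(
            f"drag formula invalid at theta_s={theta_s:g}: the dilute "
            "cylinder-array expansion requires a lower solid fraction"
        )
    c11 = 4.0 * np.pi * length / den_par
    c22 = 8.0 * np.pi * length / den_perp
    return np.diag([c11, c22, c22])


def _direction_cosine_matrix(n_f: np.ndarray) -> np.ndarray:
    """Orthonormal rows with the first row along the fibre axis."""
    n_f = np.asarray(n_f, dtype=float)
    n_f = n_f / np.linalg.norm(n_f)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(n_f[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    t1 = np.cross(n_f, helper)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(n_f, t1)
    return np.vstack([n_f, t1, t2])


def fibre_permeability(n_f: np.ndarray, c: np.ndarray) -> np.ndarray:
    """k = (r^T c r)^-1 with r the fibre direction cosine matrix.

    Eigenvalues are 1/c11 (along the fibre) and 1/c22, 1/c33 (transverse).
    """
    c = np.asarray(c, dtype=float)
    diag = np.diag(c)
    if np.any(diag == 0.0):
        raise HomogenisationError("singular drag matrix")
    r = _direction_cosine_matrix(n_f)
    return r.T @ np.diag(1.0 / diag) @ r


def _fibre_permeabilities(net: FibreNetwork, dirs: np.ndarray,
                          lengths: np.ndarray,
                          theta_s: float | None = None) -> np.ndarray:
    """(F, 3, 3) per-fibre permeabilities in the deformed configuration,
    vectorised over fibres.  ``theta_s`` overrides the network's reference
    volume fraction (used for current-frame packing)."""
    theta = net.theta_s if theta_s is None else theta_s
    log = -np.log(theta)
    den_par = log - 1.476 + 2.0 * theta - 0.5 * theta**2
    den_perp = log - 1.476 + 2.0 * theta - 1.774 * theta**2
    if den_par <= 0 or den_perp <= 0:
        raise HomogenisationError(
            f"drag formula invalid at theta_s={theta:g}"
        )
    inv_par = den_par / (4.0 * np.pi * lengths)     # 1/c11
    inv_perp = den_perp / (8.0 * np.pi * lengths)   # 1/c22 = 1/c33
    nn = np.einsum("fi,fj->fij", dirs, dirs)
    eye = np.eye(3)[None, :, :]
    return inv_perp[:, None, None] * (eye - nn) + inv_par[:, None, None] * nn


# ---------------------------------------------------------------------------
# volume-averaged upscaling (parametric frame)
# ---------------------------------------------------------------------------

def _require_state(state: MicroState, net: FibreNetwork):
    if state.dirs.shape[0] != net.n_fibres:
        raise HomogenisationError("micro state does not match the network")


def boundary_crossings(net: FibreNetwork):
    """(fibre, boundary node, interior-side node, face normal) per crossing."""
    out = []
    normal_of = {int(b): net.boundary_normals[i]
                 for i, b in enumerate(net.boundary_nodes)}
    for f, (a, b) in enumerate(net.fibres):
        if net.is_boundary[a]:
            out.append((f, int(a), int(b), normal_of[int(a)]))
        if net.is_boundary[b]:
            out.append((f, int(b), int(a), normal_of[int(b)]))
    return out


def upscale_stress(net: FibreNetwork, state: MicroState) -> np.ndarray:
    """S = (1/V) sum over boundary crossings of f (n_f_out ⊗ n), symmetrised.

    n_f_out is the current fibre direction pointing out through the crossing
    and n the outward face normal; tension produces positive normal stress.
    """
    _require_state(state, net)
    crossings = boundary_crossings(net)
    if not crossings:
        raise HomogenisationError("network has no boundary-crossing fibres")
    x = net.nodes + state.u
    S = np.zeros((3, 3))
    for f, bnode, onode, nrm in crossings:
        d_out = x[bnode] - x[onode]
        d_out = d_out / np.linalg.norm(d_out)
        S += state.force[f] * np.outer(d_out, nrm)
    S /= net.volume
    return 0.5 * (S + S.T)


def upscale_body_source(net: FibreNetwork, state: MicroState,
                        S: np.ndarray) -> np.ndarray:
    """Q = (1/V) sum over crossings of ((s - S) · u') · n.

    u' is the directional derivative of the micro displacement at the
    boundary node, approximated along the incident fibre.
    """
    _require_state(state, net)
    crossings = boundary_crossings(net)
    if not crossings:
        raise HomogenisationError("network has no boundary-crossing fibres")
    x = net.nodes + state.u
    Q = np.zeros(3)
    for f, bnode, onode, nrm in crossings:
        d_out = x[bnode] - x[onode]
        d_out /= np.linalg.norm(d_out)
        s_end = state.force[f] * np.outer(d_out, nrm)
        d_ref = net.nodes[bnode] - net.nodes[onode]
        l_ref = np.linalg.norm(d_ref)
        du = state.u[bnode] - state.u[onode]
        u_grad = np.outer(du, d_ref / l_ref) / l_ref
        Q += ((s_end - 0.5 * (S + S.T)) @ u_grad) @ nrm
    return Q / net.volume


def upscale_permeability(net: FibreNetwork, state: MicroState,
                         theta_s: float | None = None) -> np.ndarray:
    """K = (1/V) sum over fibres of the per-fibre permeability k, using
    deformed lengths and orientations (and optionally the current packing
    fraction)."""
    _require_state(state, net)
    k = _fibre_permeabilities(net, state.dirs, state.lengths, theta_s)
    K = k.sum(axis=0) / net.volume
    return 0.5 * (K + K.T)


def upscale_mixing(net: FibreNetwork, state: MicroState,
                   v_nodes: np.ndarray) -> np.ndarray:
    """d = (1/V) sum over fibres of k · v^S, with v^S the fibre midpoint
    velocity of the micro solid phase."""
    _require_state(state, net)
    v_nodes = np.asarray(v_nodes, dtype=float)
    k = _fibre_permeabilities(net, state.dirs, state.lengths)
    v_f = 0.5 * (v_nodes[net.fibres[:, 0]] + v_nodes[net.fibres[:, 1]])
    return np.einsum("fij,fj->i", k, v_f) / net.volume


def upscale_fluid_source(net: FibreNetwork, state: MicroState,
                         V_S: np.ndarray,
                         v_nodes: np.ndarray | None = None) -> float:
    """Q^F = (a_f/V) sum over boundary crossings of (V^S - v^S) · n.

    V_S: downscaled macro solid velocity at the boundary nodes ((nb, 3) in
    the order of net.boundary_nodes, or a single vector).  v^S is the fibre
    mean velocity, so the non-affine part of the micro relaxation acts as a
    fluid source.
    """
    _require_state(state, net)
    V_S = np.asarray(V_S, dtype=float)
    if V_S.ndim == 1:
        V_S = np.tile(V_S, (len(net.boundary_nodes), 1))
    if v_nodes is None:
        v_nodes = np.zeros((net.n_nodes, 3))
    order = {int(b): i for i, b in enumerate(net.boundary_nodes)}
    QF = 0.0
    for f, bnode, onode, nrm in boundary_crossings(net):
        v_fibre = 0.5 * (v_nodes[bnode] + v_nodes[onode])
        QF += float((V_S[order[bnode]] - v_fibre) @ nrm)
    return net.a_f * QF / net.volume


# ---------------------------------------------------------------------------
# physical dimensionalisation
# ---------------------------------------------------------------------------

def current_theta_s(net: FibreNetwork, J: float = 1.0) -> float:
    """Current packing fraction theta_s / J, clamped to the validity range
    of the cylinder-array drag expansion."""
    J = max(float(J), 0.2)
    return float(np.clip(net.theta_s / J, 1e-6, 0.2))


def current_eta(net: FibreNetwork, state: MicroState,
                J: float = 1.0) -> float:
    """eta evaluated in the current frame: deformed total fibre length and
    current packing fraction, so network compaction lowers the physical
    permeability."""
    return dimensionalisation_factor(current_theta_s(net, J), net.volume,
                                     net.a_f, float(state.lengths.sum()))


def upscale_all(
    net: FibreNetwork,
    state: MicroState,
    v_nodes: np.ndarray,
    V_S_boundary: np.ndarray,
    viscosity_scale: float,
    rve_side_mm: float,
    v_fluct: np.ndarray | None = None,
    J_rve: float = 1.0,
) -> UpscaledSet:
    """Full homogenised set in physical units (Pa, mm, h).

    The parametric sums are dimensionalised with the uniform substitution
    x_dim = eta x: stresses scale with 1/eta, permeabilities with
    viscosity_scale / eta^4, and the mixing vector is mapped to
    pressure-gradient units through the squared scalar permeability (see the
    methods note).  ``v_fluct`` is the non-affine part of the micro solid
    velocity used in the mixing vector (the affine part is already carried
    by the macroscale solid-velocity terms); it defaults to ``v_nodes``.
    """
    theta_cur = current_theta_s(net, J_rve)
    eta = current_eta(net, state, J_rve)
    S = upscale_stress(net, state) / eta
    Q = upscale_body_source(net, state, S * eta) / eta / rve_side_mm
    K = (upscale_permeability(net, state, theta_cur)
         * viscosity_scale / eta**4)
    QF = upscale_fluid_source(net, state, V_S_boundary, v_nodes)
    if v_fluct is None:
        v_fluct = v_nodes
    d_param = upscale_mixing(net, state, v_fluct)
    kbar = max(np.trace(K) / 3.0, 1e-300)
    d = (viscosity_scale / eta**4) * d_param * rve_side_mm / kbar**2
    return UpscaledSet(S=S, Q=Q, K=K, d=d, QF=QF, eta=eta)
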