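"""Orchestration of the coupled multiscale time stepping.

Each stromal macro element carries one fibre-network RVE at each of its eight
standard sampling points.  Every time step performs the four-stage cycle:

1. macro solve of the coupled momentum/mass system (the stroma responds
   through a stress linearisation about the last homogenised state),
2. downscale: interpolate macro displacements to RVE boundary nodes
   (quadratic shape functions) and pressures to every RVE node (linear),
3. micro solve: truss equilibrium per RVE, warm-started and independent of
   solve order,
4. upscale: volume-averaged stress, body source, permeability, mixing vector
   and fluid source refresh the macro constitutive state (explicit one-step
   lag).

Everything is seeded; repeated runs with the same configuration are
bit-identical.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field

import numpy as np

from . import homogenise as hm
from . import network as nw
from .config import default_config
from .macro import (GrowthLaw, LinearStroma, MacroSolver, SurrogateStroma,
                    TumourMaterial, isotropic_stiffness)
from .mesh import MacroMesh, REGION_STROMA, build_octant_mesh, write_vtu
from .shapes import hex8_shape, hex27_shape


class CouplingError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# coupling map and downscaling
# ---------------------------------------------------------------------------

@dataclass
class RVESlot:
    """One RVE attached to a stromal quadrature point."""

    element: int
    point: int                  # 0..7, octant sampling point
    network: nw.FibreNetwork
    phi: np.ndarray             # (n_boundary, 27) displacement interpolation
    psi: np.ndarray             # (n_nodes, 8) pressure interpolation
    state: nw.MicroState | None = None
    prev_u: np.ndarray | None = None
    upscaled: hm.UpscaledSet | None = None


@dataclass
class CouplingMap:
    """All RVE slots plus the interpolation data used for downscaling."""

    slots: list[RVESlot]
    side_mm: float              # physical RVE side length in mm

    def by_element(self):
        out: dict[int, list[RVESlot]] = {}
        for slot in self.slots:
            out.setdefault(slot.element, []).append(slot)
        return out


def build_coupling_map(mesh: MacroMesh, networks, side_um: float,
                       rve_points: np.ndarray) -> CouplingMap:
    """Attach one network per (stromal element, sampling point) and
    precompute the shape-function values at the RVE node positions.

    ``networks`` maps (element, point) -> FibreNetwork.  RVE parametric
    offsets are converted to parent-element coordinates through the Jacobian
    at the sampling point.
    """
    side_mm = side_um * 1e-3
    slots = []
    stromal = np.flatnonzero(mesh.region == REGION_STROMA)
    _, dN27 = hex27_shape(rve_points)
    X = mesh.nodes[mesh.elements]
    for e in stromal:
        J = np.einsum("pad,ai->pid", dN27, X[e])      # (8, 3, 3)
        Jinv = np.linalg.inv(J)
        for k in range(len(rve_points)):
            net = networks[(int(e), k)]
            offsets = (net.nodes - 0.5) * side_mm      # physical offsets
            parent = rve_points[k] + offsets @ Jinv[k].T
            if np.abs(parent).max() > 1.5:
                raise CouplingError(
                    f"RVE at element {e} point {k} extends far outside its "
                    "host element; the RVE side length is too large for the "
                    "mesh"
                )
            # mild extrapolation beyond the parent cube is tolerated: the
            # shape functions are polynomials and remain a partition of unity
            phi_all, _ = hex27_shape(parent)
            psi_all, _ = hex8_shape(parent)
            bidx = net.boundary_nodes
            slots.append(RVESlot(element=int(e), point=k, network=net,
                                 phi=phi_all[bidx], psi=psi_all))
    return CouplingMap(slots=slots, side_mm=side_mm)


def downscale(slot: RVESlot, mesh: MacroMesh, U: np.ndarray, P: np.ndarray,
              pressure_index: np.ndarray, side_mm: float):
    """Boundary displacements (parametric) and nodal pressures for one RVE.

    u = phi_i U_i mapped into the RVE frame (division by the physical side
    length); p = psi_i P_i at every RVE node.
    """
    conn = mesh.elements[slot.element]
    u_nodes = slot.phi @ U[conn]                   # (nb, 3) in mm
    corners = mesh.corner_elements[slot.element]
    p_e = P[pressure_index[corners]]
    p_nodes = slot.psi @ p_e                       # (n_nodes,)
    return u_nodes / side_mm, p_nodes


# ---------------------------------------------------------------------------
# stroma stiffness probe
# ---------------------------------------------------------------------------

def probe_stroma_stiffness(net: nw.FibreNetwork, viscosity_scale: float,
                           side_mm: float, delta: float = 1e-3):
    """Small-strain stiffness of one RVE by central finite differences of the
    homogenised stress under six affine strain probes; returns the
    symmetrised (3,3,3,3) tensor and its isotropic (mu, kappa) projection."""
    xb = net.nodes[net.boundary_nodes]

    def stress_at(epsilon):
        bu = xb @ epsilon.T
        st = nw.solve_micro_equilibrium(net, bu)
        return hm.upscale_stress(net, st) / hm.current_eta(net, st)

    C = np.zeros((3, 3, 3, 3))
    pairs = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
    for (k, l) in pairs:
        de = np.zeros((3, 3))
        de[k, l] += 0.5 * delta
        de[l, k] += 0.5 * delta
        Sp = stress_at(de)
        Sm = stress_at(-de)
        dS = (Sp - Sm) / (2.0 * delta)
        C[:, :, k, l] = dS
        C[:, :, l, k] = dS
    # enforce minor and major symmetry
    C = 0.25 * (C + np.transpose(C, (1, 0, 2, 3))
                + np.transpose(C, (0, 1, 3, 2))
                + np.transpose(C, (1, 0, 3, 2)))
    C = 0.5 * (C + np.transpose(C, (2, 3, 0, 1)))
    # isotropic projection (closest isotropic tensor in Frobenius norm)
    eye = np.eye(3)
    lam_tr = np.einsum("iikk->", C)
    mu_tr = np.einsum("ikik->", C)
    lam = (2.0 * lam_tr - mu_tr) / 15.0
    mu = (3.0 * mu_tr - lam_tr) / 30.0
    kappa = lam + 2.0 * mu / 3.0
    return C, float(mu), float(kappa)


# ---------------------------------------------------------------------------
# the coupled run
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    """Outcome of a coupled simulation, kept in memory for postprocessing."""

    config: dict
    mesh: MacroMesh
    solver: MacroSolver
    coupling: CouplingMap
    history: list = field(default_factory=list)
    initial_orientation: dict = field(default_factory=dict)
    output_dir: str | None = None

    @property
    def radius_increase(self) -> float:
        """Relative tumour radius increase (fraction) at the current state."""
        return interface_radial_displacement(self.mesh, self.solver.U) \
            / self.config["geometry"]["r_tumour"]

    @property
    def pts_strain(self) -> float:
        """Magnitude of PTS thickness change over the initial thickness."""
        return abs(interface_radial_displacement(self.mesh, self.solver.U)
                   - external_radial_displacement(self.mesh, self.solver.U)) \
            / self.config["geometry"]["pts_thickness"]


def _face_nodes(mesh, solver, tag):
    nodes = set()
    for e, f in mesh.facet_tags[tag]:
        nodes.update(mesh.elements[e][solver._face_nodes27(f)])
    return np.array(sorted(nodes))


def interface_radial_displacement(mesh: MacroMesh, U: np.ndarray) -> float:
    nodes = set()
    from .macro import MacroSolver as _MS  # face-node helper is on the solver
    face_ids = _face_ids_for_tag(mesh, "interface")
    for e, ids in face_ids:
        nodes.update(mesh.elements[e][ids])
    nodes = np.array(sorted(nodes))
    X = mesh.nodes[nodes]
    r = np.linalg.norm(X, axis=1)
    return float(np.mean(np.einsum("ni,ni->n", U[nodes], X / r[:, None])))


def external_radial_displacement(mesh: MacroMesh, U: np.ndarray) -> float:
    face_ids = _face_ids_for_tag(mesh, "external")
    nodes = set()
    for e, ids in face_ids:
        nodes.update(mesh.elements[e][ids])
    nodes = np.array(sorted(nodes))
    X = mesh.nodes[nodes]
    r = np.linalg.norm(X, axis=1)
    return float(np.mean(np.einsum("ni,ni->n", U[nodes], X / r[:, None])))


def _face_ids_for_tag(mesh: MacroMesh, tag):
    from .mesh import FACES
    from .shapes import HEX27_CORNERS  # noqa: F401

    axmap = {"x": 0, "y": 1, "z": 2}
    out = []
    for e, f in mesh.facet_tags[tag]:
        axis, side = FACES[f]
        ia = axmap[axis]
        ids = []
        for k in range(3):
            for j in range(3):
                for i in range(3):
                    idx = [i, j, k]
                    if idx[ia] == (0 if side == 0 else 2):
                        ids.append(i + 3 * j + 9 * k)
        out.append((e, ids))
    return out


def generate_networks(cfg: dict, mesh: MacroMesh) -> dict:
    """One seeded network per (stromal element, sampling point)."""
    fib = cfg["fibres"]
    stretch = fib.get("align_stretch")
    networks = {}
    stromal = np.flatnonzero(mesh.region == REGION_STROMA)
    for e in stromal:
        for k in range(8):
            seed = int(np.random.SeedSequence(
                [cfg["seed"], int(e), k]).generate_state(1)[0] % (2**31 - 1))
            kwargs = dict(
                count_bounds=tuple(fib["count_bounds"]),
                theta_s=fib["theta_s"], side_length=fib["side_length"],
                a_f=fib["a_f"], e_f=fib["e_f"], c0=fib["c0"],
                weld_tol=fib["weld_tol"],
            )
            if stretch is None:
                net = nw.generate_random_network(seed, **kwargs)
            else:
                net = nw.generate_aligned_network(seed, stretch, **kwargs)
            _impose_gel_density(net, fib)
            networks[(int(e), k)] = net
    return networks


def _impose_gel_density(net: nw.FibreNetwork, fib_cfg: dict) -> None:
    """Rescale the fibre cross-section so every RVE realises the configured
    gel volume fraction with the common dimensionalisation factor
    eta_nominal: a_f L is then identical across RVEs, and the sampling
    spread of total fibre length does not masquerade as a permeability
    spread across the stroma."""
    eta_nom = fib_cfg.get("eta_nominal")
    if eta_nom:
        net.a_f = net.theta_s * net.volume / (eta_nom * net.total_length)


class CoupledRun:
    """Driver object; see run_coupled for the functional entry point."""

    def __init__(self, cfg: dict | None = None):
        self.cfg = cfg or default_config()
        g = self.cfg["geometry"]
        self.mesh = build_octant_mesh(g["r_tumour"], g["pts_thickness"],
                                      g["n_angular"], g["n_radial_tumour"],
                                      g["n_radial_pts"])
        tum_cfg = self.cfg["tumour"]
        growth = GrowthLaw.from_plateau(self.cfg["growth"]["plateau"],
                                        self.cfg["growth"]["gamma"])
        self.tumour = TumourMaterial(mu=tum_cfg["mu"], kappa=tum_cfg["kappa"],
                                     k_o=tum_cfg["k_o"],
                                     theta_s=tum_cfg["theta_s"],
                                     growth=growth)
        self.networks = generate_networks(self.cfg, self.mesh)

        # stroma surrogate stiffness from a probe RVE
        probe_seed = int(np.random.SeedSequence(
            [self.cfg["seed"], 0xA11]).generate_state(1)[0] % (2**31 - 1))
        fib = self.cfg["fibres"]
        probe = nw.generate_random_network(
            probe_seed, count_bounds=tuple(fib["count_bounds"]),
            theta_s=fib["theta_s"], side_length=fib["side_length"],
            a_f=fib["a_f"], e_f=fib["e_f"], c0=fib["c0"],
            weld_tol=fib["weld_tol"])
        _impose_gel_density(probe, fib)
        side_mm = fib["side_length"] * 1e-3
        self.C_probe, self.mu_s, self.kappa_s = probe_stroma_stiffness(
            probe, self.cfg["fluid"]["viscosity_scale"], side_mm)
        n_stromal = int(np.sum(self.mesh.region == REGION_STROMA))

        self.solver = MacroSolver(
            self.mesh, self.tumour,
            SurrogateStroma(n_stromal, 27,
                            isotropic_stiffness(self.mu_s, self.kappa_s),
                            theta_s=fib["theta_s"]),
            biot_modulus=self.cfg["fluid"]["biot_modulus"],
            grad_tol=self.cfg["solver"]["grad_tol"],
        )
        self.coupling = build_coupling_map(self.mesh, self.networks,
                                           fib["side_length"],
                                           self.solver.rve_points)
        # initial stromal permeability from the undeformed networks
        self._init_fluid_sets()
        self.history: list[dict] = []
        self.initial_orientation = {
            key: nw.orientation_tensor(net)
            for key, net in self.networks.items()
        }

    # -- helpers ------------------------------------------------------------

    def _init_fluid_sets(self):
        visc = self.cfg["fluid"]["viscosity_scale"]
        by_elem = self.coupling.by_element()
        for e, slots in by_elem.items():
            Ks = []
            for slot in sorted(slots, key=lambda s: s.point):
                net = slot.network
                zero_b = np.zeros((len(net.boundary_nodes), 3))
                st = nw.solve_micro_equilibrium(
                    net, zero_b, tol=self.cfg["solver"]["micro_tol"])
                slot.state = st
                slot.prev_u = st.u.copy()
                Ks.append(hm.upscale_permeability(net, st)
                          * visc / hm.current_eta(net, st) ** 4)
            self.solver.K_elem[e] = np.mean(Ks, axis=0)

    def _micro_update(self, dt: float):
        """Stages 2-4: downscale, micro solves, upscale, refresh macro."""
        mesh, solver = self.mesh, self.solver
        visc = self.cfg["fluid"]["viscosity_scale"]
        side_mm = self.coupling.side_mm
        U, P = solver.U, solver.P
        U_prev = self._U_at_last_micro
        F27, _ = solver.qp_state()
        E27 = 0.5 * (np.einsum("...ki,...kj->...ij", F27, F27) - np.eye(3))
        stroma = solver.stroma
        by_elem = self.coupling.by_element()
        for e, slots in by_elem.items():
            sets = []
            # fixed reduction order: permuting the micro solves cannot
            # change any output bit
            for slot in sorted(slots, key=lambda s: s.point):
                net = slot.network
                bu, p_nodes = downscale(slot, mesh, U, P,
                                        mesh.pressure_index, side_mm)
                bu_prev, _ = downscale(slot, mesh, U_prev, P,
                                       mesh.pressure_index, side_mm)
                old_u = slot.state.u if slot.state is not None else None
                st = nw.solve_micro_equilibrium(
                    net, bu, nodal_p=p_nodes, u0=old_u,
                    tol=self.cfg["solver"]["micro_tol"])
                v_nodes = ((st.u - old_u) / dt if old_u is not None
                           else np.zeros_like(st.u))
                V_S_b = (bu - bu_prev) / dt
                xb = net.nodes[net.boundary_nodes]
                Ab = np.hstack([xb, np.ones((len(xb), 1))])
                # non-affine velocity fluctuation for the mixing vector
                coef, *_ = np.linalg.lstsq(Ab, V_S_b, rcond=None)
                v_affine = np.hstack([net.nodes,
                                      np.ones((net.n_nodes, 1))]) @ coef
                # current packing from the affine part of the deformation
                coef_u, *_ = np.linalg.lstsq(Ab, bu, rcond=None)
                J_rve = float(np.linalg.det(np.eye(3) + coef_u[:3].T))
                ups = hm.upscale_all(net, st, v_nodes, V_S_b, visc, side_mm,
                                     v_fluct=v_nodes - v_affine,
                                     J_rve=J_rve)
                slot.state = st
                slot.upscaled = ups
                sets.append(ups)
            # refresh the macro constitutive state of this element; the
            # explicit one-step lag is under-relaxed against the surrogate's
            # own prediction, which damps the staggered oscillation without
            # moving the converged fixed point (at equilibrium the increment
            # vanishes and S0 -> S_rve exactly)
            omega = self.cfg["solver"].get("relax", 0.5)
            sidx = solver._stroma_index[e]
            cluster = solver.qp_cluster
            S_rve = np.array([s.S for s in sets])          # (8, 3, 3)
            dE = E27[e] - stroma.E0[sidx]
            S_pred = stroma.S0[sidx] + np.einsum("ijkl,qkl->qij",
                                                 stroma.C, dE)
            stroma.S0[sidx] = (omega * S_rve[cluster]
                               + (1.0 - omega) * S_pred)
            stroma.E0[sidx] = E27[e]
            K_new = np.mean([s.K for s in sets], axis=0)
            d_new = np.mean([s.d for s in sets], axis=0)
            QF_new = np.mean([s.QF for s in sets])
            solver.K_elem[e] = (omega * K_new
                                + (1.0 - omega) * solver.K_elem[e])
            solver.d_elem[e] = (omega * d_new
                                + (1.0 - omega) * solver.d_elem[e])
            solver.QF_elem[e] = (omega * QF_new
                                 + (1.0 - omega) * solver.QF_elem[e])

    # -- main loop ----------------------------------------------------------

    def run(self, progress=None) -> RunResult:
        cfg = self.cfg
        dt = cfg["solver"]["dt"]
        t_end = cfg["solver"]["t_end"]
        every = max(int(cfg["solver"].get("coupling_every", 1)), 1)
        out_dir = cfg["output"]["dir"]
        if out_dir:
            os.makedirs(out_dir, exist_ok=True)
        self._U_at_last_micro = self.solver.U.copy()
        step = 0
        while self.solver.t < t_end - 1e-9:
            try:
                info = self.solver.step(dt)
                step += 1
                if step % every == 0:
                    self._micro_update(dt * every)
                    self._U_at_last_micro = self.solver.U.copy()
            except Exception as exc:
                if out_dir:  # checkpoint the last consistent state
                    self._write_snapshot(out_dir, step)
                    self._write_log(out_dir)
                raise CouplingError(
                    f"coupled run aborted at step {step + 1} "
                    f"(t={self.solver.t:g} h, seed={cfg['seed']}): {exc}"
                ) from exc
            rec = dict(info)
            rec["growth"] = self.tumour.growth.stretch(self.solver.t)
            rec["radius_increase"] = interface_radial_displacement(
                self.mesh, self.solver.U) / cfg["geometry"]["r_tumour"]
            self.history.append(rec)
            if progress:
                progress(rec)
            if out_dir and (step % cfg["output"]["every"] == 0
                            or self.solver.t >= t_end - 1e-9):
                self._write_snapshot(out_dir, step)
        result = RunResult(config=cfg, mesh=self.mesh, solver=self.solver,
                           coupling=self.coupling, history=self.history,
                           initial_orientation=self.initial_orientation,
                           output_dir=out_dir)
        if out_dir:
            self._write_log(out_dir)
        return result

    def _write_snapshot(self, out_dir, step):
        import h5py

        P_full = np.zeros(len(self.mesh.nodes))
        P_full[self.mesh.pressure_nodes] = self.solver.P
        _, S27 = self.solver.qp_state()
        # per-sampling-point homogenised tensors keyed by (element, point)
        with h5py.File(os.path.join(out_dir, f"state_{step:04d}.h5"),
                       "w") as fh:
            fh.attrs["t"] = self.solver.t
            fh.create_dataset("U", data=self.solver.U)
            fh.create_dataset("P", data=self.solver.P)
            fh.create_dataset("V_F", data=self.solver.V_F)
            ups = [s for s in self.coupling.slots if s.upscaled is not None]
            if ups:
                fh.create_dataset(
                    "upscaled/element",
                    data=np.array([s.element for s in ups]))
                fh.create_dataset(
                    "upscaled/point", data=np.array([s.point for s in ups]))
                for name in ("S", "Q", "K", "d"):
                    fh.create_dataset(
                        f"upscaled/{name}",
                        data=np.array([getattr(s.upscaled, name)
                                       for s in ups]))
                fh.create_dataset(
                    "upscaled/QF",
                    data=np.array([s.upscaled.QF for s in ups]))
                fh.create_dataset(
                    "upscaled/eta",
                    data=np.array([s.upscaled.eta for s in ups]))
        write_vtu(
            self.mesh, os.path.join(out_dir, f"step_{step:04d}.vtu"),
            point_data={"U": self.solver.U, "P": P_full},
            cell_data={
                "region": self.mesh.region.astype(float),
                "V_F": self.solver.V_F,
                "S_mag": np.linalg.norm(S27.mean(axis=1), axis=(1, 2)),
                "K_trace": np.trace(self.solver.K_elem, axis1=1, axis2=2) / 3,
            },
        )

    def _write_log(self, out_dir):
        if not self.history:
            return
        keys = sorted({k for rec in self.history for k in rec})
        with open(os.path.join(out_dir, "log.csv"), "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=keys)
            writer.writeheader()
            for rec in self.history:
                writer.writerow(rec)


def run_coupled(cfg: dict | None = None, progress=None) -> RunResult:
    """Run the full coupled simulation described by ``cfg`` (defaults if
    None) and return the in-memory result."""
    return CoupledRun(cfg).run(progress=progress)
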