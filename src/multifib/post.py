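"""Derived quantities: spherical components, radial/temporal profiles,
alignment statistics and stress-flow correlations.

These reproduce the standard read-outs of spheroid-in-gel simulations:
solid stress, interstitial fluid pressure, permeability and fluid velocity
resolved into spherical components against radius and time; histograms of
network alignment relative to the tumour boundary; and rank correlations
between solid stress and the fluid-phase quantities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from . import network as nw
from .mesh import REGION_STROMA


class PostprocessError(ValueError):
    pass


# ---------------------------------------------------------------------------
# spherical frames
# ---------------------------------------------------------------------------

def spherical_frame(X) -> np.ndarray:
    """Orthonormal triad (e_r, e_theta, e_phi) at position X (rows).

    e_r is radial; e_theta the polar tangent (from the +z axis); e_phi the
    azimuthal tangent.  Raises at the origin.
    """
    X = np.asarray(X, dtype=float)
    r = np.linalg.norm(X)
    if r == 0:
        raise PostprocessError("spherical frame undefined at the origin")
    e_r = X / r
    rho = np.hypot(X[0], X[1])
    if rho < 1e-12 * r:
        # on the polar axis the azimuth is arbitrary
        e_phi = np.array([0.0, 1.0, 0.0])
    else:
        e_phi = np.array([-X[1], X[0], 0.0]) / rho
    e_theta = np.cross(e_phi, e_r)
    return np.vstack([e_r, e_theta, e_phi])


def spherical_components(field, X):
    """Components of a vector (3,) or tensor (3,3) in the spherical triad
    at X: (radial, circumferential_1, circumferential_2).

    Vectors are projected; tensors return the diagonal of the rotated
    tensor.
    """
    frame = spherical_frame(X)
    field = np.asarray(field, dtype=float)
    if field.shape == (3,):
        return frame @ field
    if field.shape == (3, 3):
        return np.diag(frame @ field @ frame.T)
    raise PostprocessError("field must be a 3-vector or 3x3 tensor")


# ---------------------------------------------------------------------------
# alignment statistics
# ---------------------------------------------------------------------------

@dataclass
class AlignmentScalars:
    orientation_normal: float    # |Omega_pvec . n|, 1 = perpendicular wall
    permeability_orientation: float   # |K_pvec . Omega_pvec|
    permeability_velocity: float      # |K_pvec . V_pvec|
    ambiguous: bool


def _principal(matrix, rel_tol=1e-6):
    w, v = np.linalg.eigh(matrix)
    spread = max(abs(w[-1]), 1e-300)
    ambiguous = abs(w[-1] - w[-2]) < rel_tol * spread
    return v[:, -1], ambiguous


def alignment_scalars(omega, n_hat, K, V_F, rel_tol=1e-6) -> AlignmentScalars:
    """Absolute scalar products between the principal network orientation,
    principal permeability, the boundary normal and the fluid velocity.

    Repeated top eigenvalues (within rel_tol) are flagged ambiguous and
    should be excluded from histograms.
    """
    omega_p, amb_o = _principal(omega, rel_tol)
    k_p, amb_k = _principal(K, rel_tol)
    n_hat = np.asarray(n_hat, dtype=float)
    n_hat = n_hat / np.linalg.norm(n_hat)
    v = np.asarray(V_F, dtype=float)
    vn = np.linalg.norm(v)
    v_p = v / vn if vn > 0 else np.zeros(3)
    return AlignmentScalars(
        orientation_normal=float(abs(omega_p @ n_hat)),
        permeability_orientation=float(abs(k_p @ omega_p)),
        permeability_velocity=float(abs(k_p @ v_p)) if vn > 0 else 0.0,
        ambiguous=bool(amb_o or amb_k),
    )


def alignment_histogram(values, bins=10):
    """Histogram of alignment scalars on [0, 1]; total mass equals the
    number of included samples."""
    counts, edges = np.histogram(np.asarray(values, float),
                                 bins=bins, range=(0.0, 1.0))
    return counts, edges


# ---------------------------------------------------------------------------
# profiles and integrals
# ---------------------------------------------------------------------------

def radial_profile(radii, values, bins=12):
    """Bin per-sample values by radius; returns (bin centres, bin means)."""
    radii = np.asarray(radii, float)
    values = np.asarray(values, float)
    edges = np.linspace(radii.min(), radii.max() * (1 + 1e-12), bins + 1)
    idx = np.digitize(radii, edges) - 1
    centres = 0.5 * (edges[:-1] + edges[1:])
    means = np.full((bins,) + values.shape[1:], np.nan)
    for b in range(bins):
        sel = idx == b
        if np.any(sel):
            means[b] = values[sel].mean(axis=0)
    return centres, means


def pts_time_integral(field_series, qp_weights, pts_volume=None):
    """Integrate a stromal quadrature-point field over the PTS per time and
    normalise with the initial PTS volume.

    field_series: (T, ...) with trailing shape matching qp_weights;
    qp_weights: reference quadrature weights over the stromal points.
    """
    w = np.asarray(qp_weights, float)
    if w.size == 0:
        raise PostprocessError("empty PTS region")
    V0 = float(w.sum()) if pts_volume is None else float(pts_volume)
    series = []
    for f in field_series:
        series.append(float(np.sum(np.asarray(f, float) * w)) / V0)
    return np.asarray(series)


def correlation_heatmap(x, y, bins=30):
    """Spearman rank correlation (average-rank ties, two-sided p) plus a 2D
    histogram of the two series."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 10:
        raise PostprocessError("series must have equal length >= 10")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise PostprocessError("correlation undefined for a constant series")
    rho, p = spearmanr(x, y)
    hist, xe, ye = np.histogram2d(x, y, bins=bins)
    return float(rho), float(p), hist, (xe, ye)


# ---------------------------------------------------------------------------
# run-level analysis
# ---------------------------------------------------------------------------

def stromal_samples(result, level: str = "nodal"):
    """(stress magnitude, permeability magnitude, fluid speed) samples over
    the stroma at the current state of a coupled run.

    ``level``: "nodal" extrapolates the element fields to the stromal corner
    nodes (averaging the elements sharing each node, the form used for the
    correlation maps); "element" returns the per-element fields; "rve"
    returns one sample per fibre network.
    """
    mesh, sol = result.mesh, result.solver
    stromal = np.flatnonzero(mesh.region == REGION_STROMA)
    if level == "rve":
        smag, kmag, vmag = [], [], []
        for slot in result.coupling.slots:
            if slot.upscaled is None:
                continue
            smag.append(np.linalg.norm(slot.upscaled.S))
            kmag.append(np.trace(slot.upscaled.K) / 3.0)
            vmag.append(np.linalg.norm(sol.V_F[slot.element]))
        return np.asarray(smag), np.asarray(kmag), np.asarray(vmag)
    _, S27 = sol.qp_state()
    s_el = np.linalg.norm(S27.mean(axis=1), axis=(1, 2))
    k_el = np.trace(sol.K_elem, axis1=1, axis2=2) / 3.0
    v_el = np.linalg.norm(sol.V_F, axis=1)
    if level == "element":
        return s_el[stromal], k_el[stromal], v_el[stromal]
    if level != "nodal":
        raise PostprocessError(f"unknown sampling level {level!r}")
    sums = {}
    for e in stromal:
        for nd in mesh.corner_elements[e]:
            acc = sums.setdefault(int(nd), [0.0, 0.0, 0.0, 0])
            acc[0] += s_el[e]
            acc[1] += k_el[e]
            acc[2] += v_el[e]
            acc[3] += 1
    out = np.array([[a[0] / a[3], a[1] / a[3], a[2] / a[3]]
                    for a in sums.values()])
    return out[:, 0], out[:, 1], out[:, 2]


def stress_flow_correlations(result):
    """(rho_stress_permeability, rho_stress_velocity) over the stroma."""
    smag, kmag, vmag = stromal_samples(result)
    r_sk, _ = spearmanr(smag, kmag)
    r_sv, _ = spearmanr(smag, vmag)
    return float(r_sk), float(r_sv)


def interface_speed_ratios(result):
    """Fluid-speed ratios: peak near the interface over (mid-tumour mean,
    outer-third-of-stroma mean), and the radial flow direction there."""
    mesh, sol = result.mesh, result.solver
    nrt = result.config["geometry"]["n_radial_tumour"]
    shell = mesh.shell
    vf = np.linalg.norm(sol.V_F, axis=1)
    near = (shell == nrt - 1) | (shell == nrt)
    peak = float(vf[near].max())
    interior = shell < nrt - 1
    if not interior.any():  # single-shell tumour: no interior distinct
        interior = shell == 0
    mid_tumour = float(vf[interior].mean())
    outer = float(vf[shell == shell.max()].mean())
    cent = mesh.element_centroids()
    first = np.flatnonzero(shell == nrt)
    rhat = cent[first] / np.linalg.norm(cent[first], axis=1, keepdims=True)
    radial_flow = float(np.mean(np.einsum("ei,ei->e", sol.V_F[first], rhat)))
    return {"peak": peak, "ratio_mid_tumour": peak / mid_tumour,
            "ratio_outer": peak / outer,
            "radial_flow_first_layer": radial_flow}


def first_layer_alignment(result, initial=False):
    """Mean |orientation . outward normal| over first-layer RVEs (0 =
    circumferential, 1 = perpendicular to the boundary)."""
    mesh = result.mesh
    nrt = result.config["geometry"]["n_radial_tumour"]
    first = set(np.flatnonzero(mesh.shell == nrt).tolist())
    cent = mesh.element_centroids()
    vals = []
    for slot in result.coupling.slots:
        if slot.element not in first:
            continue
        n_hat = cent[slot.element] / np.linalg.norm(cent[slot.element])
        if initial:
            omega = result.initial_orientation[(slot.element, slot.point)]
        else:
            omega = nw.orientation_tensor(slot.state.dirs,
                                          slot.state.lengths)
        pvec, amb = _principal(omega)
        if not amb:
            vals.append(abs(pvec @ n_hat))
    return float(np.mean(vals))


def write_report(result, out_dir) -> None:
    """CSV tables and summary plots for a finished run: radial profiles of
    stress/pressure/permeability/velocity, the alignment histogram of the
    first stromal layer, and the stress-flow correlation heatmaps."""
    import csv
    import os

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mesh, sol = result.mesh, result.solver
    cent = mesh.element_centroids()
    radii = np.linalg.norm(cent, axis=1)
    _, S27 = sol.qp_state()
    S_el = S27.mean(axis=1)
    P_full = np.zeros(len(mesh.nodes))
    P_full[mesh.pressure_nodes] = sol.P
    p_el = P_full[mesh.corner_elements].mean(axis=1)

    rows = []
    for e in range(mesh.n_elements):
        s_sph = spherical_components(S_el[e], cent[e])
        k_sph = spherical_components(sol.K_elem[e], cent[e])
        v_sph = spherical_components(sol.V_F[e], cent[e])
        rows.append([radii[e], mesh.region[e], *s_sph, p_el[e], *k_sph,
                     *v_sph])
    with open(os.path.join(out_dir, "radial_profile.csv"), "w",
              newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["r_mm", "region", "S_rr", "S_tt", "S_pp", "P",
                         "K_rr", "K_tt", "K_pp", "VF_r", "VF_t", "VF_p"])
        writer.writerows(rows)

    # first-layer alignment histogram
    nrt = result.config["geometry"]["n_radial_tumour"]
    first = set(np.flatnonzero(mesh.shell == nrt).tolist())
    vals = []
    for slot in result.coupling.slots:
        if slot.element not in first or slot.state is None:
            continue
        n_hat = cent[slot.element] / np.linalg.norm(cent[slot.element])
        omega = nw.orientation_tensor(slot.state.dirs, slot.state.lengths)
        sc = alignment_scalars(omega, n_hat, sol.K_elem[slot.element],
                               sol.V_F[slot.element])
        if not sc.ambiguous:
            vals.append([sc.orientation_normal, sc.permeability_orientation,
                         sc.permeability_velocity])
    vals = np.array(vals) if vals else np.zeros((0, 3))
    with open(os.path.join(out_dir, "alignment.csv"), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["orientation_normal", "permeability_orientation",
                         "permeability_velocity"])
        writer.writerows(vals.tolist())

    smag, kmag, vmag = stromal_samples(result)
    r_sk, p_sk, *_ = correlation_heatmap(smag, kmag)
    r_sv, p_sv, *_ = correlation_heatmap(smag, vmag)
    with open(os.path.join(out_dir, "correlations.csv"), "w",
              newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["pair", "spearman_t", "p_value"])
        writer.writerow(["stress_permeability", r_sk, p_sk])
        writer.writerow(["stress_velocity", r_sv, p_sv])

    fig, axes = plt.subplots(2, 2, figsize=(10, 8))
    order = np.argsort(radii)
    axes[0, 0].plot(radii[order], [spherical_components(S_el[e], cent[e])[0]
                                   for e in order], ".-", label="radial")
    axes[0, 0].set(xlabel="r (mm)", ylabel="S_rr (Pa)",
                   title="radial solid stress")
    axes[0, 1].semilogy(radii[order],
                        [max(np.trace(sol.K_elem[e]) / 3, 1e-30)
                         for e in order], ".-")
    axes[0, 1].set(xlabel="r (mm)", ylabel="K (mm^2/Pa/h)",
                   title="permeability")
    axes[1, 0].semilogy(radii[order],
                        [max(np.linalg.norm(sol.V_F[e]), 1e-30)
                         for e in order], ".-")
    axes[1, 0].set(xlabel="r (mm)", ylabel="|V_F| (mm/h)",
                   title="interstitial fluid speed")
    if len(vals):
        axes[1, 1].hist(vals[:, 0], bins=10, range=(0, 1), alpha=0.7)
    axes[1, 1].set(xlabel="|orientation . normal|", ylabel="RVEs",
                   title="first-layer alignment")
    fig.tight_layout()
    fig.savefig(os.path.join(out_dir, "summary.png"), dpi=110)
    plt.close(fig)

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, (x, y, lab) in zip(axes, [(smag, kmag, "permeability"),
                                      (smag, vmag, "|V_F|")]):
        ax.hist2d(x, y, bins=20)
        ax.set(xlabel="|S| (Pa)", ylabel=lab)
    fig.tight_layout()
    fig.savefig(os.path.join(out_dir, "correlations.png"), dpi=110)
    plt.close(fig)


def analyse_run(result) -> dict:
    """The headline quantities of a coupled run, as plain floats."""
    r_sk, r_sv = stress_flow_correlations(result)
    speeds = interface_speed_ratios(result)
    return {
        "radius_increase_pct": 100.0 * result.radius_increase,
        "pts_strain_pct": 100.0 * result.pts_strain,
        "spearman_stress_permeability": r_sk,
        "spearman_stress_velocity": r_sv,
        "speed_ratio_mid_tumour": speeds["ratio_mid_tumour"],
        "speed_ratio_outer": speeds["ratio_outer"],
        "radial_flow_first_layer": speeds["radial_flow_first_layer"],
        "alignment_initial": first_layer_alignment(result, initial=True),
        "alignment_final": first_layer_alignment(result, initial=False),
    }
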