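"""Cross-linked collagen fibre networks (RVEs) and their truss equilibrium.

Each representative volume element is a unit parametric cube containing a
random network of one-dimensional fibres joined at pin joints.  Fibres carry
axial force only, with an exponential force-strain law (Green strain) whose
negative phase describes compression softening; joints transmit no moments.
Networks are generated by sampling straight segments, welding near
intersections into pin joints, clipping at the cube faces (creating boundary
nodes) and keeping the largest connected component.

The microscale boundary value problem is a total-Lagrangian truss
equilibrium: boundary-node displacements are prescribed (downscaled from the
macroscale), interior nodes equilibrate axial fibre forces plus the axial
push of the interpolated interstitial pressure.  A damped Newton iteration
with load substepping solves the free-node force balance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import erfi


class NetworkError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class FibreNetwork:
    """A fibre-network RVE in the unit parametric cube.

    nodes: (M, 3) reference positions; fibres: (F, 2) node pairs; l0: (F,)
    reference lengths.  boundary_nodes lists the node ids lying exactly on
    cube faces, with outward face normals in boundary_normals.  Material
    constants (cross-section a_f, stiffness e_f in Pa, exponential constant
    c0) and the solid volume fraction theta_s are uniform over the network.
    """

    nodes: np.ndarray
    fibres: np.ndarray
    l0: np.ndarray
    boundary_nodes: np.ndarray
    boundary_normals: np.ndarray
    theta_s: float
    a_f: float
    e_f: float
    c0: float
    side_length: float
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.is_boundary = np.zeros(len(self.nodes), dtype=bool)
        self.is_boundary[self.boundary_nodes] = True

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_fibres(self) -> int:
        return len(self.fibres)

    @property
    def volume(self) -> float:
        return 1.0

    @property
    def total_length(self) -> float:
        return float(self.l0.sum())

    @property
    def eta(self) -> float:
        """Dimensionalisation factor theta_s * V / (a_f * L) in the reference
        configuration."""
        return dimensionalisation_factor(self.theta_s, self.volume, self.a_f,
                                         self.total_length)

    def directions(self, u: np.ndarray | None = None):
        """(F, 3) unit vectors and (F,) lengths, optionally displaced by u."""
        x = self.nodes if u is None else self.nodes + u
        d = x[self.fibres[:, 1]] - x[self.fibres[:, 0]]
        ln = np.linalg.norm(d, axis=1)
        return d / ln[:, None], ln


@dataclass
class MicroState:
    """Equilibrium state of one RVE under prescribed boundary displacements."""

    u: np.ndarray            # (M, 3) nodal displacements, parametric
    p: np.ndarray            # (M,) nodal pressures, Pa
    eps: np.ndarray          # (F,) Green strains
    force: np.ndarray        # (F,) axial force magnitudes (solid part)
    dirs: np.ndarray         # (F, 3) current unit fibre vectors
    lengths: np.ndarray      # (F,) current lengths
    residual_norm: float
    iterations: int


def dimensionalisation_factor(theta_s: float, V: float, a_f: float,
                              L: float) -> float:
    """eta = theta_s V / (a_f L), mapping parametric lengths to physical ones."""
    if min(theta_s, V, a_f) <= 0:
        raise ValueError("theta_s, V and a_f must be positive")
    if L <= 0:
        raise ValueError("total fibre length L must be positive")
    return theta_s * V / (a_f * L)


# ---------------------------------------------------------------------------
# constitutive law
# ---------------------------------------------------------------------------

def fibre_force(eps, a_f: float, e_f: float, c0: float):
    """Axial fibre force magnitude (a_f e_f / c0) (exp(c0 eps) - 1).

    Positive in tension, negative in compression; reduces to the linear law
    a_f e_f eps as c0 -> 0.
    """
    eps = np.asarray(eps, dtype=float)
    if abs(c0) < 1e-10:
        out = a_f * e_f * eps
    else:
        # clip the exponent: keeps trial states finite during line searches
        out = (a_f * e_f / c0) * np.expm1(np.clip(c0 * eps, -60.0, 60.0))
    return out if out.ndim else float(out)


def _fibre_energy(lengths, l0, a_f, e_f, c0):
    """Exact integral of the axial force from l0 to the current length."""
    lengths = np.asarray(lengths, dtype=float)
    l0 = np.asarray(l0, dtype=float)
    if abs(c0) < 1e-10:
        return a_f * e_f * ((lengths**3 - l0**3) / (6 * l0**2)
                            - 0.5 * (lengths - l0))
    k = c0 / (2.0 * l0**2)
    if c0 > 0:
        sk = np.sqrt(k)
        # clip the erfi argument: trial states in line searches can reach
        # absurd stretches; the clipped energy stays monotone and finite
        arg = np.minimum(sk * lengths, 25.0)
        integral = (np.exp(-c0 / 2.0) * np.sqrt(np.pi) / (2.0 * sk)
                    * (erfi(arg) - erfi(np.minimum(sk * l0, 25.0))))
    else:
        from scipy.special import erf

        sk = np.sqrt(-k)
        integral = (np.exp(-c0 / 2.0) * np.sqrt(np.pi) / (2.0 * sk)
                    * (erf(sk * lengths) - erf(sk * l0)))
    return (a_f * e_f / c0) * (integral - (lengths - l0))


def strain_energy(net: FibreNetwork, u: np.ndarray) -> float:
    """Total elastic strain energy of the network at displacement u."""
    _, ln = net.directions(u)
    return float(_fibre_energy(ln, net.l0, net.a_f, net.e_f, net.c0).sum())


# ---------------------------------------------------------------------------
# orientation tensor
# ---------------------------------------------------------------------------

def orientation_tensor(net_or_dirs, lengths: np.ndarray | None = None) -> np.ndarray:
    """Length-weighted second-moment orientation tensor.

    Omega_ij = sum_f (l_i l_j / l) / sum_f l, where l_i is the projection of a
    fibre of length l on axis i.  Symmetric, positive semi-definite, unit
    trace.  Accepts a FibreNetwork or explicit (dirs, lengths) arrays.
    """
    if isinstance(net_or_dirs, FibreNetwork):
        dirs, ln = net_or_dirs.directions()
    else:
        dirs = np.asarray(net_or_dirs, dtype=float)
        ln = np.asarray(lengths, dtype=float)
    if len(ln) == 0:
        raise NetworkError("orientation tensor of an empty network")
    # l_i l_j / l = l * d_i d_j for a straight fibre with direction d
    return np.einsum("f,fi,fj->ij", ln, dirs, dirs) / ln.sum()


# ---------------------------------------------------------------------------
# network generation
# ---------------------------------------------------------------------------

def _clip_segment(p0, p1, lo=0.0, hi=1.0):
    """Clip segment p0->p1 to the axis-aligned cube [lo, hi]^3."""
    d = p1 - p0
    t0, t1 = 0.0, 1.0
    for ax in range(3):
        if abs(d[ax]) < 1e-14:
            if p0[ax] < lo or p0[ax] > hi:
                return None
            continue
        ta = (lo - p0[ax]) / d[ax]
        tb = (hi - p0[ax]) / d[ax]
        if ta > tb:
            ta, tb = tb, ta
        t0, t1 = max(t0, ta), min(t1, tb)
        if t0 >= t1:
            return None
    return p0 + t0 * d, p0 + t1 * d, t0, t1


def _segment_pair_closest(P0, D0, P1, D1):
    """Approximate closest-approach parameters for segment pairs (vectorised).

    Segments are P + s*D with s in [0, 1].  Uses the clamped quadratic
    solution with one refinement pass; adequate for welding with a finite
    tolerance.
    """
    r = P0 - P1
    a = np.einsum("ij,ij->i", D0, D0)
    b = np.einsum("ij,ij->i", D0, D1)
    c = np.einsum("ij,ij->i", D1, D1)
    d = np.einsum("ij,ij->i", D0, r)
    e = np.einsum("ij,ij->i", D1, r)
    den = a * c - b * b
    s = np.where(den > 1e-14, (b * e - c * d) / np.where(den > 1e-14, den, 1.0), 0.0)
    s = np.clip(s, 0.0, 1.0)
    t = np.clip((b * s + e) / c, 0.0, 1.0)
    s = np.clip((b * t - d) / a, 0.0, 1.0)
    diff = (P0 + s[:, None] * D0) - (P1 + t[:, None] * D1)
    return s, t, np.linalg.norm(diff, axis=1)


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        self.parent[self.find(i)] = self.find(j)


def _face_normal_of(point, tol=1e-9):
    for ax in range(3):
        if abs(point[ax]) < tol:
            n = np.zeros(3)
            n[ax] = -1.0
            return n
        if abs(point[ax] - 1.0) < tol:
            n = np.zeros(3)
            n[ax] = 1.0
            return n
    return None


def _build_network_attempt(rng, n_segments, seg_length, weld_tol, stretch):
    """One generation attempt; returns (nodes, fibres, boundary info) or None."""
    mid = rng.uniform(-0.3, 1.3, size=(n_segments, 3))
    z = rng.normal(size=(n_segments, 3))
    dirs = z / np.linalg.norm(z, axis=1, keepdims=True)
    half = 0.5 * seg_length * rng.uniform(0.8, 1.2, size=n_segments)
    if stretch is not None:
        # squared map: near-perfect alignment is reached for large stretch
        # ratios while mild ratios reproduce weak hydrogel prealignment
        dirs = dirs * np.asarray(stretch)[None, :] ** 2
        scale = np.linalg.norm(dirs, axis=1)
        half = half * np.sqrt(scale)
        dirs = dirs / scale[:, None]

    segs = []  # (start, end) clipped to the cube
    for i in range(n_segments):
        res = _clip_segment(mid[i] - half[i] * dirs[i], mid[i] + half[i] * dirs[i])
        if res is None:
            continue
        q0, q1, _, _ = res
        if np.linalg.norm(q1 - q0) > 4 * weld_tol:
            segs.append((q0, q1))
    if len(segs) < 4:
        return None
    P0 = np.array([s[0] for s in segs])
    P1 = np.array([s[1] for s in segs])
    D = P1 - P0
    n = len(segs)
    ii, jj = np.triu_indices(n, k=1)
    s, t, dist = _segment_pair_closest(P0[ii], D[ii], P0[jj], D[jj])
    hit = dist < weld_tol
    ii, jj, s, t = ii[hit], jj[hit], s[hit], t[hit]
    if len(ii) == 0:
        return None
    xpts = 0.5 * ((P0[ii] + s[:, None] * D[ii]) + (P0[jj] + t[:, None] * D[jj]))

    # weld nearby crossings into single joints
    uf = _UnionFind(len(xpts))
    if len(xpts) > 1:
        tree = cKDTree(xpts)
        for a, b in tree.query_pairs(weld_tol):
            uf.union(a, b)
    roots = {}
    joint_of = np.empty(len(xpts), dtype=int)
    joint_pts = []
    for idx in range(len(xpts)):
        r = uf.find(idx)
        if r not in roots:
            roots[r] = len(joint_pts)
            joint_pts.append([])
        joint_of[idx] = roots[r]
        joint_pts[roots[r]].append(xpts[idx])
    joint_pos = np.array([np.mean(p, axis=0) for p in joint_pts])

    # assemble nodes: joints first, then segment endpoints
    nodes = list(joint_pos)
    fibres = []
    seg_events: list[list[tuple[float, int]]] = [[] for _ in range(n)]
    for k in range(len(ii)):
        seg_events[ii[k]].append((s[k], joint_of[k]))
        seg_events[jj[k]].append((t[k], joint_of[k]))
    for si in range(n):
        ends = []
        for tpar, pt in ((0.0, P0[si]), (1.0, P1[si])):
            idx = len(nodes)
            nodes.append(pt)
            ends.append((tpar, idx))
        events = sorted(set(seg_events[si]))
        chain = [ends[0]] + [ev for ev in events] + [ends[1]]
        for (ta, na), (tb, nb) in zip(chain[:-1], chain[1:]):
            if na == nb:
                continue
            if np.linalg.norm(np.array(nodes[nb]) - np.array(nodes[na])) < 1e-6:
                continue
            fibres.append((na, nb))
    return np.array(nodes), fibres


def _trim_and_extract(nodes, fibres, min_face_nodes, min_len=0.08):
    """Contract fibres below the minimum pin-joint spacing, trim dangling
    ends, merge collinear pass-through joints, and keep the largest
    connected component.  Returns arrays or None if unusable."""
    nodes = np.asarray(nodes, dtype=float).copy()
    # snap boundary coordinates exactly onto the faces
    for v in (0.0, 1.0):
        close = np.abs(nodes - v) < 1e-9
        nodes[close] = v
    is_bnd = np.array([_face_normal_of(x) is not None for x in nodes])

    fib = {tuple(sorted(f)) for f in fibres if f[0] != f[1]}

    # contract sub-fibres shorter than the minimum spacing: the drag model
    # scales as 1/length, so stray slivers would dominate the permeability
    changed = True
    while changed:
        changed = False
        for f in sorted(fib):
            a, b = f
            if np.linalg.norm(nodes[a] - nodes[b]) >= min_len:
                continue
            if is_bnd[a] and is_bnd[b]:
                # merge only if the pair shares a face (midpoint stays on it)
                shared = [(ax, v) for ax in range(3) for v in (0.0, 1.0)
                          if nodes[a][ax] == v and nodes[b][ax] == v]
                if not shared:
                    continue
                keep, drop = a, b
                mid = 0.5 * (nodes[a] + nodes[b])
                for ax, v in shared:
                    mid[ax] = v
                nodes[keep] = mid
            else:
                keep, drop = (a, b) if is_bnd[a] else (b, a)
                if not is_bnd[keep]:
                    nodes[keep] = 0.5 * (nodes[a] + nodes[b])
            fib.discard(f)
            for g in [g for g in fib if drop in g]:
                fib.discard(g)
                other = g[0] if g[1] == drop else g[1]
                if other != keep:
                    fib.add(tuple(sorted((keep, other))))
            changed = True
            break
    changed = True
    while changed:
        changed = False
        deg: dict[int, list] = {}
        for f in fib:
            for a in f:
                deg.setdefault(a, []).append(f)
        for a, incident in list(deg.items()):
            if is_bnd[a]:
                continue
            if len(incident) == 1:
                fib.discard(incident[0])
                changed = True
            elif len(incident) == 2:
                f1, f2 = incident
                o1 = f1[0] if f1[1] == a else f1[1]
                o2 = f2[0] if f2[1] == a else f2[1]
                if o1 == o2:
                    fib.discard(f1)
                    fib.discard(f2)
                    changed = True
                    continue
                d1 = nodes[a] - nodes[o1]
                d2 = nodes[o2] - nodes[a]
                cosang = d1 @ d2 / (np.linalg.norm(d1) * np.linalg.norm(d2))
                if cosang > 0.9999:
                    fib.discard(f1)
                    fib.discard(f2)
                    fib.add(tuple(sorted((o1, o2))))
                    changed = True
    if not fib:
        return None

    # largest connected component
    uf = _UnionFind(len(nodes))
    for a, b in fib:
        uf.union(a, b)
    comps: dict[int, list] = {}
    for f in fib:
        comps.setdefault(uf.find(f[0]), []).append(f)
    best = max(comps.values(), key=lambda fl: len(fl))

    used = sorted({a for f in best for a in f})
    remap = {old: new for new, old in enumerate(used)}
    new_nodes = nodes[used]
    new_fibres = np.array([[remap[a], remap[b]] for a, b in best], dtype=int)
    bnd, normals = [], []
    for new, old in enumerate(used):
        nrm = _face_normal_of(nodes[old])
        if nrm is not None:
            bnd.append(new)
            normals.append(nrm)
    if not bnd:
        return None
    # require a minimum spread of boundary nodes per face
    normals = np.array(normals)
    for ax in range(3):
        for sgn in (-1.0, 1.0):
            if np.sum(normals @ np.eye(3)[ax] * sgn > 0.5) < min_face_nodes:
                return None
    l0 = np.linalg.norm(new_nodes[new_fibres[:, 1]] - new_nodes[new_fibres[:, 0]],
                        axis=1)
    return new_nodes, new_fibres, l0, np.array(bnd, dtype=int), normals


def _prune_to_bounds(nodes, fibres, lo, hi, min_face_nodes, rng):
    """Remove seeded-random fibres (with cascade trimming) until the element
    count falls inside [lo, hi]; returns extracted arrays or None."""
    current_nodes = np.asarray(nodes)
    current_fibres = np.asarray(fibres)
    count = len(current_fibres)
    batch = max(1, (count - hi) // 3)
    guard = 0
    while count > hi and guard < 4000:
        guard += 1
        removed = False
        for _ in range(30):
            drop = rng.choice(count, size=min(batch, count - lo),
                              replace=False)
            trial = np.delete(current_fibres, drop, axis=0)
            res = _trim_and_extract(current_nodes, [tuple(f) for f in trial],
                                    min_face_nodes)
            if res is not None and len(res[1]) >= lo:
                current_nodes, current_fibres = res[0], res[1]
                count = len(current_fibres)
                removed = True
                batch = max(1, min(batch, (count - hi) // 3 + 1))
                break
            batch = max(1, batch // 2)
        if not removed:
            return None
    if lo <= count <= hi:
        return _trim_and_extract(current_nodes,
                                 [tuple(f) for f in current_fibres],
                                 min_face_nodes)
    return None


def generate_random_network(
    seed: int,
    count_bounds=(200, 300),
    theta_s: float = 0.003,
    side_length: float = 20.0,
    a_f: float = 2.5e-5,
    e_f: float = 5.0e5,
    c0: float = 2.0,
    weld_tol: float = 0.03,
    seg_length: float = 1.6,
    stretch=None,
    min_face_nodes: int = 3,
    max_attempts: int = 150,
) -> FibreNetwork:
    """Generate a seeded random fibre network with a fibre count inside
    ``count_bounds``.

    Straight segments with uniform random orientations and midpoints are
    welded at near-intersections (tolerance in cube side lengths), clipped at
    the cube faces, and trimmed; the number of seed segments is adapted until
    the truss-element count lands in the configured bounds.  An optional
    ``stretch`` biases the direction distribution by the affine map
    d -> diag(stretch)^2 d / |.| (monotone in each component).
    """
    lo, hi = count_bounds
    if not (50 <= lo < hi <= 2000):
        raise ValueError("count bounds must satisfy 50 <= lo < hi <= 2000")
    if not 0.0 < theta_s < 0.2:
        raise ValueError("theta_s must lie in (0, 0.2)")
    rng = np.random.default_rng([int(seed), 0x5EED])
    n_seg = max(6, int(0.11 * (lo + hi)))
    n_lo = n_hi = None   # bracket of segment counts around the target band
    for _ in range(max_attempts):
        built = _build_network_attempt(rng, n_seg, seg_length, weld_tol, stretch)
        result = _trim_and_extract(built[0], built[1], min_face_nodes) \
            if built is not None else None
        if result is not None:
            count = len(result[1])
            if lo <= count <= hi:
                nodes, fibres, l0, bnd, normals = result
                return FibreNetwork(
                    nodes=nodes, fibres=fibres, l0=l0,
                    boundary_nodes=bnd, boundary_normals=normals,
                    theta_s=theta_s, a_f=a_f, e_f=e_f, c0=c0,
                    side_length=side_length, seed=int(seed),
                    meta={"n_segments": n_seg,
                          "stretch": None if stretch is None else tuple(stretch)},
                )
            if count > hi:
                # percolation can jump straight past the band (dominant for
                # aligned networks): prune the giant component down into it
                pruned = _prune_to_bounds(result[0], result[1], lo, hi,
                                          min_face_nodes, rng)
                if pruned is not None:
                    nodes, fibres, l0, bnd, normals = pruned
                    return FibreNetwork(
                        nodes=nodes, fibres=fibres, l0=l0,
                        boundary_nodes=bnd, boundary_normals=normals,
                        theta_s=theta_s, a_f=a_f, e_f=e_f, c0=c0,
                        side_length=side_length, seed=int(seed),
                        meta={"n_segments": n_seg, "pruned": True,
                              "stretch": None if stretch is None
                              else tuple(stretch)},
                    )
            # noisy bisection on the segment count
            if count < lo:
                n_lo = n_seg
                if n_hi is not None and n_hi > n_seg + 1:
                    n_seg = (n_seg + n_hi) // 2
                else:
                    n_seg = int(n_seg * min(1.25,
                                            (lo / max(count, 1)) ** 0.35)) + 1
            else:
                n_hi = n_seg
                if n_lo is not None and n_lo < n_seg - 1:
                    n_seg = (n_seg + n_lo) // 2
                else:
                    n_seg = max(6, int(n_seg * max(0.8,
                                                   (hi / count) ** 0.35)) - 1)
            if n_lo is not None and n_hi is not None and n_lo >= n_hi:
                n_lo = n_hi = None  # stochastic overlap: reset the bracket
        else:
            n_seg = int(n_seg * 1.15) + 1
    raise NetworkError(
        f"failed to generate a connected network within bounds {count_bounds} "
        f"after {max_attempts} attempts (seed={seed})"
    )


def generate_aligned_network(seed: int, alignment_stretch, **kwargs) -> FibreNetwork:
    """Generate a network whose fibre directions are biased by an affine
    stretch diag(alignment_stretch) applied before clipping to the cube.

    A larger stretch component increases the corresponding orientation-tensor
    diagonal; (1, 1, 1) reproduces the random generator.
    """
    stretch = np.asarray(alignment_stretch, dtype=float)
    if stretch.shape != (3,) or np.any(stretch <= 0):
        raise ValueError("alignment_stretch must be three positive components")
    if np.all(stretch == 1.0):
        stretch = None  # identity stretch: bit-identical to the random path
    else:
        # strongly aligned networks rarely anchor on the faces parallel to
        # the dominant direction; one node per face still covers the surface
        kwargs.setdefault("min_face_nodes", 1)
    return generate_random_network(seed, stretch=stretch, **kwargs)


# ---------------------------------------------------------------------------
# microscale equilibrium
# ---------------------------------------------------------------------------

def _assemble(net: FibreNetwork, u: np.ndarray, p: np.ndarray | None):
    """Residual (internal force) and per-fibre state at displacement u."""
    d, ln = net.directions(u)
    eps = (ln**2 - net.l0**2) / (2.0 * net.l0**2)
    g = fibre_force(eps, net.a_f, net.e_f, net.c0)
    h = g.copy()
    if p is not None:
        pbar = 0.5 * (p[net.fibres[:, 0]] + p[net.fibres[:, 1]])
        h = h - net.a_f * pbar
    fvec = h[:, None] * d
    r = np.zeros((net.n_nodes, 3))
    np.add.at(r, net.fibres[:, 1], fvec)
    np.add.at(r, net.fibres[:, 0], -fvec)
    return r, eps, g, h, d, ln


def _tangent(net: FibreNetwork, d, ln, eps, h):
    """Dense free-free tangent blocks: returns (M, M, 3, 3) assembled array."""
    M = net.n_nodes
    gp = net.a_f * net.e_f * np.exp(np.clip(net.c0 * eps, -50, 50)) * ln / net.l0**2
    if abs(net.c0) < 1e-10:
        gp = net.a_f * net.e_f * ln / net.l0**2
    k_ax = (gp - h / ln)[:, None, None] * np.einsum("fi,fj->fij", d, d)
    k_tr = (h / ln)[:, None, None] * np.eye(3)[None, :, :]
    kf = k_ax + k_tr
    K = np.zeros((M, M, 3, 3))
    i, j = net.fibres[:, 0], net.fibres[:, 1]
    np.add.at(K, (i, i), kf)
    np.add.at(K, (j, j), kf)
    np.add.at(K, (i, j), -kf)
    np.add.at(K, (j, i), -kf)
    return K


def _affine_guess(net: FibreNetwork, boundary_u: np.ndarray) -> np.ndarray:
    """Least-squares affine field fitted to the boundary displacements."""
    xb = net.nodes[net.boundary_nodes]
    A = np.hstack([xb, np.ones((len(xb), 1))])
    coef, *_ = np.linalg.lstsq(A, boundary_u, rcond=None)
    u = np.hstack([net.nodes, np.ones((net.n_nodes, 1))]) @ coef
    u[net.boundary_nodes] = boundary_u
    return u


def solve_micro_equilibrium(
    net: FibreNetwork,
    boundary_u: np.ndarray,
    nodal_p: np.ndarray | None = None,
    u0: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 60,
    max_substeps: int = 16,
) -> MicroState:
    """Solve the free-node force balance under prescribed boundary motion.

    boundary_u: (n_boundary, 3) displacements for net.boundary_nodes (exact
    Dirichlet data).  nodal_p: optional (M,) interstitial pressures, which
    enter only through their interpolated nodal values.  Newton iteration
    with adaptive Tikhonov damping and load substepping; the residual
    tolerance is relative to the fibre force scale a_f * e_f.
    """
    boundary_u = np.asarray(boundary_u, dtype=float)
    if boundary_u.shape != (len(net.boundary_nodes), 3):
        raise ValueError("boundary_u must cover every boundary node")
    free = ~net.is_boundary
    tol_abs = tol * net.a_f * net.e_f

    u_start = np.zeros((net.n_nodes, 3)) if u0 is None else u0.copy()
    ub_start = u_start[net.boundary_nodes]

    xb = net.nodes[net.boundary_nodes]
    Ab = np.hstack([xb, np.ones((len(xb), 1))])
    Aall = np.hstack([net.nodes, np.ones((net.n_nodes, 1))])

    n_sub = 1
    while n_sub <= max_substeps:
        u = u_start.copy()
        ok = True
        for step in range(1, n_sub + 1):
            frac = step / n_sub
            ub = ub_start + frac * (boundary_u - ub_start)
            # extend the boundary increment into the interior by its
            # best-fit affine field (exact for translations and uniform
            # strain increments), then equilibrate
            delta_b = ub - u[net.boundary_nodes]
            coef, *_ = np.linalg.lstsq(Ab, delta_b, rcond=None)
            target = u + Aall @ coef
            target[net.boundary_nodes] = ub
            u, ok, res, its = _newton(net, target, nodal_p, free, tol_abs,
                                      max_iter)
            if not ok:
                break
        if ok:
            r, eps, g, h, d, ln = _assemble(net, u, nodal_p)
            return MicroState(
                u=u,
                p=np.zeros(net.n_nodes) if nodal_p is None else np.asarray(nodal_p, float),
                eps=eps, force=g, dirs=d, lengths=ln,
                residual_norm=res, iterations=its,
            )
        n_sub *= 2
    raise NetworkError(
        f"micro Newton failed to converge (last residual {res:.3e}, "
        f"tolerance {tol_abs:.3e}, seed={net.seed})"
    )


def _total_energy(net, u, nodal_p):
    """Elastic energy plus the axial work of the interpolated pressure;
    its gradient with respect to free nodes is the equilibrium residual."""
    _, ln = net.directions(u)
    with np.errstate(over="ignore", invalid="ignore"):
        E = float(_fibre_energy(ln, net.l0, net.a_f, net.e_f, net.c0).sum())
        if nodal_p is not None:
            pbar = 0.5 * (nodal_p[net.fibres[:, 0]]
                          + nodal_p[net.fibres[:, 1]])
            E -= float(np.sum(net.a_f * pbar * (ln - net.l0)))
    return E if np.isfinite(E) else 1e30


def _newton(net, u, nodal_p, free, tol_abs, max_iter):
    """Levenberg-style Newton descent on the total energy.

    The tangent can be indefinite in buckled regions, so a diagonal shift
    lambda*diag(K) is adapted until the step is an energy-descent direction;
    all retries reuse the assembled tangent.
    """
    nfree = int(free.sum())
    if nfree == 0:
        r, *_ = _assemble(net, u, nodal_p)
        return u, True, 0.0, 0
    lam = 0.0
    r, eps, g, h, d, ln = _assemble(net, u, nodal_p)
    res = np.abs(r[free]).max()
    E = _total_energy(net, u, nodal_p)
    polished = False
    for it in range(1, max_iter + 1):
        if res < tol_abs:
            return u, True, res, it - 1
        K = _tangent(net, d, ln, eps, h)
        Kff = K[np.ix_(free, free)].transpose(0, 2, 1, 3).reshape(
            3 * nfree, 3 * nfree)
        diag = np.abs(np.diag(Kff))
        diag = np.maximum(diag, 1e-9 * max(diag.max(), 1e-30))
        rf = r[free].reshape(-1)
        progressed = False
        for attempt in range(30):
            A = Kff + lam * np.diag(diag) if lam > 0 else Kff
            try:
                du = np.linalg.solve(A, -rf)
            except np.linalg.LinAlgError:
                lam = max(lam * 5.0, 1e-6)
                continue
            slope = float(rf @ du)
            if not np.all(np.isfinite(du)) or slope >= 0:
                lam = max(lam * 5.0, 1e-6)
                continue
            alpha = 1.0
            for _ in range(6):
                u_try = u.copy()
                u_try[free] += alpha * du.reshape(nfree, 3)
                E_try = _total_energy(net, u_try, nodal_p)
                armijo = (np.isfinite(E_try)
                          and E_try <= E + 1e-4 * alpha * slope)
                res_try = None
                if not armijo and np.isfinite(E_try):
                    # near flat minima the energy decrement is below double
                    # precision; fall back to residual decrease
                    r_t, eps_t, g_t, h_t, d_t, ln_t = _assemble(
                        net, u_try, nodal_p)
                    res_try = np.abs(r_t[free]).max()
                if armijo or (res_try is not None
                              and (res_try < 0.99 * res
                                   or res_try < tol_abs)):
                    if res_try is None:
                        r_t, eps_t, g_t, h_t, d_t, ln_t = _assemble(
                            net, u_try, nodal_p)
                        res_try = np.abs(r_t[free]).max()
                    u, r, eps, g, h, d, ln = (u_try, r_t, eps_t, g_t, h_t,
                                              d_t, ln_t)
                    res = res_try
                    E = E_try
                    progressed = True
                    break
                alpha *= 0.25
            if progressed:
                lam = lam / 3.0 if lam > 1e-12 else 0.0
                break
            lam = max(lam * 5.0, 1e-6)
        if not progressed or it == max_iter:
            if polished or res < tol_abs:
                return u, res < tol_abs, res, it
            # rare: flat buckled regions defeat the shifted Newton; a
            # trust-region Newton descent on the energy handles them
            u, r, eps, g, h, d, ln, res, E = _trust_region_polish(
                net, u, nodal_p, free, nfree, tol_abs)
            lam = 1e-6
            polished = True
    return u, res < tol_abs, res, max_iter


def _trust_region_polish(net, u, nodal_p, free, nfree, tol_abs):
    from scipy.optimize import minimize as _min

    def fun(x):
        uu = u.copy()
        uu[free] = x.reshape(nfree, 3)
        rr, *_ = _assemble(net, uu, nodal_p)
        return _total_energy(net, uu, nodal_p), rr[free].reshape(-1)

    def hess(x):
        uu = u.copy()
        uu[free] = x.reshape(nfree, 3)
        _, eps_h, _, h_h, d_h, ln_h = _assemble(net, uu, nodal_p)
        Kh = _tangent(net, d_h, ln_h, eps_h, h_h)
        return Kh[np.ix_(free, free)].transpose(0, 2, 1, 3).reshape(
            3 * nfree, 3 * nfree)

    sol = _min(fun, u[free].reshape(-1), jac=True, hess=hess,
               method="trust-ncg",
               options=dict(maxiter=3000, gtol=0.05 * tol_abs))
    u = u.copy()
    u[free] = sol.x.reshape(nfree, 3)
    r, eps, g, h, d, ln = _assemble(net, u, nodal_p)
    return (u, r, eps, g, h, d, ln, np.abs(r[free]).max(),
            _total_energy(net, u, nodal_p))


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_network(net: FibreNetwork, group) -> None:
    """Write a network into an open h5py group."""
    group.create_dataset("nodes", data=net.nodes)
    group.create_dataset("fibres", data=net.fibres)
    group.create_dataset("l0", data=net.l0)
    group.create_dataset("boundary_nodes", data=net.boundary_nodes)
    group.create_dataset("boundary_normals", data=net.boundary_normals)
    for key in ("theta_s", "a_f", "e_f", "c0", "side_length"):
        group.attrs[key] = getattr(net, key)
    group.attrs["seed"] = -1 if net.seed is None else net.seed


def export_fibre_csv(net: FibreNetwork, path) -> None:
    """Write a per-fibre table (end nodes, reference length, direction) for
    inspection."""
    dirs, _ = net.directions()
    with open(path, "w") as fh:
        fh.write("fibre,node_a,node_b,l0,nx,ny,nz\n")
        for f, (a, b) in enumerate(net.fibres):
            fh.write(f"{f},{a},{b},{net.l0[f]:.9g},"
                     f"{dirs[f, 0]:.9g},{dirs[f, 1]:.9g},{dirs[f, 2]:.9g}\n")


def load_network(group) -> FibreNetwork:
    seed = int(group.attrs["seed"])
    return FibreNetwork(
        nodes=group["nodes"][()],
        fibres=group["fibres"][()],
        l0=group["l0"][()],
        boundary_nodes=group["boundary_nodes"][()],
        boundary_normals=group["boundary_normals"][()],
        theta_s=float(group.attrs["theta_s"]),
        a_f=float(group.attrs["a_f"]),
        e_f=float(group.attrs["e_f"]),
        c0=float(group.attrs["c0"]),
        side_length=float(group.attrs["side_length"]),
        seed=None if seed < 0 else seed,
    )
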