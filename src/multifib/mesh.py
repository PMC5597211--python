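"""Macroscale hexahedral meshes of the tumour + peritumoural-stroma octant.

The domain is one octant of a sphere: a tumour spheroid of radius ``r_tumour``
surrounded by a shell of peritumoural stroma (PTS).  Spherical symmetry is
exploited, so the three coordinate planes are symmetry surfaces.  The octant is
meshed with all-hexahedral elements by a cubed-sphere decomposition: each
radial shell is split into three angular blocks, one per spherical patch
obtained by centrally projecting a quarter of each cube face bordering the
octant.  The innermost shell collapses onto the origin (a standard collapsed
hexahedron construction); its Jacobian remains positive at all interior
quadrature points.

Displacements are interpolated with 27-node triquadratic hexahedra, pressure
with the 8 corner nodes of the same elements.  Lengths are in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .shapes import HEX8_FACES, HEX27_CORNERS, gauss_points, hex27_shape

REGION_TUMOUR = 0
REGION_STROMA = 1

TAG_INTERFACE = "interface"
TAG_EXTERNAL = "external"
TAG_SYMMETRY = "symmetry"

#: face id -> (axis index, side) in parent coordinates
FACES = [("x", 0), ("x", 1), ("y", 0), ("y", 1), ("z", 0), ("z", 1)]
_AXIS = {"x": 0, "y": 1, "z": 2}

# Gmsh 27-node hexahedron ordering -> lexicographic (i + 3j + 9k) ordering
GMSH27_TO_LEX = np.array(
    [0, 2, 8, 6, 18, 20, 26, 24,
     1, 3, 9, 5, 11, 7, 17, 15, 19, 21, 23, 25,
     4, 10, 12, 14, 16, 22,
     13]
)
LEX_TO_GMSH27 = np.argsort(GMSH27_TO_LEX)

# lexicographic corner numbering (i + 2j + 4k) -> VTK hexahedron ordering
_LEX8_TO_VTK = np.array([0, 1, 3, 2, 4, 5, 7, 6])


class MeshError(ValueError):
    pass


@dataclass
class MacroMesh:
    """An all-hex macroscale mesh with quadratic/linear node sets.

    nodes
        (n_nodes, 3) reference coordinates in mm.
    elements
        (n_elem, 27) connectivity, lexicographic parent ordering.
    region
        (n_elem,) int, REGION_TUMOUR or REGION_STROMA.
    shell
        (n_elem,) int radial shell index (0 innermost); -1 for non-spherical
        meshes.
    facet_tags
        tag name -> (n_facets, 2) int array of (element, face id).
    """

    nodes: np.ndarray
    elements: np.ndarray
    region: np.ndarray
    shell: np.ndarray
    facet_tags: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        corners = np.unique(self.elements[:, HEX27_CORNERS])
        self.pressure_index = np.full(len(self.nodes), -1, dtype=int)
        self.pressure_index[corners] = np.arange(len(corners))
        self.pressure_nodes = corners

    # -- derived quantities -------------------------------------------------

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def corner_elements(self) -> np.ndarray:
        """(n_elem, 8) corner connectivity in lexicographic corner order."""
        return self.elements[:, HEX27_CORNERS]

    def element_centroids(self) -> np.ndarray:
        N, _ = hex27_shape(np.zeros((1, 3)))
        return np.einsum("a,eai->ei", N[0], self.nodes[self.elements])

    def jacobians(self, points: np.ndarray) -> np.ndarray:
        """(n_elem, n_pts, 3, 3) Jacobians dX/dxi at the parent points."""
        _, dN = hex27_shape(points)
        X = self.nodes[self.elements]
        return np.einsum("pad,eai->epid", dN, X)

    def element_volumes(self, order: int = 3) -> np.ndarray:
        pts, wts = gauss_points(order)
        J = self.jacobians(pts)
        return np.einsum("p,ep->e", wts, np.linalg.det(J))

    def check_jacobians(self, order: int = 2) -> None:
        pts, _ = gauss_points(order)
        det = np.linalg.det(self.jacobians(pts))
        if not np.all(det > 0.0):
            bad = np.argwhere(det <= 0.0)
            raise MeshError(
                f"degenerate (inverted) element: det J <= 0 at element "
                f"{bad[0][0]}, quadrature point {bad[0][1]}"
            )

    def boundary_facets(self) -> np.ndarray:
        return np.vstack([v for v in self.facet_tags.values() if len(v)])

    def facet_corner_nodes(self, elem: int, face: int) -> np.ndarray:
        axis, side = FACES[face]
        return self.corner_elements[elem][list(HEX8_FACES[(axis, side)])]

    def facet_normal(self, elem: int, face: int) -> np.ndarray:
        """Outward unit normal at the facet centre."""
        axis, side = FACES[face]
        ia = _AXIS[axis]
        centre = np.zeros(3)
        centre[ia] = -1.0 if side == 0 else 1.0
        _, dN = hex27_shape(centre[None, :])
        J = np.einsum("ad,ai->id", dN[0], self.nodes[self.elements[elem]])
        t1, t2 = (ia + 1) % 3, (ia + 2) % 3
        n = np.cross(J[:, t1], J[:, t2])
        if side == 0:
            n = -n
        return n / np.linalg.norm(n)

    def facet_area_normals(self, facets: np.ndarray, order: int = 3):
        """Per-facet quadrature (points in parent coords, weights x |da|, unit
        normals); used for surface integrals.  Returns (pts, w_area, normals)
        with shapes (n_f, q, 3), (n_f, q), (n_f, q, 3)."""
        x1, w1 = np.polynomial.legendre.leggauss(order)
        out_pts, out_w, out_n = [], [], []
        for elem, face in facets:
            axis, side = FACES[face]
            ia = _AXIS[axis]
            t1, t2 = (ia + 1) % 3, (ia + 2) % 3
            pts = np.zeros((order * order, 3))
            pts[:, ia] = -1.0 if side == 0 else 1.0
            grid = np.array([[a, b] for b in x1 for a in x1])
            pts[:, t1] = grid[:, 0]
            pts[:, t2] = grid[:, 1]
            wts = np.array([wa * wb for wb in w1 for wa in w1])
            _, dN = hex27_shape(pts)
            J = np.einsum("pad,ai->pid", dN, self.nodes[self.elements[elem]])
            n = np.cross(J[:, :, t1], J[:, :, t2], axis=-1)
            if side == 0:
                n = -n
            da = np.linalg.norm(n, axis=-1)
            out_pts.append(pts)
            out_w.append(wts * da)
            out_n.append(n / da[:, None])
        return np.array(out_pts), np.array(out_w), np.array(out_n)


# ---------------------------------------------------------------------------
# octant construction
# ---------------------------------------------------------------------------

def _patch(block: int, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Unit-sphere point of cubed-sphere patch `block` at parameters (a, b)."""
    one = np.ones_like(a)
    if block == 0:      # caps +z
        v = np.stack([a, b, one], axis=-1)
    elif block == 1:    # caps +x
        v = np.stack([one, a, b], axis=-1)
    else:               # caps +y
        v = np.stack([b, one, a], axis=-1)
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


class _NodePool:
    def __init__(self):
        self.coords: list[np.ndarray] = []
        self.lookup: dict[tuple, int] = {}

    def add(self, x: np.ndarray) -> int:
        key = tuple(np.round(x, 12))
        idx = self.lookup.get(key)
        if idx is None:
            idx = len(self.coords)
            self.lookup[key] = idx
            self.coords.append(np.asarray(x, dtype=float))
        return idx


def build_octant_mesh(
    r_tumour: float,
    pts_thickness: float,
    n_angular: int,
    n_radial_tumour: int,
    n_radial_pts: int,
) -> MacroMesh:
    """Build the spherical octant mesh of tumour plus stromal shell.

    Element count is ``3 * n_angular**2 * (n_radial_tumour + n_radial_pts)``;
    the first ``n_radial_tumour`` shells are tumour, the rest stroma.
    """
    if r_tumour <= 0 or pts_thickness <= 0:
        raise MeshError("radii must be positive")
    if min(n_angular, n_radial_tumour, n_radial_pts) < 1:
        raise MeshError("element counts must be >= 1")

    r_outer = r_tumour + pts_thickness
    shells = np.concatenate([
        np.linspace(0.0, r_tumour, n_radial_tumour + 1),
        r_tumour + pts_thickness * np.arange(1, n_radial_pts + 1) / n_radial_pts,
    ])
    # quadratic radial grid: shell boundaries plus mid-shell values
    n_shell = len(shells) - 1
    rgrid = np.empty(2 * n_shell + 1)
    rgrid[0::2] = shells
    rgrid[1::2] = 0.5 * (shells[:-1] + shells[1:])

    na = 2 * n_angular + 1
    agrid = np.linspace(0.0, 1.0, na)

    pool = _NodePool()
    elements, region, shell_idx = [], [], []
    for block in range(3):
        # node index grid (ia, ib, ir)
        gid = np.empty((na, na, len(rgrid)), dtype=int)
        for ir, r in enumerate(rgrid):
            if r == 0.0:
                pt = np.zeros(3)
                idx = pool.add(pt)
                gid[:, :, ir] = idx
                continue
            for ib, b in enumerate(agrid):
                sph = _patch(block, agrid, np.full(na, b))
                for ia in range(na):
                    gid[ia, ib, ir] = pool.add(r * sph[ia])
        for er in range(n_shell):
            for eb in range(n_angular):
                for ea in range(n_angular):
                    conn = [
                        gid[2 * ea + i, 2 * eb + j, 2 * er + k]
                        for k in range(3)
                        for j in range(3)
                        for i in range(3)
                    ]
                    elements.append(conn)
                    region.append(
                        REGION_TUMOUR if er < n_radial_tumour else REGION_STROMA
                    )
                    shell_idx.append(er)

    mesh = MacroMesh(
        nodes=np.array(pool.coords),
        elements=np.array(elements, dtype=int),
        region=np.array(region, dtype=int),
        shell=np.array(shell_idx, dtype=int),
        facet_tags={},
        meta={
            "kind": "octant",
            "r_tumour": r_tumour,
            "pts_thickness": pts_thickness,
            "n_angular": n_angular,
            "n_radial_tumour": n_radial_tumour,
            "n_radial_pts": n_radial_pts,
        },
    )
    _tag_octant_facets(mesh, r_outer)
    mesh.check_jacobians()
    return mesh


def _facet_table(mesh: MacroMesh):
    """sorted corner tuple -> list of (elem, face)."""
    table: dict[tuple, list[tuple[int, int]]] = {}
    corners = mesh.corner_elements
    for e in range(mesh.n_elements):
        for f, (axis, side) in enumerate(FACES):
            quad = corners[e][list(HEX8_FACES[(axis, side)])]
            if len(set(quad)) < 3:
                continue  # collapsed face at the origin: zero measure
            key = tuple(sorted(set(quad)))
            table.setdefault(key, []).append((e, f))
    return table


def _tag_octant_facets(mesh: MacroMesh, r_outer: float, tol: float = 1e-9) -> None:
    table = _facet_table(mesh)
    interface, external, symmetry = [], [], []
    for key, owners in table.items():
        if len(owners) == 1:
            e, f = owners[0]
            pts = mesh.nodes[list(key)]
            if np.all(np.abs(np.linalg.norm(pts, axis=1) - r_outer) < 1e-6 * r_outer):
                external.append((e, f))
            elif any(np.all(np.abs(pts[:, ax]) < tol) for ax in range(3)):
                symmetry.append((e, f))
            else:  # pragma: no cover - should not happen on a valid octant
                raise MeshError(f"untaggable boundary facet on element {e}")
        elif len(owners) == 2:
            (e1, f1), (e2, f2) = owners
            if mesh.region[e1] != mesh.region[e2]:
                # store the facet once, owned by the tumour-side element
                if mesh.region[e1] == REGION_TUMOUR:
                    interface.append((e1, f1))
                else:
                    interface.append((e2, f2))
    mesh.facet_tags = {
        TAG_INTERFACE: np.array(sorted(interface), dtype=int).reshape(-1, 2),
        TAG_EXTERNAL: np.array(sorted(external), dtype=int).reshape(-1, 2),
        TAG_SYMMETRY: np.array(sorted(symmetry), dtype=int).reshape(-1, 2),
    }


def build_box_mesh(
    lengths=(1.0, 1.0, 1.0),
    divisions=(1, 1, 4),
    region: int = REGION_STROMA,
) -> MacroMesh:
    """Structured quadratic box mesh, used for benchmark problems.

    Boundary facets are tagged ``x0``/``x1``/... by bounding plane.
    """
    L = np.asarray(lengths, dtype=float)
    nd = np.asarray(divisions, dtype=int)
    if np.any(L <= 0) or np.any(nd < 1):
        raise MeshError("box lengths and divisions must be positive")
    grids = [np.linspace(0.0, L[i], 2 * nd[i] + 1) for i in range(3)]
    nx, ny, nz = [len(g) for g in grids]
    gid = np.arange(nx * ny * nz).reshape(nx, ny, nz, order="F")  # i fastest
    nodes = np.array(
        [[grids[0][i], grids[1][j], grids[2][k]]
         for k in range(nz) for j in range(ny) for i in range(nx)]
    )
    gid = np.empty((nx, ny, nz), dtype=int)
    c = 0
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                gid[i, j, k] = c
                c += 1
    elements = []
    for ek in range(nd[2]):
        for ej in range(nd[1]):
            for ei in range(nd[0]):
                elements.append(
                    [gid[2 * ei + i, 2 * ej + j, 2 * ek + k]
                     for k in range(3) for j in range(3) for i in range(3)]
                )
    mesh = MacroMesh(
        nodes=nodes,
        elements=np.array(elements, dtype=int),
        region=np.full(len(elements), region, dtype=int),
        shell=np.full(len(elements), -1, dtype=int),
        facet_tags={},
        meta={"kind": "box", "lengths": tuple(L), "divisions": tuple(nd)},
    )
    table = _facet_table(mesh)
    tags: dict[str, list] = {f"{ax}{s}": [] for ax in "xyz" for s in (0, 1)}
    tol = 1e-9 * max(L)
    for key, owners in table.items():
        if len(owners) != 1:
            continue
        e, f = owners[0]
        pts = mesh.nodes[list(key)]
        for ax in range(3):
            if np.all(np.abs(pts[:, ax]) < tol):
                tags[f"{'xyz'[ax]}0"].append((e, f))
            elif np.all(np.abs(pts[:, ax] - L[ax]) < tol):
                tags[f"{'xyz'[ax]}1"].append((e, f))
    mesh.facet_tags = {
        k: np.array(sorted(v), dtype=int).reshape(-1, 2) for k, v in tags.items()
    }
    mesh.check_jacobians()
    return mesh


# ---------------------------------------------------------------------------
# Gmsh MSH v2.2 ASCII I/O
# ---------------------------------------------------------------------------

_REGION_NAMES = {REGION_TUMOUR: "tumour", REGION_STROMA: "stroma"}
_REGION_IDS = {REGION_TUMOUR: 1, REGION_STROMA: 2}
_FACET_BASE = 100


def write_msh(mesh: MacroMesh, path) -> None:
    """Write the mesh as Gmsh MSH v2.2 ASCII with 27-node hexahedra.

    Regions become 3D physical groups; facet tags become 2D physical groups of
    4-node quads.
    """
    tag_names = sorted(mesh.facet_tags)
    facet_ids = {name: _FACET_BASE + i + 1 for i, name in enumerate(tag_names)}
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat"]
    lines.append("$PhysicalNames")
    n_phys = len(set(mesh.region)) + len(tag_names)
    lines.append(str(n_phys))
    for r in sorted(set(mesh.region)):
        lines.append(f'3 {_REGION_IDS[r]} "{_REGION_NAMES[r]}"')
    for name in tag_names:
        lines.append(f'2 {facet_ids[name]} "{name}"')
    lines.append("$EndPhysicalNames")
    lines.append("$Nodes")
    lines.append(str(len(mesh.nodes)))
    for i, x in enumerate(mesh.nodes):
        lines.append(f"{i + 1} {x[0]:.17g} {x[1]:.17g} {x[2]:.17g}")
    lines.append("$EndNodes")
    lines.append("$Elements")
    quads = []
    for name in tag_names:
        for elem, face in mesh.facet_tags[name]:
            quads.append((facet_ids[name], mesh.facet_corner_nodes(elem, face)))
    lines.append(str(mesh.n_elements + len(quads)))
    eid = 1
    for phys, quad in quads:
        nn = " ".join(str(n + 1) for n in quad)
        lines.append(f"{eid} 3 2 {phys} {phys} {nn}")
        eid += 1
    for e in range(mesh.n_elements):
        phys = _REGION_IDS[mesh.region[e]]
        conn = mesh.elements[e][GMSH27_TO_LEX]
        nn = " ".join(str(n + 1) for n in conn)
        lines.append(f"{eid} 12 2 {phys} {phys} {nn}")
        eid += 1
    lines.append("$EndElements")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_msh(path) -> MacroMesh:
    """Read a Gmsh MSH v2.2/v4.1 ASCII mesh of 8- or 27-node hexahedra.

    8-node hexahedra are elevated to the internal 27-node representation by
    inserting edge/face/volume nodes at interpolated positions.  Physical
    groups of dimension 3 become regions, quad groups become facet tags.
    """
    with open(path) as fh:
        text = fh.read()
    sections = {}
    pos = 0
    while True:
        start = text.find("$", pos)
        if start < 0:
            break
        name = text[start + 1: text.find("\n", start)].strip()
        end = text.find(f"$End{name}")
        if end < 0:
            raise MeshError(f"unterminated MSH section {name}")
        sections[name] = text[text.find("\n", start) + 1: end].strip("\n")
        pos = end + len(name) + 4
    if "MeshFormat" not in sections:
        raise MeshError("not a Gmsh MSH file")
    version = sections["MeshFormat"].split()[0]
    phys_names = {}
    if "PhysicalNames" in sections:
        rows = sections["PhysicalNames"].splitlines()[1:]
        for row in rows:
            parts = row.split(None, 2)
            phys_names[int(parts[1])] = parts[2].strip().strip('"')
    if version.startswith("2"):
        nodes, raw_elems = _read_msh2(sections)
    elif version.startswith("4"):
        nodes, raw_elems = _read_msh4(sections)
    else:
        raise MeshError(f"unsupported MSH version {version}")
    return _assemble_from_raw(nodes, raw_elems, phys_names)


def _read_msh2(sections):
    node_rows = sections["Nodes"].splitlines()
    n_nodes = int(node_rows[0])
    ids = np.empty(n_nodes, dtype=int)
    coords = np.empty((n_nodes, 3))
    for i, row in enumerate(node_rows[1: n_nodes + 1]):
        parts = row.split()
        ids[i] = int(parts[0])
        coords[i] = [float(v) for v in parts[1:4]]
    remap = {nid: i for i, nid in enumerate(ids)}
    elem_rows = sections["Elements"].splitlines()
    n_elem = int(elem_rows[0])
    raw = []
    for row in elem_rows[1: n_elem + 1]:
        parts = [int(v) for v in row.split()]
        etype, ntags = parts[1], parts[2]
        phys = parts[3] if ntags >= 1 else 0
        conn = [remap[v] for v in parts[3 + ntags:]]
        raw.append((etype, phys, conn))
    return coords, raw


def _read_msh4(sections):
    node_lines = sections["Nodes"].splitlines()
    header = node_lines[0].split()
    n_blocks = int(header[0])
    idx = 1
    ids, coords = [], []
    for _ in range(n_blocks):
        _, _, _, n_in_block = (int(v) for v in node_lines[idx].split())
        idx += 1
        block_ids = [int(node_lines[idx + i]) for i in range(n_in_block)]
        idx += n_in_block
        for i in range(n_in_block):
            coords.append([float(v) for v in node_lines[idx + i].split()[:3]])
        idx += n_in_block
        ids.extend(block_ids)
    remap = {nid: i for i, nid in enumerate(ids)}
    elem_lines = sections["Elements"].splitlines()
    n_blocks = int(elem_lines[0].split()[0])
    idx = 1
    raw = []
    for _ in range(n_blocks):
        _, entity, etype, n_in_block = (int(v) for v in elem_lines[idx].split())
        idx += 1
        for i in range(n_in_block):
            parts = [int(v) for v in elem_lines[idx + i].split()]
            raw.append((etype, entity, [remap[v] for v in parts[1:]]))
        idx += n_in_block
    return np.array(coords), raw


def _assemble_from_raw(coords, raw, phys_names):
    hexes, quads = [], []
    for etype, phys, conn in raw:
        if etype == 5:      # 8-node hexahedron
            hexes.append((phys, conn, 8))
        elif etype == 12:   # 27-node hexahedron
            hexes.append((phys, conn, 27))
        elif etype == 3:    # 4-node quad (facet group)
            quads.append((phys, conn))
        elif etype in (1, 8, 15, 2, 9, 10, 16):  # points/lines/triangle-free?
            if etype in (2, 9):
                continue  # stray triangles in surface groups are ignored
            continue
        elif etype == 4:
            raise MeshError("unsupported element type: tetrahedra")
        else:
            raise MeshError(f"unsupported element type {etype}")
    if not hexes:
        raise MeshError("unsupported element type: no hexahedra found")

    coords = np.asarray(coords, dtype=float)
    nodes = list(coords)
    elements, regions = [], []
    edge_cache: dict[tuple, int] = {}

    def midnode(node_ids):
        key = tuple(sorted(node_ids))
        idx = edge_cache.get(key)
        if idx is None:
            idx = len(nodes)
            nodes.append(np.mean([nodes[n] for n in node_ids], axis=0))
            edge_cache[key] = idx
        return idx

    for phys, conn, order in hexes:
        if order == 27:
            lex = np.empty(27, dtype=int)
            lex[GMSH27_TO_LEX] = conn
            elements.append(lex.tolist())
        else:
            g = conn  # gmsh corner order
            lex = {}
            lex_ids = [0, 2, 8, 6, 18, 20, 26, 24]
            for li, gi in zip(lex_ids, range(8)):
                lex[li] = g[gi]
            edges = {
                1: (0, 1), 3: (0, 3), 9: (0, 4), 5: (1, 2), 11: (1, 5),
                7: (2, 3), 17: (2, 6), 15: (3, 7), 19: (4, 5), 21: (4, 7),
                23: (5, 6), 25: (6, 7),
            }
            for li, (a, b) in edges.items():
                lex[li] = midnode((g[a], g[b]))
            faces = {
                4: (0, 1, 2, 3), 10: (0, 1, 5, 4), 12: (0, 3, 7, 4),
                14: (1, 2, 6, 5), 16: (2, 3, 7, 6), 22: (4, 5, 6, 7),
            }
            for li, quad in faces.items():
                lex[li] = midnode(tuple(g[q] for q in quad))
            lex[13] = midnode(tuple(g[q] for q in range(8)))
            elements.append([lex[i] for i in range(27)])
        regions.append(phys)

    region_ids = sorted(set(regions))
    region_map = {}
    for rid in region_ids:
        name = phys_names.get(rid, "")
        if name == "tumour":
            region_map[rid] = REGION_TUMOUR
        elif name == "stroma":
            region_map[rid] = REGION_STROMA
        else:
            region_map[rid] = region_ids.index(rid)
    mesh = MacroMesh(
        nodes=np.array(nodes),
        elements=np.array(elements, dtype=int),
        region=np.array([region_map[r] for r in regions], dtype=int),
        shell=np.full(len(elements), -1, dtype=int),
        facet_tags={},
        meta={"kind": "msh"},
    )
    # rebuild facet tags from quads
    table = _facet_table(mesh)
    tags: dict[str, list] = {}
    for phys, conn in quads:
        key = tuple(sorted(set(conn)))
        owners = table.get(key, [])
        name = phys_names.get(phys, f"surface_{phys}")
        for e, f in owners[:1]:
            tags.setdefault(name, []).append((e, f))
    mesh.facet_tags = {
        k: np.array(sorted(v), dtype=int).reshape(-1, 2) for k, v in tags.items()
    }
    mesh.check_jacobians()
    return mesh


# ---------------------------------------------------------------------------
# VTU output
# ---------------------------------------------------------------------------

def write_vtu(mesh: MacroMesh, path, point_data=None, cell_data=None) -> None:
    """Write an XML VTU snapshot (linear hexahedra on the corner nodes).

    point_data maps name -> per-corner-node array (scalar or vector), indexed
    by the mesh's quadratic node numbering (the corner subset is extracted);
    cell_data maps name -> per-element array.
    """
    point_data = point_data or {}
    cell_data = cell_data or {}
    corners = mesh.pressure_nodes        # unique corner nodes
    remap = mesh.pressure_index
    cells = remap[mesh.corner_elements][:, _LEX8_TO_VTK]
    npts, ncell = len(corners), mesh.n_elements

    def fmt(arr):
        return " ".join(f"{v:.10g}" for v in np.asarray(arr, dtype=float).ravel())

    out = ['<?xml version="1.0"?>']
    out.append('<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">')
    out.append("<UnstructuredGrid>")
    out.append(f'<Piece NumberOfPoints="{npts}" NumberOfCells="{ncell}">')
    out.append("<Points>")
    out.append('<DataArray type="Float64" NumberOfComponents="3" format="ascii">')
    out.append(fmt(mesh.nodes[corners]))
    out.append("</DataArray></Points>")
    out.append("<Cells>")
    out.append('<DataArray type="Int64" Name="connectivity" format="ascii">')
    out.append(" ".join(str(v) for v in cells.ravel()))
    out.append("</DataArray>")
    out.append('<DataArray type="Int64" Name="offsets" format="ascii">')
    out.append(" ".join(str(8 * (i + 1)) for i in range(ncell)))
    out.append("</DataArray>")
    out.append('<DataArray type="UInt8" Name="types" format="ascii">')
    out.append(" ".join("12" for _ in range(ncell)))
    out.append("</DataArray></Cells>")
    out.append("<PointData>")
    for name, arr in point_data.items():
        arr = np.asarray(arr, dtype=float)
        sub = arr[corners] if arr.shape[0] == len(mesh.nodes) else arr
        ncomp = 1 if sub.ndim == 1 else sub.shape[1]
        out.append(
            f'<DataArray type="Float64" Name="{name}" '
            f'NumberOfComponents="{ncomp}" format="ascii">'
        )
        out.append(fmt(sub))
        out.append("</DataArray>")
    out.append("</PointData>")
    out.append("<CellData>")
    for name, arr in cell_data.items():
        arr = np.asarray(arr, dtype=float).reshape(ncell, -1)
        out.append(
            f'<DataArray type="Float64" Name="{name}" '
            f'NumberOfComponents="{arr.shape[1]}" format="ascii">'
        )
        out.append(fmt(arr))
        out.append("</DataArray>")
    out.append("</CellData>")
    out.append("</Piece></UnstructuredGrid></VTKFile>")
    with open(path, "w") as fh:
        fh.write("\n".join(out) + "\n")


def read_vtu_cell_count(path) -> int:
    """Cheap check used by tests and the CLI: number of cells in a VTU file."""
    import re

    with open(path) as fh:
        m = re.search(r'NumberOfCells="(\d+)"', fh.read())
    if not m:
        raise MeshError("not a VTU file")
    return int(m.group(1))
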