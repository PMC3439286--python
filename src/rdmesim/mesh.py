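"""Unstructured-mesh representation and built-in mesh generators.

The spatial discretization is *vertex centered*: every mesh vertex is a
voxel (subvolume) of the reaction-diffusion master equation, and the dual
cell volume of a vertex is the corresponding entry of the row-lumped finite
element mass matrix (see :mod:`rdmesim.assembly`).

Units are micrometres for length throughout the package; seconds for time.

Subdomain labels are small positive integers attached to elements
(tetrahedra, triangles, line segments).  Label ``0`` is reserved for
"excluded".  Vertex labels are *derived* from element labels: a vertex
takes the label of a volume element containing it, but a vertex incident
to any labelled surface triangle takes that surface label instead
(surface labels are the more specific ones — a membrane vertex hosts both
cytosolic and membrane-bound species, which is why the surface membership
is additionally recorded in a boolean mask).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cc
from scipy.spatial import Delaunay

__all__ = [
    "Mesh",
    "CapsuleSegment",
    "generate_interval_mesh",
    "generate_box_mesh",
    "generate_icosphere_surface",
    "generate_fibonacci_sphere_surface",
    "generate_capsule_mesh",
    "generate_capsule_union_mesh",
    "CYTOSOL",
    "MEMBRANE",
]

#: default volume subdomain label
CYTOSOL = 1
#: default boundary-surface subdomain label
MEMBRANE = 2

_DEGENERATE_TOL = 1e-12


class MeshGenerationError(RuntimeError):
    """Raised when a generator cannot produce a valid mesh."""


@dataclass
class Mesh:
    """Conforming simplicial mesh with per-element subdomain labels.

    Parameters
    ----------
    vertices
        ``(N, 3)`` float array of coordinates in micrometres.
    tetrahedra
        ``(T, 4)`` integer connectivity (may be empty for surface-only or
        1D meshes).
    triangles
        ``(S, 3)`` integer connectivity of boundary/surface elements.
    lines
        ``(L, 2)`` integer connectivity of 1D interval elements.  Interval
        meshes are a degenerate embedding used mostly as analytically
        tractable fixtures; assembly produces the classical 1D operators
        for them.
    """

    vertices: np.ndarray
    tetrahedra: np.ndarray = field(default_factory=lambda: np.zeros((0, 4), dtype=np.int64))
    triangles: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), dtype=np.int64))
    lines: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=np.int64))
    tet_subdomain: np.ndarray | None = None
    tri_subdomain: np.ndarray | None = None
    line_subdomain: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(np.atleast_2d(self.vertices), dtype=np.float64)
        if self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (N, 3) array")
        self.tetrahedra = np.ascontiguousarray(self.tetrahedra, dtype=np.int64).reshape(-1, 4)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        self.lines = np.ascontiguousarray(self.lines, dtype=np.int64).reshape(-1, 2)
        n = self.n_vertices
        for conn, what in ((self.tetrahedra, "tetrahedra"), (self.triangles, "triangles"), (self.lines, "lines")):
            if conn.size and (conn.min() < 0 or conn.max() >= n):
                raise ValueError(f"{what} reference vertices outside [0, {n})")
        if self.tet_subdomain is None:
            self.tet_subdomain = np.full(len(self.tetrahedra), CYTOSOL, dtype=np.int64)
        if self.tri_subdomain is None:
            self.tri_subdomain = np.full(len(self.triangles), MEMBRANE, dtype=np.int64)
        if self.line_subdomain is None:
            self.line_subdomain = np.full(len(self.lines), CYTOSOL, dtype=np.int64)
        self.tet_subdomain = np.asarray(self.tet_subdomain, dtype=np.int64)
        self.tri_subdomain = np.asarray(self.tri_subdomain, dtype=np.int64)
        self.line_subdomain = np.asarray(self.line_subdomain, dtype=np.int64)
        if len(self.tet_subdomain) != len(self.tetrahedra):
            raise ValueError("tet_subdomain length mismatch")
        if len(self.tri_subdomain) != len(self.triangles):
            raise ValueError("tri_subdomain length mismatch")
        if len(self.line_subdomain) != len(self.lines):
            raise ValueError("line_subdomain length mismatch")
        self._check_degenerate()
        self._vertex_subdomain = self._derive_vertex_subdomain()
        self._surface_mask = self._derive_surface_mask()

    # -- derived fields ---------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def vertex_subdomain(self) -> np.ndarray:
        """Per-vertex integer label (surface labels take precedence)."""
        return self._vertex_subdomain

    @property
    def surface_mask(self) -> np.ndarray:
        """Boolean mask of vertices incident to at least one triangle."""
        return self._surface_mask

    def _derive_vertex_subdomain(self) -> np.ndarray:
        sd = np.zeros(self.n_vertices, dtype=np.int64)
        for conn, labels in ((self.lines, self.line_subdomain), (self.tetrahedra, self.tet_subdomain)):
            for elem, lab in zip(conn, labels):
                sd[elem] = lab
        # surface labels overwrite volume labels (more specific); among
        # several surface labels at a vertex the largest wins, making the
        # derivation order-independent (absorbing "sink" labels are by
        # convention the largest)
        order = np.argsort(self.tri_subdomain, kind="stable")
        for idx in order:
            sd[self.triangles[idx]] = self.tri_subdomain[idx]
        return sd

    def _derive_surface_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_vertices, dtype=bool)
        if len(self.triangles):
            mask[np.unique(self.triangles)] = True
        return mask

    def _check_degenerate(self) -> None:
        if len(self.tetrahedra):
            vol = np.abs(self.tet_volumes())
            if vol.min() <= _DEGENERATE_TOL:
                raise ValueError("degenerate tetrahedron (|volume| <= 1e-12 um^3)")
        if len(self.triangles):
            area = self.tri_areas()
            if area.min() <= _DEGENERATE_TOL:
                raise ValueError("degenerate triangle (area <= 1e-12 um^2)")
        if len(self.lines):
            d = np.linalg.norm(np.diff(self.vertices[self.lines], axis=1)[:, 0, :], axis=1)
            if d.min() <= _DEGENERATE_TOL:
                raise ValueError("degenerate line segment")

    # -- geometry ---------------------------------------------------------

    def tet_volumes(self) -> np.ndarray:
        """Signed volumes of the tetrahedra (um^3)."""
        v = self.vertices[self.tetrahedra]
        a, b, c = v[:, 1] - v[:, 0], v[:, 2] - v[:, 0], v[:, 3] - v[:, 0]
        return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0

    def tri_areas(self) -> np.ndarray:
        """Areas of the surface triangles (um^2)."""
        v = self.vertices[self.triangles]
        return 0.5 * np.linalg.norm(np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1)

    def edges(self) -> np.ndarray:
        """Unique undirected element edges as an (E, 2) array."""
        parts = []
        for conn, k in ((self.tetrahedra, 4), (self.triangles, 3), (self.lines, 2)):
            if len(conn) == 0:
                continue
            for i in range(k):
                for j in range(i + 1, k):
                    parts.append(conn[:, [i, j]])
        if not parts:
            return np.zeros((0, 2), dtype=np.int64)
        e = np.vstack(parts)
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def connected_components(self) -> tuple[int, np.ndarray]:
        """Number of edge-connected components and per-vertex labels."""
        e = self.edges()
        n = self.n_vertices
        adj = coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n))
        return _cc(adj, directed=False)

    def with_relabelled_surface(self, label: int) -> "Mesh":
        """Copy of the mesh with every triangle labelled ``label``."""
        return Mesh(
            self.vertices.copy(),
            self.tetrahedra.copy(),
            self.triangles.copy(),
            self.lines.copy(),
            self.tet_subdomain.copy(),
            np.full(len(self.triangles), label, dtype=np.int64),
            self.line_subdomain.copy(),
        )


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_interval_mesh(n_voxels: int, length: float) -> Mesh:
    """Uniform 1D chain on the x-axis with ``n_voxels`` vertices.

    Spacing is ``h = length / (n_voxels - 1)``; lumped voxel volumes are
    ``h/2`` at the two ends and ``h`` in the interior (units: um).
    """
    if n_voxels < 2:
        raise ValueError("n_voxels must be >= 2")
    if length <= 0:
        raise ValueError("length must be positive")
    x = np.linspace(0.0, length, n_voxels)
    verts = np.column_stack([x, np.zeros(n_voxels), np.zeros(n_voxels)])
    lines = np.column_stack([np.arange(n_voxels - 1), np.arange(1, n_voxels)])
    return Mesh(verts, lines=lines)


_CUBE_TETS = np.array(  # Kuhn subdivision of the unit cube into 6 tets
    [
        [0, 1, 3, 7],
        [0, 1, 5, 7],
        [0, 4, 5, 7],
        [0, 4, 6, 7],
        [0, 2, 6, 7],
        [0, 2, 3, 7],
    ],
    dtype=np.int64,
)


def generate_box_mesh(nx: int, ny: int, nz: int, lx: float, ly: float, lz: float) -> Mesh:
    """Structured box split into 6 tetrahedra per cell (Kuhn subdivision)."""
    if min(nx, ny, nz) < 2:
        raise ValueError("grid sizes must be >= 2")
    if min(lx, ly, lz) <= 0:
        raise ValueError("box dimensions must be positive")
    xs = np.linspace(0, lx, nx)
    ys = np.linspace(0, ly, ny)
    zs = np.linspace(0, lz, nz)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    verts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def vid(i, j, k):
        return (i * ny + j) * nz + k

    tets = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            for k in range(nz - 1):
                corners = np.array(
                    [vid(i + a, j + b, k + c) for a in (0, 1) for b in (0, 1) for c in (0, 1)]
                )
                tets.append(corners[_CUBE_TETS])
    tets = np.vstack(tets)
    tets = _orient_tets(verts, tets)
    tris = _boundary_faces(tets)
    return Mesh(verts, tetrahedra=tets, triangles=tris)


def _orient_tets(verts: np.ndarray, tets: np.ndarray) -> np.ndarray:
    v = verts[tets]
    neg = np.einsum("ij,ij->i", v[:, 1] - v[:, 0], np.cross(v[:, 2] - v[:, 0], v[:, 3] - v[:, 0])) < 0
    tets = tets.copy()
    tets[neg] = tets[neg][:, [0, 1, 3, 2]]
    return tets


def _boundary_faces(tets: np.ndarray) -> np.ndarray:
    """Faces of the tet mesh that belong to exactly one tetrahedron."""
    faces = np.vstack(
        [tets[:, [0, 1, 2]], tets[:, [0, 1, 3]], tets[:, [0, 2, 3]], tets[:, [1, 2, 3]]]
    )
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return faces[counts[inv] == 1]


def generate_icosphere_surface(subdivisions: int, radius: float) -> Mesh:
    """Triangulated sphere by recursive icosahedron subdivision.

    ``20 * 4**subdivisions`` triangles; vertices projected onto the sphere.
    The result is a surface-only mesh (no tetrahedra).
    """
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    if radius <= 0:
        raise ValueError("radius must be positive")
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    for _ in range(subdivisions):
        verts, faces = _subdivide(verts, faces)
    verts *= radius / np.linalg.norm(verts, axis=1)[:, None]
    return Mesh(verts, triangles=faces)


def _subdivide(verts: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    edge_mid: dict[tuple[int, int], int] = {}
    verts = list(verts)

    def mid(a: int, b: int) -> int:
        key = (a, b) if a < b else (b, a)
        if key not in edge_mid:
            edge_mid[key] = len(verts)
            verts.append(0.5 * (verts[a] + verts[b]))
        return edge_mid[key]

    new_faces = []
    for a, b, c in faces:
        ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
        new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
    return np.array(verts), np.array(new_faces, dtype=np.int64)


def generate_fibonacci_sphere_surface(n_vertices: int, radius: float = 1.0) -> Mesh:
    """Sphere surface triangulated from a Fibonacci point set.

    Unlike :func:`generate_icosphere_surface` this allows an arbitrary
    vertex count; the triangulation is the convex hull of the points.
    """
    if n_vertices < 4:
        raise ValueError("need at least 4 vertices")
    i = np.arange(n_vertices)
    golden = (1 + np.sqrt(5)) / 2
    z = 1 - 2 * (i + 0.5) / n_vertices
    theta = 2 * np.pi * i / golden
    rho = np.sqrt(np.maximum(0.0, 1 - z * z))
    pts = radius * np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    from scipy.spatial import ConvexHull

    hull = ConvexHull(pts)
    faces = hull.simplices.astype(np.int64)
    # orient all faces outward
    v = pts[faces]
    nrm = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    flip = np.einsum("ij,ij->i", nrm, v.mean(axis=1)) < 0
    faces[flip] = faces[flip][:, [0, 2, 1]]
    return Mesh(pts, triangles=faces)


# -- implicit capsule-union meshing -----------------------------------------


@dataclass(frozen=True)
class CapsuleSegment:
    """A capsule primitive: all points within ``radius`` of segment p0-p1.

    With ``p0 == p1`` this is a sphere.  Unions of these primitives are the
    geometric vocabulary of the built-in generators (rod-shaped bacteria,
    branched tube look-alikes of neurons).
    """

    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    radius: float
    label: int = CYTOSOL

    def distance(self, pts: np.ndarray) -> np.ndarray:
        p0 = np.asarray(self.p0, dtype=float)
        p1 = np.asarray(self.p1, dtype=float)
        d = p1 - p0
        L2 = d @ d
        if L2 == 0:
            return np.linalg.norm(pts - p0, axis=1)
        t = np.clip(((pts - p0) @ d) / L2, 0.0, 1.0)
        proj = p0 + t[:, None] * d
        return np.linalg.norm(pts - proj, axis=1)

    def sdf(self, pts: np.ndarray) -> np.ndarray:
        return self.distance(pts) - self.radius

    def project_to_surface(self, pts: np.ndarray) -> np.ndarray:
        """Closest point on the capsule surface for each input point."""
        p0 = np.asarray(self.p0, dtype=float)
        p1 = np.asarray(self.p1, dtype=float)
        d = p1 - p0
        L2 = d @ d
        if L2 > 0:
            t = np.clip(((pts - p0) @ d) / L2, 0.0, 1.0)
            proj = p0 + t[:, None] * d
        else:
            proj = np.broadcast_to(p0, pts.shape)
        nrm = pts - proj
        nn = np.linalg.norm(nrm, axis=1)
        # points exactly on the axis get an arbitrary but fixed direction
        unit = np.where(nn[:, None] > 1e-12, nrm / np.maximum(nn, 1e-12)[:, None], [1.0, 0.0, 0.0])
        return proj + self.radius * unit

    def _segment_distance(self, other: "CapsuleSegment") -> float:
        """Minimum distance between the two axis segments."""
        p0, p1 = np.asarray(self.p0, float), np.asarray(self.p1, float)
        q0, q1 = np.asarray(other.p0, float), np.asarray(other.p1, float)
        # sample-based minimization is robust enough for mesh clustering
        t = np.linspace(0, 1, 64)
        pa = p0 + np.outer(t, p1 - p0)
        best = np.inf
        for q in (q0 + np.outer(t, q1 - q0)):
            best = min(best, float(np.min(np.linalg.norm(pa - q, axis=1))))
        return best

    def overlaps(self, other: "CapsuleSegment") -> bool:
        return self._segment_distance(other) < self.radius + other.radius - 1e-12


def generate_capsule_union_mesh(
    segments: list[CapsuleSegment],
    h: float,
    surface_label: int | None = MEMBRANE,
    seed: int = 0,
) -> Mesh:
    """Tetrahedralize the union of capsule primitives.

    A body-centred-cubic point lattice of spacing ``h`` covers the domain;
    lattice points within ``0.3 h`` of the implicit surface are snapped
    onto it (a simplified isosurface-stuffing scheme, which avoids the
    sliver tetrahedra a naive surface sampling produces), the point set is
    Delaunay triangulated, and tetrahedra whose centroid lies outside the
    union are discarded.  The remaining boundary faces become the labelled
    surface.  Tet labels come from the first primitive containing the tet
    centroid.  Mutually overlapping primitives are meshed together;
    disjoint or merely touching bodies become separate mesh components.
    """
    if h <= 0:
        raise MeshGenerationError("target edge length h must be positive")
    if any(s.radius <= 0 for s in segments):
        raise MeshGenerationError("capsule radius must be positive")
    # mesh mutually overlapping primitives together; merely touching or
    # disjoint bodies become separate mesh components
    n = len(segments)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if segments[i].overlaps(segments[j]):
                parent[find(i)] = find(j)
    clusters: dict[int, list[CapsuleSegment]] = {}
    for i, s in enumerate(segments):
        clusters.setdefault(find(i), []).append(s)
    if len(clusters) > 1:
        meshes = [
            generate_capsule_union_mesh(group, h, surface_label, seed + k)
            for k, group in enumerate(clusters.values())
        ]
        return _concatenate_meshes(meshes)
    rng = np.random.default_rng(seed)

    def union_sdf(pts: np.ndarray) -> np.ndarray:
        return np.min(np.column_stack([s.sdf(pts) for s in segments]), axis=1)

    def project(pts: np.ndarray) -> np.ndarray:
        out = pts.copy()
        best = np.full(len(pts), np.inf)
        for s in segments:
            cand = s.project_to_surface(pts)
            d = np.abs(s.distance(pts) - s.radius)
            upd = d < best
            out[upd] = cand[upd]
            best[upd] = d[upd]
        return out

    # BCC lattice covering the union's bounding box
    lo = np.min([np.minimum(s.p0, s.p1) for s in segments], axis=0) - np.max(
        [s.radius for s in segments]
    ) - 2 * h
    hi = np.max([np.maximum(s.p0, s.p1) for s in segments], axis=0) + np.max(
        [s.radius for s in segments]
    ) + 2 * h
    axes = [np.arange(lo[d], hi[d] + h, h) for d in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    lattice = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    lattice = np.vstack([lattice, lattice + h / 2])
    d = union_sdf(lattice)
    near = np.abs(d) < 0.3 * h
    lattice[near] = project(lattice[near])
    keep = (d < 0) | near
    pts = lattice[keep]
    snapped = near[keep]
    # tiny jitter on interior points breaks the degenerate co-spherical
    # configurations of an exact BCC lattice
    pts[~snapped] += rng.uniform(-0.01 * h, 0.01 * h, size=(int((~snapped).sum()), 3))

    if len(pts) < 5:
        raise MeshGenerationError("parameters produce too few mesh points; decrease h")
    tri = Delaunay(pts)
    tets = tri.simplices.astype(np.int64)
    centroids = pts[tets].mean(axis=1)
    keep = union_sdf(centroids) < -1e-12
    # drop slivers of negligible volume
    v = pts[tets]
    vol = np.abs(
        np.einsum("ij,ij->i", v[:, 1] - v[:, 0], np.cross(v[:, 2] - v[:, 0], v[:, 3] - v[:, 0]))
    ) / 6.0
    keep &= vol > max(1e-10, 1e-6 * h**3)
    tets = tets[keep]
    if len(tets) == 0:
        raise MeshGenerationError("no interior tetrahedra; geometry thinner than h?")
    tets = _orient_tets(pts, tets)
    tris = _boundary_faces(tets)
    # drop unreferenced vertices
    used = np.unique(np.concatenate([tets.ravel(), tris.ravel()]))
    remap = -np.ones(len(pts), dtype=np.int64)
    remap[used] = np.arange(len(used))
    pts = pts[used]
    tets = remap[tets]
    tris = remap[tris]

    def label_of(points: np.ndarray) -> np.ndarray:
        lab = np.full(len(points), segments[0].label, dtype=np.int64)
        best = np.full(len(points), np.inf)
        for s in segments:
            d = s.sdf(points)
            upd = d < best
            lab[upd] = s.label
            best[upd] = d[upd]
        return lab

    tet_sd = label_of(pts[tets].mean(axis=1))
    if surface_label is None:
        # label boundary triangles by the primitive they belong to, so
        # derived vertex labels carry the region structure everywhere
        tri_sd = label_of(pts[tris].mean(axis=1))
    else:
        tri_sd = np.full(len(tris), surface_label, dtype=np.int64)
    return Mesh(pts, tetrahedra=tets, triangles=tris, tet_subdomain=tet_sd, tri_subdomain=tri_sd)


def _concatenate_meshes(meshes: list[Mesh]) -> Mesh:
    off = 0
    verts, tets, tris, tsd, ssd = [], [], [], [], []
    for m in meshes:
        verts.append(m.vertices)
        tets.append(m.tetrahedra + off)
        tris.append(m.triangles + off)
        tsd.append(m.tet_subdomain)
        ssd.append(m.tri_subdomain)
        off += m.n_vertices
    return Mesh(
        np.vstack(verts),
        tetrahedra=np.vstack(tets),
        triangles=np.vstack(tris),
        tet_subdomain=np.concatenate(tsd),
        tri_subdomain=np.concatenate(ssd),
    )


def generate_capsule_mesh(
    length: float, radius: float, h: float, xsep: float = 0.0, seed: int = 0
) -> Mesh:
    """Rod-shaped cell (cylinder with hemispherical caps) along the x-axis.

    The geometry is the union of a base capsule spanning ``[0, length]``
    and a copy translated by ``xsep`` along +x — the parametrization used
    to emulate a growing/dividing bacterium.  For ``xsep`` larger than the
    axial segment length the union disconnects into two cells.

    Boundary triangles are labelled :data:`MEMBRANE`, tetrahedra
    :data:`CYTOSOL`.
    """
    if radius <= 0:
        raise MeshGenerationError("radius must be positive")
    if length <= 2 * radius:
        raise MeshGenerationError("length must exceed the two cap radii (2*radius)")
    if xsep < 0:
        raise MeshGenerationError("xsep must be >= 0")
    segs = [CapsuleSegment((radius, 0, 0), (length - radius, 0, 0), radius)]
    if xsep > 0:
        segs.append(CapsuleSegment((radius + xsep, 0, 0), (length - radius + xsep, 0, 0), radius))
    return generate_capsule_union_mesh(segs, h, surface_label=MEMBRANE, seed=seed)
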