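"""Triangulated cell cortex and substrate-plane geometry.

The cell cortex is a closed, outward-oriented icosphere whose connectivity is
immutable for the lifetime of a simulation; only node positions move.  The
substrate is a rigid plane at z = 0 tiled by right isosceles triangles of
fixed area, used to accumulate traction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh


def fast_cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise cross product without numpy's generic-axis overhead."""
    c = np.empty_like(a)
    c[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    c[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    c[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return c


def scatter_add(out: np.ndarray, idx: np.ndarray, vals: np.ndarray) -> None:
    """out[idx] += vals for (n, 3) values, via bincount (faster than ufunc.at)."""
    n = len(out)
    for k in range(3):
        out[:, k] += np.bincount(idx, weights=vals[:, k], minlength=n)

__all__ = [
    "CellMesh",
    "SubstrateGrid",
    "Region",
    "build_cell_mesh",
    "build_substrate_grid",
    "fit_local_sphere",
    "enclosed_volume",
    "SUBSTRATE_TRI_AREA",
]

#: Area of one substrate triangle [m^2].
SUBSTRATE_TRI_AREA = 2.102e-12


class Region:
    """Per-triangle region codes of the cell cortex."""

    BODY = 0
    LP = 1
    FRONT_LM = 2
    REAR_LM = 3
    TOP = 4

    NAMES = {0: "body", 1: "Lp", 2: "frontLm", 3: "rearLm", 4: "top"}


class MeshTopologyError(ValueError):
    """Mesh is not closed/orientable as required."""


@dataclass
class CellMesh:
    """Closed triangulated cortex with reference (rest) state.

    Connectivity arrays (``edges``, ``triangles``, ``hinges``,
    ``tri_neighbors``) are built once and never change; positions and
    velocities evolve.
    """

    positions: np.ndarray          # (N, 3) [m]
    velocities: np.ndarray         # (N, 3) [m/s]
    edges: np.ndarray              # (E, 2) int
    rest_lengths: np.ndarray       # (E,) [m]
    triangles: np.ndarray          # (T, 3) int, outward-oriented
    ref_tri_areas: np.ndarray      # (T,) [m^2]
    ref_total_area: float          # [m^2]
    ref_volume: float              # [m^3]
    hinges: np.ndarray             # (E, 4) int: edge v0,v1 + opposite v2,v3
    ref_dihedrals: np.ndarray      # (E,) [rad] dihedral angle of built state
    tri_neighbors: np.ndarray      # (T, 3) int: triangle adjacent across each edge
    region: np.ndarray = None      # (T,) int8 Region codes
    interface_node: np.ndarray = None  # (N,) bool

    def __post_init__(self):
        n, t = len(self.positions), len(self.triangles)
        if self.region is None:
            self.region = np.full(t, Region.TOP, dtype=np.int8)
        if self.interface_node is None:
            self.interface_node = np.zeros(n, dtype=bool)

    # -- derived quantities --------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def edge_vectors(self) -> np.ndarray:
        return self.positions[self.edges[:, 1]] - self.positions[self.edges[:, 0]]

    def tri_corners(self):
        p = self.positions
        t = self.triangles
        return p[t[:, 0]], p[t[:, 1]], p[t[:, 2]]

    def tri_normals_areas(self):
        """Outward unit normals and areas of all triangles."""
        a, b, c = self.tri_corners()
        cr = fast_cross(b - a, c - a)
        nrm = np.sqrt(np.einsum("ij,ij->i", cr, cr))
        areas = 0.5 * nrm
        with np.errstate(invalid="ignore", divide="ignore"):
            normals = cr / nrm[:, None]
        return normals, areas

    def tri_centroids(self) -> np.ndarray:
        a, b, c = self.tri_corners()
        return (a + b + c) / 3.0

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted incident-triangle normals, normalized per vertex."""
        a, b, c = self.tri_corners()
        cr = fast_cross(b - a, c - a)  # area-weighted normals (2A n)
        vn = np.zeros_like(self.positions)
        for k in range(3):
            np.add.at(vn, self.triangles[:, k], cr)
        nrm = np.linalg.norm(vn, axis=1)
        nrm[nrm == 0] = 1.0
        return vn / nrm[:, None]

    def total_area(self) -> float:
        return float(self.tri_normals_areas()[1].sum())

    def copy(self) -> "CellMesh":
        return CellMesh(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            edges=self.edges, rest_lengths=self.rest_lengths,
            triangles=self.triangles, ref_tri_areas=self.ref_tri_areas,
            ref_total_area=self.ref_total_area, ref_volume=self.ref_volume,
            hinges=self.hinges, ref_dihedrals=self.ref_dihedrals,
            tri_neighbors=self.tri_neighbors,
            region=self.region.copy(),
            interface_node=self.interface_node.copy(),
        )


def _build_connectivity(faces: np.ndarray):
    """Edges, hinge quadruples and per-triangle neighbors of a closed mesh."""
    edge_map: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for ti, (a, b, c) in enumerate(faces):
        for (u, v, w) in ((a, b, c), (b, c, a), (c, a, b)):
            key = (min(u, v), max(u, v))
            edge_map.setdefault(key, []).append((ti, w))
    edges, hinges = [], []
    tri_neighbors = np.full((len(faces), 3), -1, dtype=np.int64)
    for (u, v), incident in edge_map.items():
        if len(incident) != 2:
            raise MeshTopologyError(
                f"edge ({u},{v}) shared by {len(incident)} triangles; mesh not closed"
            )
        (t1, w1), (t2, w2) = incident
        edges.append((u, v))
        hinges.append((u, v, w1, w2))
    # neighbor lookup: triangle adjacent across the edge opposite local vertex k
    for (u, v), ((t1, _), (t2, _)) in edge_map.items():
        for ta, tb in ((t1, t2), (t2, t1)):
            verts = faces[ta]
            for k in range(3):
                e = {verts[(k + 1) % 3], verts[(k + 2) % 3]}
                if e == {u, v}:
                    tri_neighbors[ta, k] = tb
    return (np.asarray(edges, dtype=np.int64),
            np.asarray(hinges, dtype=np.int64),
            tri_neighbors)


def dihedral_angles(positions: np.ndarray, hinges: np.ndarray) -> np.ndarray:
    """Signed dihedral angle at each hinge (0 for coplanar, >0 convex)."""
    x0 = positions[hinges[:, 0]]
    x1 = positions[hinges[:, 1]]
    x2 = positions[hinges[:, 2]]
    x3 = positions[hinges[:, 3]]
    e = x1 - x0
    n1 = fast_cross(e, x2 - x0)
    n2 = fast_cross(x3 - x0, e)
    n1n = np.sqrt(np.einsum("ij,ij->i", n1, n1))
    n2n = np.sqrt(np.einsum("ij,ij->i", n2, n2))
    cosb = np.einsum("ij,ij->i", n1, n2) / (n1n * n2n)
    sinb = np.einsum("ij,ij->i", fast_cross(n1, n2), e) / (
        n1n * n2n * np.sqrt(np.einsum("ij,ij->i", e, e)))
    return np.arctan2(sinb, np.clip(cosb, -1.0, 1.0))


def build_cell_mesh(radius: float = 8e-6, subdivision: int = 3) -> CellMesh:
    """Build the spherical cortex as an icosphere scaled to ``radius``.

    An icosphere with ``s`` subdivisions has ``10*4**s + 2`` nodes and
    ``20*4**s`` triangles.  The built state (edge lengths, triangle areas,
    enclosed volume, dihedral angles) is recorded as the reference state.

    A subdivision below 2 cannot resolve the ~1-2 um lamellipodium band of an
    8 um cell and triggers a warning.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if subdivision < 1:
        raise ValueError("subdivision must be >= 1")
    if subdivision < 2:
        warnings.warn("subdivision < 2 cannot resolve the lamellipodium band",
                      stacklevel=2)
    ico = trimesh.creation.icosphere(subdivisions=subdivision, radius=radius)
    faces = np.asarray(ico.faces, dtype=np.int64)
    pos = np.asarray(ico.vertices, dtype=np.float64)
    edges, hinges, tri_neighbors = _build_connectivity(faces)

    a, b, c = pos[faces[:, 0]], pos[faces[:, 1]], pos[faces[:, 2]]
    areas = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
    mesh = CellMesh(
        positions=pos,
        velocities=np.zeros_like(pos),
        edges=edges,
        rest_lengths=np.linalg.norm(pos[edges[:, 1]] - pos[edges[:, 0]], axis=1),
        triangles=faces,
        ref_tri_areas=areas,
        ref_total_area=float(areas.sum()),
        ref_volume=_signed_volume(pos, faces),
        hinges=hinges,
        ref_dihedrals=dihedral_angles(pos, hinges),
        tri_neighbors=tri_neighbors,
    )
    if mesh.ref_volume <= 0:
        raise MeshTopologyError("built mesh is not outward-oriented")
    return mesh


def _signed_volume(positions: np.ndarray, faces: np.ndarray) -> float:
    a = positions[faces[:, 0]]
    b = positions[faces[:, 1]]
    c = positions[faces[:, 2]]
    return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


def enclosed_volume(mesh: CellMesh) -> float:
    """Signed enclosed volume by the divergence theorem [m^3].

    Raises
    ------
    MeshTopologyError
        If the mesh is not closed or the orientation is inward (negative
        volume).
    """
    # closedness is structural and verified at build time; re-verify cheaply
    if mesh.hinges.shape[0] != mesh.edges.shape[0]:
        raise MeshTopologyError("mesh is not closed")
    v = _signed_volume(mesh.positions, mesh.triangles)
    if v <= 0:
        raise MeshTopologyError(f"negative enclosed volume ({v:.3e}); inward orientation")
    return v


# -- local sphere fitting ------------------------------------------------

#: Radii beyond this multiple of the patch size are reported as flat (inf).
_FLAT_RADIUS_FACTOR = 1e4


def fit_sphere_to_points(points: np.ndarray) -> tuple[np.ndarray | None, float]:
    """Algebraic least-squares sphere through ``points``.

    Returns ``(center, radius)``; a degenerate (planar) point set returns
    ``(None, inf)``.
    """
    pts = np.asarray(points, dtype=np.float64)
    centroid = pts.mean(axis=0)
    q = pts - centroid
    scale = np.linalg.norm(q, axis=1).max()
    if scale == 0:
        raise ValueError("degenerate point set")
    q = q / scale
    A = np.column_stack([2.0 * q, np.ones(len(q))])
    rhs = np.einsum("ij,ij->i", q, q)
    sol, _, rank, sv = np.linalg.lstsq(A, rhs, rcond=None)
    if rank < 4 or sv[-1] < 1e-9 * sv[0]:
        return None, math.inf
    c = sol[:3]
    r = math.sqrt(max(sol[3] + c @ c, 0.0))
    radius = r * scale
    if radius > _FLAT_RADIUS_FACTOR * scale:
        return None, math.inf
    return centroid + c * scale, radius


def fit_local_sphere(triangle: int, mesh: CellMesh) -> float:
    """Radius [m] of the sphere fit to a triangle's 1-ring neighborhood.

    A flat neighborhood (e.g., a substrate triangle) returns ``inf``.
    Collinear triangle vertices raise ``ValueError``.
    """
    tri = mesh.triangles[triangle]
    a, b, c = mesh.positions[tri]
    cross = np.cross(b - a, c - a)
    if np.linalg.norm(cross) < 1e-12 * max(np.linalg.norm(b - a), 1e-300) ** 2:
        raise ValueError(f"triangle {triangle} has collinear vertices")
    ring = set(tri.tolist())
    for k in range(3):
        nb = mesh.tri_neighbors[triangle, k]
        ring.update(mesh.triangles[nb].tolist())
    pts = mesh.positions[sorted(ring)]
    _, radius = fit_sphere_to_points(pts)
    return radius


def ring_curvature_radii(mesh: CellMesh, tri_ids: np.ndarray) -> np.ndarray:
    """Vectorised convenience: 1-ring sphere-fit radii for many triangles."""
    return np.array([fit_local_sphere(int(t), mesh) for t in tri_ids])


# -- substrate -----------------------------------------------------------

@dataclass
class SubstrateGrid:
    """Rigid plane at z = 0 tiled by right isosceles triangles.

    Each square cell of side ``leg`` is split along its diagonal into two
    right isosceles triangles of area :data:`SUBSTRATE_TRI_AREA`.  Triangles
    are indexed ``2*(j*nx + i) + h`` with ``h = 0`` for the lower-left half
    (u + v < 1 in square-local coordinates) and ``h = 1`` otherwise.
    """

    origin: np.ndarray        # (2,) lower-left corner [m]
    nx: int
    ny: int
    leg: float                # [m]
    forces: np.ndarray = None  # (2*nx*ny, 3) accumulated force [N]

    def __post_init__(self):
        if self.forces is None:
            self.forces = np.zeros((self.n_triangles, 3))

    @property
    def n_triangles(self) -> int:
        return 2 * self.nx * self.ny

    @property
    def tri_area(self) -> float:
        return 0.5 * self.leg**2

    @property
    def extent(self) -> tuple[float, float]:
        return self.nx * self.leg, self.ny * self.leg

    def triangle_index(self, x, y):
        """Index of the triangle containing each (x, y) point.

        Raises ``ValueError`` for points outside the grid.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        u = (x - self.origin[0]) / self.leg
        v = (y - self.origin[1]) / self.leg
        i = np.floor(u).astype(np.int64)
        j = np.floor(v).astype(np.int64)
        if np.any((i < 0) | (i >= self.nx) | (j < 0) | (j >= self.ny)):
            raise ValueError("point outside substrate grid; enlarge the plane")
        half = ((u - i) + (v - j) >= 1.0).astype(np.int64)
        return 2 * (j * self.nx + i) + half

    def triangle_vertices(self, index: int) -> np.ndarray:
        """(3, 3) vertex coordinates of one triangle (z = 0)."""
        half = index % 2
        cell = index // 2
        j, i = divmod(cell, self.nx)
        x0 = self.origin[0] + i * self.leg
        y0 = self.origin[1] + j * self.leg
        L = self.leg
        if half == 0:
            verts = [(x0, y0), (x0 + L, y0), (x0, y0 + L)]
        else:
            verts = [(x0 + L, y0), (x0 + L, y0 + L), (x0, y0 + L)]
        return np.array([(x, y, 0.0) for x, y in verts])


def build_substrate_grid(
    length: float = 80e-6,
    width: float = 40e-6,
    origin: tuple[float, float] | None = None,
) -> SubstrateGrid:
    """Tile a rectangle of roughly ``length`` x ``width`` with substrate triangles.

    The extent snaps to integer multiples of the triangle leg
    ``sqrt(2 * 2.102 um^2)`` so that the tiling is exact.  By default the
    grid is centred on y = 0 and spans x in [-length/4, +3 length/4], leaving
    room ahead of a cell initialized at the origin and migrating in +x.
    """
    if length <= 0 or width <= 0:
        raise ValueError("substrate extent must be positive")
    leg = math.sqrt(2.0 * SUBSTRATE_TRI_AREA)
    nx = max(1, round(length / leg))
    ny = max(1, round(width / leg))
    if origin is None:
        origin = (-nx * leg / 4.0, -ny * leg / 2.0)
    return SubstrateGrid(origin=np.asarray(origin, dtype=float), nx=nx, ny=ny, leg=leg)
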