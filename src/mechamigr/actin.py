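"""Globular-actin surface field, region demarcation, and polarization forces.

A reaction–diffusion field G (molecules/m^2) lives on the cortex triangles:
periphery triangles of the cell–substrate interface act as sources, all
triangles decay, and diffusion runs across triangle adjacency by a
finite-volume scheme.  Thresholds on G demarcate the lamellipodium (Lp, the
outer band of the leading front, where protrusion acts) and the lamella (Lm,
the bands where focal adhesions may form).  The steady-state band structure
follows the decay length sqrt(D_actin / k_deg) ~ 2.2 um.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from .geometry import CellMesh, Region
from .params import ParamSet

__all__ = [
    "ActinField",
    "RegionLabels",
    "StabilityError",
    "diffusion_weights",
    "stability_limit",
    "step_actin_field",
    "update_interface_flags",
    "identify_periphery",
    "split_front_rear",
    "demarcate_regions",
    "triangle_gradients",
    "protrusion_forces",
    "counter_force",
]


class StabilityError(RuntimeError):
    """Explicit diffusion step exceeds its stability bound."""


@dataclass
class ActinField:
    """Per-triangle globular-actin concentration [molecules/m^2]."""

    G: np.ndarray

    def copy(self) -> "ActinField":
        return ActinField(G=self.G.copy())


@dataclass
class RegionLabels:
    """Per-triangle region codes plus the (fixed, +x) polarity axis."""

    labels: np.ndarray                         # (T,) int8 Region codes
    axis: np.ndarray = dc_field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))

    def mask(self, code: int) -> np.ndarray:
        return self.labels == code


def diffusion_weights(mesh: CellMesh):
    """Finite-volume diffusion weights across triangle adjacency.

    For each triangle i and neighbor k (across shared edge), the exchange
    weight is (shared edge length) / (centroid distance); the rate of change
    of G_i is D/A_i * sum_k w_ik (G_k - G_i).

    Returns
    -------
    (areas, neighbor_index, weights) with shapes (T,), (T, 3), (T, 3).
    """
    pos = mesh.positions
    tris = mesh.triangles
    cent = mesh.tri_centroids()
    areas = mesh.tri_normals_areas()[1]
    nb = mesh.tri_neighbors
    w = np.empty((len(tris), 3))
    own = np.arange(len(tris))
    for k in range(3):
        # edge opposite local vertex k: vertices (k+1)%3, (k+2)%3
        va = pos[tris[:, (k + 1) % 3]]
        vb = pos[tris[:, (k + 2) % 3]]
        elen = np.linalg.norm(vb - va, axis=1)
        dist = np.linalg.norm(cent[nb[:, k]] - cent, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            w[:, k] = np.where(nb[:, k] == own, 0.0, elen / dist)
    # a triangle listed as its own neighbor marks an open boundary (zero flux)
    return areas, nb, w


def stability_limit(mesh: CellMesh, params: ParamSet, weights=None) -> float:
    """Largest stable explicit time step for the surface-diffusion scheme [s]."""
    areas, _, w = weights if weights is not None else diffusion_weights(mesh)
    rate = params.D_actin * w.sum(axis=1) / areas  # per-triangle outflow rate
    total = rate + params.k_deg
    return float(1.0 / total.max())


def step_actin_field(
    field: ActinField,
    mesh: CellMesh,
    sources: np.ndarray,
    dt: float,
    params: ParamSet,
    subcycle: bool = True,
    weights=None,
) -> ActinField:
    """Advance the actin field by ``dt``.

    dG/dt = k_gen * 1[source] - k_deg * G + D_actin * Laplacian(G), explicit
    Euler with sub-cycling when ``dt`` exceeds the stability bound.  With
    ``subcycle=False`` an over-long step raises :class:`StabilityError`
    reporting the bound.  Nonnegativity is preserved by the stable scheme.
    ``weights`` may carry precomputed :func:`diffusion_weights`.
    """
    if weights is None:
        weights = diffusion_weights(mesh)
    areas, nb, w = weights
    bound = stability_limit(mesh, params, weights)
    if dt > bound and not subcycle:
        raise StabilityError(f"dt={dt} exceeds explicit stability bound {bound:.4g} s")
    nsub = max(1, int(np.ceil(dt / bound)))
    h = dt / nsub

    src = np.zeros(mesh.n_triangles)
    src[np.asarray(sources, dtype=np.int64)] = params.k_gen

    G = field.G.astype(np.float64, copy=True)
    coef = params.D_actin / areas
    for _ in range(nsub):
        flux = (w * (G[nb] - G[:, None])).sum(axis=1)
        G = G + h * (src - params.k_deg * G + coef * flux)
    np.maximum(G, 0.0, out=G)
    return ActinField(G=G)


def steady_state_actin(mesh: CellMesh, sources: np.ndarray, params: ParamSet) -> ActinField:
    """Exact steady state of the reaction–diffusion field (sparse solve).

    Solves ``(A_i k_deg + D sum_k w_ik) G_i - D sum_k w_ik G_k = A_i k_gen``
    on source triangles (0 elsewhere) — the fixed point the explicit
    integrator relaxes to.
    """
    import scipy.sparse
    import scipy.sparse.linalg

    areas, nb, w = diffusion_weights(mesh)
    T = mesh.n_triangles
    rows = np.repeat(np.arange(T), 3)
    cols = nb.ravel()
    offdiag = -params.D_actin * w.ravel()
    diag = areas * params.k_deg + params.D_actin * w.sum(axis=1)
    A = scipy.sparse.coo_matrix(
        (np.concatenate([offdiag, diag]),
         (np.concatenate([rows, np.arange(T)]),
          np.concatenate([cols, np.arange(T)]))),
        shape=(T, T)).tocsr()
    rhs = np.zeros(T)
    rhs[np.asarray(sources, dtype=np.int64)] = \
        areas[np.asarray(sources, dtype=np.int64)] * params.k_gen
    G = scipy.sparse.linalg.spsolve(A, rhs)
    return ActinField(G=np.maximum(G, 0.0))


def update_interface_flags(mesh: CellMesh, params: ParamSet) -> None:
    """Flag nodes within ``interface_height`` of the substrate plane (z = 0)."""
    mesh.interface_node[:] = mesh.positions[:, 2] <= params.interface_height


def _interface_triangles(mesh: CellMesh) -> np.ndarray:
    """Triangles all of whose vertices are interface nodes."""
    return mesh.interface_node[mesh.triangles].all(axis=1)


def identify_periphery(mesh: CellMesh) -> np.ndarray:
    """Source triangles: the boundary ring of the cell–substrate interface.

    Interface triangles adjacent to at least one non-interface triangle.
    Returns an empty array (with a warning) if the cell is detached.
    """
    iface = _interface_triangles(mesh)
    if not iface.any():
        warnings.warn("cell has no substrate interface; periphery is empty",
                      stacklevel=2)
        return np.empty(0, dtype=np.int64)
    neighbor_iface = iface[mesh.tri_neighbors]  # (T, 3)
    ring = iface & ~neighbor_iface.all(axis=1)
    return np.flatnonzero(ring)


def split_front_rear(mesh: CellMesh) -> np.ndarray:
    """Per-triangle front mask of the interface partition.

    Interface entities with centroid x >= x of the interface-node centre of
    mass are front (ties break to front); the mask is reported for every
    triangle but only meaningful on the interface.
    """
    if not mesh.interface_node.any():
        raise ValueError("no interface; cannot split front/rear")
    x_com = mesh.positions[mesh.interface_node, 0].mean()
    return mesh.tri_centroids()[:, 0] >= x_com


def demarcate_regions(field: ActinField, mesh: CellMesh, params: ParamSet) -> RegionLabels:
    """Label triangles Lp / frontLm / rearLm / body / top from the actin field.

    Thresholds are fractions (theta_Lp, theta_Lm) of the source steady state
    G* = k_gen / k_deg.  The Lp is restricted to the leading front; the rear
    has a lamellum but no lamellipodium.  Non-interface triangles are ``top``.
    """
    if params.theta_Lm >= params.theta_Lp:
        raise ValueError("theta_Lm must be below theta_Lp")
    gstar = params.G_star
    iface = _interface_triangles(mesh)
    front = split_front_rear(mesh)

    labels = np.full(mesh.n_triangles, Region.TOP, dtype=np.int8)
    labels[iface] = Region.BODY
    g = field.G
    lm = iface & (g >= params.theta_Lm * gstar) & (g < params.theta_Lp * gstar)
    lp = iface & (g >= params.theta_Lp * gstar)
    labels[lm & front] = Region.FRONT_LM
    labels[lm & ~front] = Region.REAR_LM
    labels[lp & front] = Region.LP
    # high-G rear triangles are lamellum, not lamellipodium
    labels[lp & ~front] = Region.REAR_LM
    if not (labels == Region.FRONT_LM).any() and not (labels == Region.REAR_LM).any():
        warnings.warn("empty lamellum after demarcation", stacklevel=2)
    out = RegionLabels(labels=labels)
    mesh.region[:] = labels
    return out


def triangle_gradients(field: ActinField, mesh: CellMesh) -> np.ndarray:
    """Surface gradient of G per triangle [molecules/m^3].

    Least-squares fit over the three centroid-to-neighbor differences; the
    minimum-norm solution lies in the local surface plane.
    """
    cent = mesh.tri_centroids()
    nb = mesh.tri_neighbors
    grads = np.zeros((mesh.n_triangles, 3))
    d = cent[nb] - cent[:, None, :]          # (T, 3, 3)
    dg = field.G[nb] - field.G[:, None]      # (T, 3)
    # normal-equation solve with Tikhonov guard for the out-of-plane direction
    AtA = np.einsum("tki,tkj->tij", d, d)
    Atb = np.einsum("tki,tk->ti", d, dg)
    scale = np.trace(AtA, axis1=1, axis2=2)[:, None, None]
    AtA = AtA + 1e-9 * scale * np.eye(3)
    grads = np.linalg.solve(AtA, Atb[..., None])[..., 0]
    return grads


def protrusion_forces(
    field: ActinField,
    labels: RegionLabels,
    mesh: CellMesh,
    params: ParamSet,
) -> np.ndarray:
    """Per-triangle protrusion force [N], nonzero only on Lp triangles.

    F = k_prot * G * grad(G)/|grad(G)| projected on the substrate-tangent
    (xy) plane; zero where the gradient is degenerate.
    """
    out = np.zeros((mesh.n_triangles, 3))
    lp = labels.mask(Region.LP)
    if not lp.any():
        return out
    grads = triangle_gradients(field, mesh)
    g_t = grads[lp].copy()
    g_t[:, 2] = 0.0  # substrate-tangent projection
    norms = np.linalg.norm(g_t, axis=1)
    eps = 1e-9 * params.G_star / params.R_c
    ok = norms > eps
    direction = np.zeros_like(g_t)
    direction[ok] = g_t[ok] / norms[ok, None]
    out[lp] = params.k_prot * field.G[lp, None] * direction
    return out


def counter_force(prot: np.ndarray, mesh: CellMesh) -> np.ndarray:
    """Per-node counter force balancing the total protrusion force.

    Every cortex node receives -(1/n_node) * sum of the per-triangle
    protrusion forces, so protrusion + counter sum to zero exactly.
    """
    total = prot.sum(axis=0)
    return np.tile(-total / mesh.n_nodes, (mesh.n_nodes, 1))
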