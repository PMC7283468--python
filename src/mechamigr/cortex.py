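"""Passive cortex mechanics: edge viscoelasticity, area/volume conservation,
and hinge bending.

All conservative contributions are exact analytic gradients of the discrete
energies below, so they can be verified against central finite differences:

* edge springs        E_s = sum_e (k_cortex/2) (d - d*)^2
* local area          E_Al = sum_t (k_area_loc/2) (A - A_ref)^2 / A_ref
* global area         E_Ag = (k_area_glob/2) (A_tot - A_ref_tot)^2 / A_ref_tot
* volume              E_V = (k_vol/2) (V - V_ref)^2 / V_ref
* bending             E_B = k_bend sum_h (1 - cos(theta - theta_ref))

The edge dashpot is part of the friction operator of the dynamics engine;
:func:`edge_viscoelastic_forces` exposes it explicitly for testing.
"""

from __future__ import annotations

import numpy as np

from .geometry import (CellMesh, dihedral_angles, _signed_volume,
                       fast_cross, scatter_add)
from .params import ParamSet

__all__ = [
    "ForceAccumulator",
    "edge_viscoelastic_forces",
    "area_conservation_forces",
    "volume_conservation_force",
    "bending_forces",
    "cortex_energies",
]

CATEGORIES = (
    "linear", "dashpot", "area", "volume", "bend",
    "contact", "fa", "sf", "protrusion", "counter",
)


class ForceAccumulator:
    """Per-node force vectors [N] keyed by category."""

    def __init__(self, n_nodes: int):
        self.n_nodes = n_nodes
        self.forces: dict[str, np.ndarray] = {}

    def __getitem__(self, category: str) -> np.ndarray:
        if category not in self.forces:
            self.forces[category] = np.zeros((self.n_nodes, 3))
        return self.forces[category]

    def add(self, category: str, contribution: np.ndarray) -> None:
        arr = self[category]
        arr += contribution

    def total(self) -> np.ndarray:
        out = np.zeros((self.n_nodes, 3))
        for f in self.forces.values():
            out += f
        return out

    def internal_total(self) -> np.ndarray:
        """Sum of cell-internal categories (must balance to zero net force)."""
        out = np.zeros((self.n_nodes, 3))
        for cat in ("linear", "area", "volume", "bend", "sf", "protrusion", "counter"):
            if cat in self.forces:
                out += self.forces[cat]
        return out


def edge_viscoelastic_forces(mesh: CellMesh, params: ParamSet) -> dict[str, np.ndarray]:
    """Spring (``linear``) and dashpot forces of the cortex edges.

    Per edge (i, j): spring magnitude ``k_cortex * (d_ij - d*_ij)`` along the
    edge axis, and damping ``-Lambda_d * (n_ij . v_ij)`` along the same axis;
    equal and opposite on the two endpoints.
    """
    i, j = mesh.edges[:, 0], mesh.edges[:, 1]
    dvec = mesh.positions[j] - mesh.positions[i]
    d = np.sqrt(np.einsum("ij,ij->i", dvec, dvec))
    if np.any(d <= 0):
        raise ValueError("zero-length cortex edge")
    nhat = dvec / d[:, None]

    # tension positive when stretched: pulls i toward j
    tension = params.k_cortex * (d - mesh.rest_lengths)
    f_spring_i = tension[:, None] * nhat

    vrel = mesh.velocities[i] - mesh.velocities[j]
    f_dash_i = -params.Lambda_d * np.einsum("ij,ij->i", nhat, vrel)[:, None] * nhat

    n = mesh.n_nodes
    spring = np.zeros((n, 3))
    dash = np.zeros((n, 3))
    scatter_add(spring, i, f_spring_i)
    scatter_add(spring, j, -f_spring_i)
    scatter_add(dash, i, f_dash_i)
    scatter_add(dash, j, -f_dash_i)
    return {"linear": spring, "dashpot": dash}


def _tri_area_gradients(mesh: CellMesh):
    """Areas and dA/dx for each triangle corner; shape (T,), 3 x (T, 3)."""
    a, b, c = mesh.tri_corners()
    cr = fast_cross(b - a, c - a)
    nrm = np.sqrt(np.einsum("ij,ij->i", cr, cr))
    areas = 0.5 * nrm
    nhat = cr / nrm[:, None]
    # grad of A wrt corner p is 0.5 * nhat x (opposite edge vector)
    ga = 0.5 * fast_cross(nhat, c - b)
    gb = 0.5 * fast_cross(nhat, a - c)
    gc = 0.5 * fast_cross(nhat, b - a)
    return areas, (ga, gb, gc)


def area_conservation_forces(mesh: CellMesh, params: ParamSet) -> np.ndarray:
    """Restoring forces of the local + global area energies (category ``area``)."""
    if mesh.ref_tri_areas is None or mesh.ref_total_area is None:
        raise ValueError("reference areas missing")
    areas, grads = _tri_area_gradients(mesh)
    coeff_loc = params.k_area_loc * (areas - mesh.ref_tri_areas) / mesh.ref_tri_areas
    coeff_glob = params.k_area_glob * (areas.sum() - mesh.ref_total_area) / mesh.ref_total_area
    coeff = coeff_loc + coeff_glob  # dE/dA per triangle
    out = np.zeros((mesh.n_nodes, 3))
    for k, g in enumerate(grads):
        scatter_add(out, mesh.triangles[:, k], -coeff[:, None] * g)
    return out


def volume_conservation_force(mesh: CellMesh, params: ParamSet) -> np.ndarray:
    """Restoring force of the volume energy (category ``volume``)."""
    a, b, c = mesh.tri_corners()
    v = _signed_volume(mesh.positions, mesh.triangles)
    coeff = params.k_vol * (v - mesh.ref_volume) / mesh.ref_volume  # dE/dV
    # dV/da = (b x c)/6 etc.
    out = np.zeros((mesh.n_nodes, 3))
    scatter_add(out, mesh.triangles[:, 0], -coeff / 6.0 * fast_cross(b, c))
    scatter_add(out, mesh.triangles[:, 1], -coeff / 6.0 * fast_cross(c, a))
    scatter_add(out, mesh.triangles[:, 2], -coeff / 6.0 * fast_cross(a, b))
    return out


def _dihedral_gradients(positions: np.ndarray, hinges: np.ndarray):
    """Dihedral angles and their gradients wrt the four hinge vertices.

    Uses the standard translation-invariant decomposition: the two opposite
    vertices move along their triangle normals, the edge vertices carry the
    complementary weights so that the four gradients sum to zero.
    """
    x0 = positions[hinges[:, 0]]
    x1 = positions[hinges[:, 1]]
    x2 = positions[hinges[:, 2]]
    x3 = positions[hinges[:, 3]]
    e0 = x1 - x0
    elen2 = np.einsum("ij,ij->i", e0, e0)
    elen = np.sqrt(elen2)
    n1 = fast_cross(e0, x2 - x0)
    n2 = fast_cross(x3 - x0, e0)
    n1sq = np.einsum("ij,ij->i", n1, n1)
    n2sq = np.einsum("ij,ij->i", n2, n2)
    if np.any(n1sq == 0) or np.any(n2sq == 0):
        raise ValueError("degenerate hinge (zero-area triangle)")

    g2 = -(elen / n1sq)[:, None] * n1
    g3 = -(elen / n2sq)[:, None] * n2
    alpha2 = np.einsum("ij,ij->i", x2 - x0, e0) / elen2
    alpha3 = np.einsum("ij,ij->i", x3 - x0, e0) / elen2
    g0 = -((1.0 - alpha2)[:, None] * g2 + (1.0 - alpha3)[:, None] * g3)
    g1 = -(alpha2[:, None] * g2 + alpha3[:, None] * g3)

    theta = dihedral_angles(positions, hinges)
    return theta, (g0, g1, g2, g3)


def bending_forces(mesh: CellMesh, params: ParamSet) -> np.ndarray:
    """Hinge bending forces (category ``bend``).

    Energy ``k_bend * (1 - cos(theta - theta_ref))`` per hinge, with
    ``theta_ref`` the dihedral angle of the built sphere (spontaneous
    curvature of the rest shape).
    """
    theta, grads = _dihedral_gradients(mesh.positions, mesh.hinges)
    dE = params.k_bend * np.sin(theta - mesh.ref_dihedrals)  # dE/dtheta
    out = np.zeros((mesh.n_nodes, 3))
    for k, g in enumerate(grads):
        scatter_add(out, mesh.hinges[:, k], -dE[:, None] * g)
    return out


def cortex_energies(mesh: CellMesh, params: ParamSet) -> dict[str, float]:
    """Discrete cortex energies [J] of the current configuration."""
    i, j = mesh.edges[:, 0], mesh.edges[:, 1]
    d = np.linalg.norm(mesh.positions[j] - mesh.positions[i], axis=1)
    e_spring = 0.5 * params.k_cortex * np.sum((d - mesh.rest_lengths) ** 2)

    areas = mesh.tri_normals_areas()[1]
    e_area_loc = 0.5 * params.k_area_loc * np.sum(
        (areas - mesh.ref_tri_areas) ** 2 / mesh.ref_tri_areas)
    e_area_glob = 0.5 * params.k_area_glob * (
        (areas.sum() - mesh.ref_total_area) ** 2 / mesh.ref_total_area)

    v = _signed_volume(mesh.positions, mesh.triangles)
    e_vol = 0.5 * params.k_vol * (v - mesh.ref_volume) ** 2 / mesh.ref_volume

    theta = dihedral_angles(mesh.positions, mesh.hinges)
    e_bend = params.k_bend * np.sum(1.0 - np.cos(theta - mesh.ref_dihedrals))

    return {
        "spring": float(e_spring),
        "area_local": float(e_area_loc),
        "area_global": float(e_area_glob),
        "volume": float(e_vol),
        "bend": float(e_bend),
        "total": float(e_spring + e_area_loc + e_area_glob + e_vol + e_bend),
    }
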