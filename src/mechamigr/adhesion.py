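"""Transient adhesive contact and discrete focal adhesions.

Two cell–substrate interactions coexist:

* a transient adhesive contact between cortex triangles and the plane,
  modeled as Maugis–Dugdale sphere-on-flat contact — a repulsive Hertzian
  core plus a constant-stress (Dugdale) adhesive annulus evaluated on the
  undeformed gap profile.  It holds the initialized cell on the plane and is
  calibrated to stay far below focal-adhesion forces;
* discrete focal adhesions (FAs): a stiff FA spring in series with a softer
  ligand spring anchored at a fixed substrate point.  FAs form
  stochastically on lamellum nodes, disassemble at a force-dependent
  (catch-like) rate, and rupture above a hard force threshold, after which
  the node is refractory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import CellMesh, SubstrateGrid, Region, fit_local_sphere
from .params import ParamSet, Condition, Setup

__all__ = [
    "FocalAdhesion",
    "FAEvent",
    "RefractoryState",
    "maugis_dugdale_contact",
    "contact_forces_plane",
    "hertz_force",
    "attempt_fa_formation",
    "fa_force",
    "fa_forces_array",
    "fa_disassembly_rate",
    "step_fa_population",
    "expected_lifetime",
]

# region tags for FAs
TAG_FRONT = Region.FRONT_LM
TAG_REAR = Region.REAR_LM
TAG_OUTSIDE = -1


@dataclass
class FocalAdhesion:
    """A discrete node–substrate bond with a fixed anchor point."""

    node_id: int
    anchor: np.ndarray                 # (3,) fixed substrate point [m]
    birth_time: float                  # [s]
    region_tag: int = TAG_FRONT        # refreshed each step
    force: np.ndarray = field(default_factory=lambda: np.zeros(3))  # [N]
    bound_sf: int = -1                 # fiber id or -1
    uid: int = -1                      # unique id, assigned by the engine

    @property
    def force_mag(self) -> float:
        return float(np.linalg.norm(self.force))


@dataclass
class FAEvent:
    time: float
    node_id: int
    kind: str          # "form" | "disassemble" | "rupture"
    force_mag: float
    region_tag: int


class RefractoryState:
    """Per-node countdown timers [s]; a node with time remaining cannot bind."""

    def __init__(self, n_nodes: int):
        self.timers = np.zeros(n_nodes)

    def is_refractory(self, node_id) -> bool:
        return bool(np.any(self.timers[node_id] > 0))

    def start(self, node_ids, duration: float) -> None:
        self.timers[node_ids] = duration

    def advance(self, dt: float) -> None:
        np.maximum(self.timers - dt, 0.0, out=self.timers)


# -- transient contact ---------------------------------------------------

def hertz_force(delta: float, R: float, E_eff: float) -> float:
    """Hertzian sphere-on-flat repulsion [N] at overlap ``delta`` (0 if separated)."""
    if delta <= 0:
        return 0.0
    return (4.0 / 3.0) * E_eff * math.sqrt(R) * delta**1.5


def _md_normal_force(gap, R, area_cap, params: ParamSet):
    """Vectorised signed normal force: positive pushes the cell up (+z).

    ``gap`` is the surface–plane separation (negative = overlap).  The
    adhesive annulus is the region of the undeformed parabolic gap profile
    where the separation is below ``h_contact``; its area is capped at the
    triangle's own area so a single triangle cannot claim more adhesive
    contact than it tiles.
    """
    gap = np.asarray(gap, dtype=float)
    delta = np.maximum(-gap, 0.0)
    f_rep = (4.0 / 3.0) * params.E_contact * np.sqrt(R) * delta**1.5

    h0 = params.h_contact
    sep = np.maximum(gap, 0.0)
    annulus = np.where(sep < h0, 2.0 * math.pi * R * (h0 - sep), 0.0)
    annulus = np.minimum(annulus, area_cap)
    f_adh = params.sigma0_contact * annulus
    return f_rep - f_adh


def maugis_dugdale_contact(
    cell_triangle: int,
    substrate_triangle: int,
    mesh: CellMesh,
    params: ParamSet,
    grid: SubstrateGrid | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Adhesive normal contact force between a cell triangle and the plane.

    The cell-side sphere is fit to the triangle's 1-ring (radius capped at
    ``R_contact_max``; a flat/degenerate fit falls back to the cap, the
    sphere-on-flat limit); the substrate sphere is flat (infinite radius), so
    the effective radius is the cell-side one.

    Returns
    -------
    (force_on_cell_triangle, force_on_substrate_triangle)
        Equal and opposite vectors [N].  Zero beyond the adhesive range.
    """
    try:
        R = fit_local_sphere(cell_triangle, mesh)
    except ValueError:
        raise
    if not math.isfinite(R):
        R = params.R_contact_max
    R = min(R, params.R_contact_max)
    centroid = mesh.tri_centroids()[cell_triangle]
    area = mesh.tri_normals_areas()[1][cell_triangle]
    fz = float(_md_normal_force(centroid[2], R, area, params))
    f_cell = np.array([0.0, 0.0, fz])
    return f_cell, -f_cell


def contact_forces_plane(
    mesh: CellMesh,
    radii: np.ndarray,
    params: ParamSet,
):
    """Vectorised transient contact of all cortex triangles with the plane.

    Parameters
    ----------
    radii
        Per-triangle fitted curvature radii (inf allowed); refreshed
        periodically by the engine since curvature evolves slowly.

    Returns
    -------
    (node_forces, tri_fz)
        Per-node forces (N, 3) and the per-triangle normal force carried, for
        substrate bookkeeping.
    """
    cent = mesh.tri_centroids()
    areas = mesh.tri_normals_areas()[1]
    gap = cent[:, 2]
    active = gap < params.h_contact
    node_forces = np.zeros((mesh.n_nodes, 3))
    tri_fz = np.zeros(mesh.n_triangles)
    if not active.any():
        return node_forces, tri_fz
    R = np.minimum(np.where(np.isfinite(radii[active]), radii[active],
                            params.R_contact_max), params.R_contact_max)
    fz = _md_normal_force(gap[active], R, areas[active], params)
    tri_fz[active] = fz
    share = fz / 3.0
    for k in range(3):
        np.add.at(node_forces[:, 2], mesh.triangles[active, k], share)

    # node-level repulsive core: the rigid plane repels every surface point,
    # not only triangle centroids; without this, contact-line nodes sink tens
    # of nm and spuriously pre-tension nm-scale FA springs.  A linear penalty
    # keeps the stiffness bounded (explicit-step stability).
    z = mesh.positions[:, 2]
    pen = np.maximum(-z, 0.0)
    node_forces[:, 2] += params.k_wall * pen
    return node_forces, tri_fz


# -- focal adhesions -----------------------------------------------------

def attempt_fa_formation(
    node_id: int,
    mesh: CellMesh,
    substrate: SubstrateGrid,
    refractory: RefractoryState,
    labels,
    params: ParamSet,
    rng: np.random.Generator,
    *,
    dt: float | None = None,
    adhered_nodes=frozenset(),
    clock: float = 0.0,
) -> FocalAdhesion | None:
    """One stochastic FA formation attempt for a lamellum node.

    Succeeds with probability ``1 - exp(-r_on_FA * dt)`` provided the node is
    in the lamellum, within ``bind_distance`` vertically of the plane, not
    refractory, and not already adhered.  The anchor is the closest point on
    the plane at formation and never moves.
    """
    if dt is None:
        dt = params.dt
    if node_id in adhered_nodes:
        return None
    if refractory.is_refractory(node_id):
        return None
    tag = node_region_tag(node_id, mesh, labels)
    if tag == TAG_OUTSIDE:
        return None
    pos = mesh.positions[node_id]
    if abs(pos[2]) > params.bind_distance:
        return None
    if rng.random() >= 1.0 - math.exp(-params.r_on_FA * dt):
        return None
    anchor = np.array([pos[0], pos[1], 0.0])
    return FocalAdhesion(node_id=node_id, anchor=anchor, birth_time=clock,
                         region_tag=tag)


def node_region_tag(node_id: int, mesh: CellMesh, labels) -> int:
    """FA region tag of a node: frontLm / rearLm if any incident triangle is
    in that lamellum, otherwise outside."""
    lab = labels.labels if hasattr(labels, "labels") else labels
    incident = np.flatnonzero((mesh.triangles == node_id).any(axis=1))
    tri_labels = lab[incident]
    if (tri_labels == Region.FRONT_LM).any():
        return TAG_FRONT
    if (tri_labels == Region.REAR_LM).any():
        return TAG_REAR
    return TAG_OUTSIDE


def fa_force(fa: FocalAdhesion, mesh: CellMesh, k_ECM: float, params: ParamSet) -> np.ndarray:
    """Two-spring tension on the cell node [N].

    Magnitude ``(1/k_FA + 1/k_ECM)^-1 * (L - (L_FA0 + L_ECM0))`` along the
    node-to-anchor axis when stretched beyond the combined rest length; zero
    otherwise (the bond carries no compression).
    """
    d = fa.anchor - mesh.positions[fa.node_id]
    L = np.linalg.norm(d)
    rest = params.L_FA0 + params.L_ECM0
    if L <= rest:
        return np.zeros(3)
    k_series = params.series_stiffness(k_ECM)
    return k_series * (L - rest) * d / L


def fa_forces_array(
    node_pos: np.ndarray,
    anchors: np.ndarray,
    k_ECM: float,
    params: ParamSet,
) -> np.ndarray:
    """Vectorised FA tensions for stacked node positions / anchors [(n,3)]."""
    d = anchors - node_pos
    L = np.linalg.norm(d, axis=1)
    rest = params.L_FA0 + params.L_ECM0
    k_series = params.series_stiffness(k_ECM)
    stretch = np.maximum(L - rest, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (k_series * stretch / np.where(L > 0, L, 1.0))[:, None] * d
    return out


def fa_disassembly_rate(
    fa: FocalAdhesion,
    setup: Setup,
    condition: Condition,
    params: ParamSet,
) -> float:
    """Force-dependent disassembly rate [1/s].

    ``r = beta * r_off_FA0 * exp(-zeta_FA |F|)`` with beta = beta_front in
    the front lamellum and beta_rear in the rear; FAs outside the lamellum
    have the rate multiplied by ``outside_Lm_factor``.  With FA maturation
    off the exponential factor is 1.
    """
    beta = params.beta_rear if fa.region_tag == TAG_REAR else params.beta_front
    rate = beta * condition.r_off_FA0
    if setup.FA_mat:
        rate *= math.exp(-params.zeta_FA * fa.force_mag)
    if fa.region_tag == TAG_OUTSIDE:
        rate *= params.outside_Lm_factor
    return rate


def disassembly_rates_array(
    force_mags: np.ndarray,
    region_tags: np.ndarray,
    setup: Setup,
    condition: Condition,
    params: ParamSet,
) -> np.ndarray:
    beta = np.where(region_tags == TAG_REAR, params.beta_rear, params.beta_front)
    rates = beta * condition.r_off_FA0
    if setup.FA_mat:
        rates = rates * np.exp(-params.zeta_FA * force_mags)
    rates = np.where(region_tags == TAG_OUTSIDE,
                     rates * params.outside_Lm_factor, rates)
    return rates


def step_fa_population(
    fas: list[FocalAdhesion],
    setup: Setup,
    condition: Condition,
    params: ParamSet,
    rng: np.random.Generator,
    clock: float,
    refractory: RefractoryState | None = None,
    dt: float | None = None,
):
    """Stochastic disassembly and forced rupture of the FA population.

    Each FA disassembles with probability ``1 - exp(-r dt)``; any FA whose
    carried force strictly exceeds ``F_rup`` is removed as a rupture and its
    node becomes refractory for ``lambda_ref``.  Disassembly and rupture are
    logged as distinct event kinds.

    Returns
    -------
    (survivors, events)
    """
    if dt is None:
        dt = params.dt
    survivors: list[FocalAdhesion] = []
    events: list[FAEvent] = []
    if not fas:
        return survivors, events
    fmags = np.array([fa.force_mag for fa in fas])
    tags = np.array([fa.region_tag for fa in fas])
    rates = disassembly_rates_array(fmags, tags, setup, condition, params)
    u = rng.random(len(fas))
    p_dis = 1.0 - np.exp(-rates * dt)
    for fa, fmag, pd, ui in zip(fas, fmags, p_dis, u):
        if fmag > params.F_rup:
            events.append(FAEvent(clock, fa.node_id, "rupture", float(fmag),
                                  fa.region_tag))
            if refractory is not None:
                refractory.start(fa.node_id, params.lambda_ref)
        elif ui < pd:
            events.append(FAEvent(clock, fa.node_id, "disassemble", float(fmag),
                                  fa.region_tag))
        else:
            survivors.append(fa)
    return survivors, events


def expected_lifetime(r_off0: float) -> float:
    """Expected zero-force FA lifetime [min] for a per-second disassembly rate.

    From the Poisson-process relation ``<lambda> = -1 / ln(1 - r)`` seconds.
    """
    if not (0.0 < r_off0 < 1.0):
        raise ValueError(f"rate must be in (0, 1) per second, got {r_off0!r}")
    return -1.0 / math.log(1.0 - r_off0) / 60.0
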