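"""Overdamped equation of motion, time stepping, initialization, and
collective-detachment events.

Each step solves ``M v = F`` for all node velocities, where ``F`` stacks the
explicit forces (cortex elasticity, transient contact, FA and SF tensions,
protrusion and its counter force) and ``M`` is the friction operator built
from cortex dashpots, substrate contact friction, and liquid drag.  Friction
is isotropic per node/pair, so the 3N x 3N system decouples into one SPD
N x N solve applied to three right-hand sides (the vector form of the
equation of motion sums ``Lambda_d (v_i - v_j)`` over edges plus diagonal
``Gamma`` terms).  Forces are explicit, friction implicit — a semi-implicit
scheme stable at dt = 0.05 s for the full stiffness range studied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from . import actin as _actin
from . import adhesion as _adh
from . import cortex as _cortex
from .adhesion import FAEvent, FocalAdhesion, RefractoryState
from .fibers import (StressFiber, form_stress_fibers, prune_stress_fibers,
                     sf_forces, update_stall_and_strengthen)
from .geometry import (CellMesh, Region, SubstrateGrid, build_cell_mesh,
                       build_substrate_grid, fit_local_sphere)
from .params import Condition, ParamSet, Setup

__all__ = [
    "SimState",
    "InstabilityError",
    "assemble_friction",
    "step",
    "initialize_cell",
    "detect_full_retraction",
    "run_simulation",
]

#: A node moving farther than this in one step signals numerical instability.
MAX_STEP_DISPLACEMENT = 0.5e-6

#: Curvature radii for contact are refreshed on this step stride (curvature
#: evolves on much slower time scales than dt).
CURVATURE_REFRESH = 200


class InstabilityError(RuntimeError):
    pass


@dataclass
class SimState:
    """Complete simulation state (composition of all model state)."""

    clock: float
    mesh: CellMesh
    substrate: SubstrateGrid
    field: _actin.ActinField
    labels: _actin.RegionLabels
    fas: list[FocalAdhesion]
    refractory: RefractoryState
    sfs: list[StressFiber]
    rng: np.random.Generator
    events: list[FAEvent] = field(default_factory=list)
    retraction_times: list[float] = field(default_factory=list)
    rupture_window_times: list[float] = field(default_factory=list)
    cum_ruptures: int = 0
    cum_disassemblies: int = 0
    fa_uid_counter: int = 0
    metrics_rows: list[dict] = field(default_factory=list)
    _prev_com_x: float | None = None
    cum_displacement: float = 0.0
    # caches
    _radii: np.ndarray | None = None
    _step_count: int = 0
    _cho_cache: tuple | None = None


def assemble_friction(state: SimState, params: ParamSet) -> np.ndarray:
    """Symmetric positive-definite friction operator (N x N, [N s/m]).

    Diagonal ``Gamma_liquid`` on every node plus ``Gamma_subs`` on nodes in
    substrate contact (within the adhesive range or holding an FA); cortex
    dashpots contribute ``Lambda_d`` in graph-Laplacian structure over the
    mesh edges.  Applied identically to each velocity component.
    """
    mesh = state.mesh
    n = mesh.n_nodes
    M = np.zeros((n, n))
    if len(mesh.edges):
        i, j = mesh.edges[:, 0], mesh.edges[:, 1]
        np.add.at(M, (i, i), params.Lambda_d)
        np.add.at(M, (j, j), params.Lambda_d)
        np.add.at(M, (i, j), -params.Lambda_d)
        np.add.at(M, (j, i), -params.Lambda_d)
    diag = np.full(n, params.Gamma_liquid)
    contact = mesh.positions[:, 2] <= params.h_contact
    for fa in state.fas:
        contact[fa.node_id] = True
    diag[contact] += params.Gamma_subs
    M[np.diag_indices(n)] += diag
    if not np.all(np.isfinite(M)):
        raise ValueError("non-finite friction assembly")
    return M


def _compute_forces(
    state: SimState,
    setup: Setup,
    condition: Condition,
    params: ParamSet,
    include_activity: bool = True,
) -> _cortex.ForceAccumulator:
    """All explicit force categories of the current configuration."""
    mesh = state.mesh
    acc = _cortex.ForceAccumulator(mesh.n_nodes)

    ve = _cortex.edge_viscoelastic_forces(mesh, params)
    acc.add("linear", ve["linear"])
    acc.add("area", _cortex.area_conservation_forces(mesh, params))
    acc.add("volume", _cortex.volume_conservation_force(mesh, params))
    acc.add("bend", _cortex.bending_forces(mesh, params))

    # transient contact, with slowly refreshed curvature radii
    if state._radii is None or state._step_count % CURVATURE_REFRESH == 0:
        state._radii = _contact_radii(mesh, params)
    contact_nodes, _tri_fz = _adh.contact_forces_plane(mesh, state._radii, params)
    acc.add("contact", contact_nodes)

    if include_activity:
        # focal adhesions
        if state.fas:
            nodes = np.array([fa.node_id for fa in state.fas])
            anchors = np.array([fa.anchor for fa in state.fas])
            forces = _adh.fa_forces_array(mesh.positions[nodes], anchors,
                                          condition.k_ECM, params)
            fa_acc = acc["fa"]
            np.add.at(fa_acc, nodes, forces)
            for fa, f in zip(state.fas, forces):
                fa.force = f
        # stress fibers
        if state.sfs:
            sf_acc = acc["sf"]
            for sf in state.sfs:
                fi, fj = sf_forces(sf, mesh, params)
                sf_acc[sf.node_i] += fi
                sf_acc[sf.node_j] += fj
        # protrusion + counter
        prot_tri = _actin.protrusion_forces(state.field, state.labels, mesh, params)
        prot_nodes = acc["protrusion"]
        share = prot_tri / 3.0
        for k in range(3):
            np.add.at(prot_nodes, mesh.triangles[:, k], share)
        acc.add("counter", _actin.counter_force(prot_tri, mesh))
    return acc


def _contact_radii(mesh: CellMesh, params: ParamSet) -> np.ndarray:
    """Fitted-sphere radii for triangles near the plane; inf elsewhere."""
    radii = np.full(mesh.n_triangles, np.inf)
    near = np.flatnonzero(mesh.tri_centroids()[:, 2] < 4.0 * params.h_contact)
    for t in near:
        try:
            radii[t] = fit_local_sphere(int(t), mesh)
        except ValueError:
            radii[t] = params.R_contact_max
    return radii


def detect_full_retraction(rupture_times, clock: float, params: ParamSet) -> bool:
    """True when at least ``n_thr`` ruptures fall in the trailing window.

    ``rupture_times`` is the list of rupture timestamps since the last event
    (the engine clears it when an event fires, so one cascade is never
    counted twice).
    """
    recent = [t for t in rupture_times if t > clock - params.rupture_window]
    return len(recent) >= params.n_thr


def _lm_nodes(mesh: CellMesh) -> np.ndarray:
    lm_tri = (mesh.region == Region.FRONT_LM) | (mesh.region == Region.REAR_LM)
    return np.unique(mesh.triangles[lm_tri])


def _node_region_tags(mesh: CellMesh) -> np.ndarray:
    """Per-node FA region tag (front/rear lamellum membership, else outside)."""
    front = np.zeros(mesh.n_nodes, dtype=bool)
    rear = np.zeros(mesh.n_nodes, dtype=bool)
    front[mesh.triangles[mesh.region == Region.FRONT_LM]] = True
    rear[mesh.triangles[mesh.region == Region.REAR_LM]] = True
    tags = np.full(mesh.n_nodes, _adh.TAG_OUTSIDE, dtype=np.int64)
    tags[rear] = _adh.TAG_REAR
    tags[front] = _adh.TAG_FRONT
    return tags


def step(
    state: SimState,
    setup: Setup,
    condition: Condition,
    params: ParamSet,
    include_activity: bool = True,
) -> SimState:
    """Advance the coupled system by one time step ``params.dt``.

    Order of operations: explicit forces; implicit friction solve for
    velocities; position update; then the sub-updates in fixed order —
    interface/actin/regions, FA stochastic disassembly and forced rupture,
    full-retraction detection, SF stall/strengthen and pruning, SF
    formation, FA formation.
    """
    mesh = state.mesh
    dt = params.dt
    acc = _compute_forces(state, setup, condition, params, include_activity)
    F = acc.total()

    # the friction operator only changes when the contact/FA node set does;
    # cache its Cholesky factor on that key
    contact = mesh.positions[:, 2] <= params.h_contact
    for fa in state.fas:
        contact[fa.node_id] = True
    key = contact.tobytes()
    if state._cho_cache is None or state._cho_cache[0] != key:
        M = assemble_friction(state, params)
        try:
            cho = scipy.linalg.cho_factor(M, check_finite=False)
        except scipy.linalg.LinAlgError as exc:
            raise InstabilityError(f"friction solve failed: {exc}") from exc
        state._cho_cache = (key, cho)
    v = scipy.linalg.cho_solve(state._cho_cache[1], F, check_finite=False)

    disp = np.linalg.norm(v, axis=1) * dt
    if disp.max() > MAX_STEP_DISPLACEMENT:
        raise InstabilityError(
            f"node displacement {disp.max():.3g} m in one step exceeds "
            f"{MAX_STEP_DISPLACEMENT:.3g} m; reduce dt or stiffness")
    mesh.velocities[:] = v
    mesh.positions += v * dt
    state.clock += dt
    state._step_count += 1

    # ---- field / region updates ----
    _actin.update_interface_flags(mesh, params)
    if not include_activity:
        # spreading phase: the actin field is solved to steady state at the
        # end of initialization, so transient updates are skipped here
        return state
    sources = _actin.identify_periphery(mesh) if mesh.interface_node.any() else \
        np.empty(0, dtype=np.int64)
    state.field = _actin.step_actin_field(state.field, mesh, sources, dt,
                                          params, weights=_actin.diffusion_weights(mesh))
    if mesh.interface_node.any():
        state.labels = _actin.demarcate_regions(state.field, mesh, params)

    # refresh FA region tags
    tags = _node_region_tags(mesh)
    for fa in state.fas:
        fa.region_tag = int(tags[fa.node_id])

    state.refractory.advance(dt)

    # ---- FA stochastic events ----
    survivors, events = _adh.step_fa_population(
        state.fas, setup, condition, params, state.rng, state.clock,
        refractory=state.refractory, dt=dt)
    for ev in events:
        if ev.kind == "rupture":
            state.cum_ruptures += 1
            state.rupture_window_times.append(ev.time)
        elif ev.kind == "disassemble":
            state.cum_disassemblies += 1
    state.events.extend(events)
    state.fas = survivors

    # ---- full retraction ----
    state.rupture_window_times = [
        t for t in state.rupture_window_times
        if t > state.clock - params.rupture_window]
    if detect_full_retraction(state.rupture_window_times, state.clock, params):
        state.retraction_times.append(state.clock)
        state.events.append(FAEvent(state.clock, -1, "full_retraction", 0.0, 0))
        state.fas = []
        state.sfs = []
        state.refractory.start(_lm_nodes(mesh), params.lambda_ref)
        state.rupture_window_times = []

    # ---- stress fibers: stall/strengthen, prune, form ----
    for sf in state.sfs:
        update_stall_and_strengthen(sf, setup, state.clock, params, mesh=mesh)
    state.sfs = prune_stress_fibers(state.sfs, state.fas)
    state.sfs.extend(form_stress_fibers(state.fas, state.sfs, params,
                                        state.rng, mesh, clock=state.clock, dt=dt))

    # ---- FA formation ----
    adhered = np.zeros(mesh.n_nodes, dtype=bool)
    for fa in state.fas:
        adhered[fa.node_id] = True
    eligible = np.flatnonzero(
        (tags != _adh.TAG_OUTSIDE)
        & (np.abs(mesh.positions[:, 2]) <= params.bind_distance)
        & (state.refractory.timers <= 0)
        & ~adhered)
    if len(eligible):
        p_on = 1.0 - math.exp(-params.r_on_FA * dt)
        hits = eligible[state.rng.random(len(eligible)) < p_on]
        for node in hits:
            pos = mesh.positions[node]
            state.fa_uid_counter += 1
            state.fas.append(FocalAdhesion(
                node_id=int(node),
                anchor=np.array([pos[0], pos[1], 0.0]),
                birth_time=state.clock,
                region_tag=int(tags[node]),
                uid=state.fa_uid_counter))
            state.events.append(FAEvent(state.clock, int(node), "form", 0.0,
                                        int(tags[node])))
    return state


def initialize_cell(
    params: ParamSet,
    condition: Condition,
    subdivision: int = 2,
    substrate: SubstrateGrid | None = None,
    seed: int = 0,
) -> SimState:
    """Attach-and-spread initialization: contact + cortex forces only.

    The cell is placed tangent to the plane (with a slight overlap inside the
    adhesive range) and advanced without FAs, SFs, protrusion or
    mechanosensing until the cell–substrate interface area changes by less
    than 1% per minute, up to ``init_duration``.  The actin field is then set
    to its exact steady state and the regions demarcated.  The procedure is
    deterministic and identical for all conditions.
    """
    mesh = build_cell_mesh(radius=params.R_c, subdivision=subdivision)
    mesh.positions[:, 2] += params.R_c + 0.25 * params.h_contact
    if substrate is None:
        substrate = build_substrate_grid()
    state = SimState(
        clock=0.0, mesh=mesh, substrate=substrate,
        field=_actin.ActinField(G=np.zeros(mesh.n_triangles)),
        labels=_actin.RegionLabels(labels=mesh.region.copy()),
        fas=[], refractory=RefractoryState(mesh.n_nodes), sfs=[],
        rng=np.random.default_rng(seed),
    )
    setup = Setup(FA_mat=False, SF_str=False)
    check_every = int(round(60.0 / params.dt))
    min_steps = 5 * check_every  # let the contact line develop before testing
    n_steps = int(round(params.init_duration / params.dt))
    prev_area = None
    for k in range(n_steps):
        step(state, setup, condition, params, include_activity=False)
        if (k + 1) % check_every == 0:
            _actin.update_interface_flags(mesh, params)
            area = float(mesh.tri_normals_areas()[1][
                mesh.interface_node[mesh.triangles].all(axis=1)].sum())
            if (k + 1) >= min_steps and prev_area is not None and \
                    prev_area > 0 and abs(area - prev_area) / prev_area < 0.01:
                break
            prev_area = area

    _actin.update_interface_flags(mesh, params)
    if not mesh.interface_node.any():
        raise RuntimeError("cell failed to attach to the substrate plane")
    sources = _actin.identify_periphery(mesh)
    state.field = _actin.steady_state_actin(mesh, sources, params)
    state.labels = _actin.demarcate_regions(state.field, mesh, params)
    state.clock = 0.0
    state._step_count = 0
    mesh.velocities[:] = 0.0
    return state


def run_simulation(
    condition: Condition,
    setup: Setup,
    duration: float,
    seed: int,
    params: ParamSet | None = None,
    subdivision: int = 2,
    save_interval: float = 60.0,
    stop_on_retraction: bool = False,
):
    """Initialize and run a migration simulation.

    Parameters
    ----------
    duration
        Simulated time after initialization [s]; 0 returns the initialized
        state with an empty log.
    stop_on_retraction
        Stop early after the first full-retraction event (used by screening
        runs that only need the event).

    Returns
    -------
    (metrics, state) — a :class:`pandas.DataFrame` metrics log and the final
    state.  Fully reproducible from ``(condition, setup, seed)``.
    """
    from .analysis import append_metrics, metrics_frame

    if params is None:
        from .params import load_params
        params = load_params()
    state = initialize_cell(params, condition, subdivision=subdivision)
    state.rng = np.random.default_rng(seed)
    n_steps = int(round(duration / params.dt))
    save_every = max(1, int(round(save_interval / params.dt)))
    for k in range(n_steps):
        step(state, setup, condition, params)
        if (k + 1) % save_every == 0:
            append_metrics(state, condition, params)
        if stop_on_retraction and state.retraction_times:
            append_metrics(state, condition, params)
            break
    return metrics_frame(state), state
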