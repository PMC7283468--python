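"""Stress-fiber lifecycle: formation, contraction, stalling-driven
strengthening, logistic weakening with shortening, and pruning.

A stress fiber (SF) is a pair of equal and opposite forces pulling two
FA-bearing cortex nodes together with magnitude ``n_str * F_am * phi``:
``n_str`` steps up by one (to a cap) each time the fiber's 10 s
moving-average length stalls, and ``phi`` is a logistic factor that collapses
once the fiber has shortened by about dL50, releasing the front node.

:func:`reduced_two_spring_experiment` reproduces the idealized single-node
system (FA + ligand spring pulled by one SF, no cortex) whose force-vs-time
trace is a staircase with ~F_am steps; stiffer ligands stall — and therefore
strengthen — sooner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import CellMesh
from .params import ParamSet, Setup

__all__ = [
    "StressFiber",
    "form_stress_fibers",
    "sf_weakening_phi",
    "sf_forces",
    "update_stall_and_strengthen",
    "prune_stress_fibers",
    "reduced_two_spring_experiment",
    "TwoSpringTrace",
]


@dataclass
class StressFiber:
    """Contractile force pair between two cortex nodes."""

    node_i: int
    node_j: int
    L_fib0: float                   # length at formation [m]
    birth_time: float               # [s]
    n_str: int = 1
    fa_i_uid: int = -1              # uid of the FA bound at each endpoint
    fa_j_uid: int = -1
    fa_i_alive: bool = True
    fa_j_alive: bool = True
    rear_detach_time: float | None = None
    # moving-average state
    _ma_sum: float = 0.0
    _ma_count: int = 0
    last_avg: float | None = None
    stall_times: list = field(default_factory=list)

    def current_length(self, mesh: CellMesh) -> float:
        return float(np.linalg.norm(
            mesh.positions[self.node_j] - mesh.positions[self.node_i]))

    def phi(self, L_fib: float, params: ParamSet) -> float:
        return sf_weakening_phi(L_fib - self.L_fib0, params)


def sf_weakening_phi(dL: float, params: ParamSet):
    """Logistic weakening factor phi = 1 / (1 + exp(-mu (dL + dL50))).

    phi ~ 1 for small shortening, exactly 1/2 at dL = -dL50, and -> 0 with
    further contraction.
    """
    return 1.0 / (1.0 + np.exp(-params.mu * (np.asarray(dL, dtype=float) + params.dL50)))


def form_stress_fibers(
    fas,
    existing_sfs: list[StressFiber],
    params: ParamSet,
    rng: np.random.Generator,
    mesh: CellMesh,
    clock: float = 0.0,
    dt: float | None = None,
) -> list[StressFiber]:
    """Stochastically pair unbound FAs into new stress fibers.

    Each step, every SF-unbound FA attempts pairing with probability
    ``1 - exp(-sf_pair_rate * dt)``; an attempting FA picks a partner
    uniformly at random among the other still-unbound FAs whose node lies at
    least ``L_fib_min0`` away (fibers only span front-to-rear distances).
    Fibers start with ``n_str = 1`` and ``phi = 1`` (force ``F_am``).
    """
    if dt is None:
        dt = params.dt
    unbound = [fa for fa in fas if fa.bound_sf < 0]
    if len(unbound) < 2:
        return []
    p = 1.0 - math.exp(-params.sf_pair_rate * dt)
    attempts = np.flatnonzero(rng.random(len(unbound)) < p)
    if len(attempts) == 0:
        return []
    new: list[StressFiber] = []
    next_id = len(existing_sfs)
    for a_idx in attempts:
        fa_a = unbound[a_idx]
        if fa_a.bound_sf >= 0:
            continue
        # candidate partners: any other still-unbound FA far enough away
        partners = [fa for fa in unbound
                    if fa is not fa_a and fa.bound_sf < 0]
        if not partners:
            continue
        dists = np.linalg.norm(
            np.array([mesh.positions[fa.node_id] for fa in partners])
            - mesh.positions[fa_a.node_id], axis=1)
        ok = np.flatnonzero(dists >= params.L_fib_min0)
        if len(ok) == 0:
            continue
        pick = int(ok[rng.integers(len(ok))])
        fa_b = partners[pick]
        L = float(dists[pick])
        sf = StressFiber(node_i=fa_a.node_id, node_j=fa_b.node_id,
                         L_fib0=L, birth_time=clock,
                         fa_i_uid=fa_a.uid, fa_j_uid=fa_b.uid)
        fa_a.bound_sf = next_id
        fa_b.bound_sf = next_id
        next_id += 1
        new.append(sf)
    return new


def sf_forces(sf: StressFiber, mesh: CellMesh, params: ParamSet):
    """Equal/opposite contractile force pair [(3,), (3,)] on (node_i, node_j)."""
    d = mesh.positions[sf.node_j] - mesh.positions[sf.node_i]
    L = np.linalg.norm(d)
    if L == 0:
        import warnings
        warnings.warn("stress fiber with coincident endpoints exerts no force",
                      stacklevel=2)
        return np.zeros(3), np.zeros(3)
    mag = sf.n_str * params.F_am * sf.phi(L, params)
    f_i = mag * d / L          # pulls i toward j
    return f_i, -f_i


def update_stall_and_strengthen(
    sf: StressFiber,
    setup: Setup,
    clock: float,
    params: ParamSet,
    L_fib: float | None = None,
    mesh: CellMesh | None = None,
) -> StressFiber:
    """Feed one length sample into the 10 s moving-average stall detector.

    Every full window the filtered length is compared with the previous one;
    a difference below ``L_thr`` in magnitude is a stall.  With SF
    strengthening on, a stall increments ``n_str`` up to the cap; with it
    off, stalls are still detected (logged in ``stall_times``) but the force
    level never rises.
    """
    if L_fib is None:
        L_fib = sf.current_length(mesh)
    window_steps = int(round(params.ma_window / params.dt))
    sf._ma_sum += L_fib
    sf._ma_count += 1
    if sf._ma_count >= window_steps:
        avg = sf._ma_sum / sf._ma_count
        if sf.last_avg is not None and abs(avg - sf.last_avg) < params.L_thr:
            sf.stall_times.append(clock)
            if setup.SF_str:
                sf.n_str = min(sf.n_str + 1, params.n_str_max)
        sf.last_avg = avg
        sf._ma_sum = 0.0
        sf._ma_count = 0
    return sf


def prune_stress_fibers(sfs: list[StressFiber], fas) -> list[StressFiber]:
    """Drop fibers whose FA died at *both* endpoints.

    A fiber keeps pulling both nodes while at least one of the two FAs it
    formed between survives.  The fiber stays bound to its cortex nodes: a
    later FA at the same node is a different bond and may seed a second
    fiber, so forces from successive fibers can stack on one node.
    """
    live_uids = {fa.uid for fa in fas}
    survivors = []
    for sf in sfs:
        sf.fa_i_alive = sf.fa_i_uid in live_uids
        sf.fa_j_alive = sf.fa_j_uid in live_uids
        if sf.fa_i_alive or sf.fa_j_alive:
            survivors.append(sf)
    return survivors


@dataclass
class TwoSpringTrace:
    """Result of the isolated two-spring strengthening experiment."""

    times: np.ndarray          # [s]
    F_ECM: np.ndarray          # ligand-spring force magnitude [N]
    n_str: np.ndarray          # strengthening factor trace
    stall_times: np.ndarray    # [s]

    @property
    def final_n_str(self) -> int:
        return int(self.n_str[-1])

    @property
    def first_stall(self) -> float:
        return float(self.stall_times[0]) if len(self.stall_times) else math.inf


def reduced_two_spring_experiment(
    k_ECM: float,
    duration: float,
    params: ParamSet,
    setup: Setup = Setup(FA_mat=True, SF_str=True),
    sample_every: int = 20,
) -> TwoSpringTrace:
    """Simulate one node bound to the plane by the FA + ligand springs and
    pulled by a single stress fiber, without a cortex.

    Overdamped scalar dynamics: ``gamma dx/dt = F_SF - k_series x`` with
    ``gamma = Gamma_subs + Gamma_liquid``; the fiber shortens by exactly the
    node displacement, so ``dL_fib = -x`` drives the logistic weakening.
    Stall detection and strengthening run exactly as in the full model.

    Returns the stepwise ligand-spring force trace and the stall times: a
    non-decreasing staircase with ~F_am steps, plateauing at
    ``n_str_max * F_am`` (stiffness permitting), reached sooner the stiffer
    the ligand.
    """
    if k_ECM <= 0:
        raise ValueError("k_ECM must be positive")
    dt = params.dt
    gamma = params.Gamma_subs + params.Gamma_liquid
    k_series = params.series_stiffness(k_ECM)
    n_steps = int(round(duration / dt))
    window_steps = int(round(params.ma_window / dt))

    x = 0.0
    n_str = 1
    ma_sum = 0.0
    ma_count = 0
    last_avg = None
    stalls: list[float] = []
    times = np.empty(n_steps // sample_every + 1)
    f_trace = np.empty_like(times)
    n_trace = np.empty_like(times)
    k_out = 0
    for step in range(n_steps):
        t = step * dt
        phi = float(sf_weakening_phi(-x, params))
        f_sf = n_str * params.F_am * phi
        f_ecm = k_series * x
        x += dt * (f_sf - f_ecm) / gamma

        ma_sum += -x          # fiber length up to a constant; differences matter
        ma_count += 1
        if ma_count >= window_steps:
            avg = ma_sum / ma_count
            if last_avg is not None and abs(avg - last_avg) < params.L_thr:
                stalls.append(t)
                if setup.SF_str:
                    n_str = min(n_str + 1, params.n_str_max)
            last_avg = avg
            ma_sum = 0.0
            ma_count = 0

        if step % sample_every == 0:
            times[k_out] = t
            f_trace[k_out] = k_series * x
            n_trace[k_out] = n_str
            k_out += 1
    return TwoSpringTrace(times=times[:k_out], F_ECM=f_trace[:k_out],
                          n_str=n_trace[:k_out], stall_times=np.array(stalls))
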