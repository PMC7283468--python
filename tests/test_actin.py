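"""Actin field dynamics, region demarcation, and polarization forces."""

import math

import numpy as np
import pytest

from mechamigr import actin as A
from mechamigr.geometry import CellMesh, Region, build_cell_mesh
from mechamigr.params import load_params


@pytest.fixture()
def field20(ico1):
    """Small closed mesh (80 triangles) with a zero field."""
    return A.ActinField(G=np.zeros(ico1.n_triangles))


def _flat_strip(n_cells: int, h: float):
    """Open triangulated strip in the xy-plane, n_cells squares of side h.

    Returns a minimal CellMesh-like object good enough for the actin
    operators (positions, triangles, tri_neighbors); boundary neighbors wrap
    onto themselves (zero-flux).
    """
    # 2 rows of nodes, n_cells+1 columns
    nx = n_cells + 1
    pos = []
    for j in range(2):
        for i in range(nx):
            pos.append((i * h, j * h, 0.0))
    pos = np.array(pos)
    tris = []
    for i in range(n_cells):
        a, b = i, i + 1
        c, d = nx + i, nx + i + 1
        tris.append((a, b, d))
        tris.append((a, d, c))
    tris = np.array(tris, dtype=np.int64)

    t = len(tris)
    nb = np.empty((t, 3), dtype=np.int64)
    edge_map = {}
    for ti, tri in enumerate(tris):
        for k in range(3):
            e = tuple(sorted((tri[(k + 1) % 3], tri[(k + 2) % 3])))
            edge_map.setdefault(e, []).append((ti, k))
    for e, lst in edge_map.items():
        if len(lst) == 2:
            (t1, k1), (t2, k2) = lst
            nb[t1, k1] = t2
            nb[t2, k2] = t1
        else:
            (t1, k1), = lst
            nb[t1, k1] = t1  # boundary: self (zero flux)
    mesh = CellMesh.__new__(CellMesh)
    mesh.positions = pos
    mesh.velocities = np.zeros_like(pos)
    mesh.triangles = tris
    mesh.tri_neighbors = nb
    mesh.edges = np.empty((0, 2), dtype=np.int64)
    mesh.region = np.zeros(t, dtype=np.int8)
    mesh.interface_node = np.ones(len(pos), dtype=bool)
    return mesh


class TestStepActinField:
    def test_pure_decay_closed_form(self, ico1, field20, params):
        """With no diffusion and no source, G(t) = exp(-k_deg t)."""
        p = load_params(D_actin=1e-30)  # diffusion off
        field = A.ActinField(G=np.ones(ico1.n_triangles))
        t_target = 1.0 / p.k_deg  # 62.5 s
        n = int(round(t_target / p.dt))
        for _ in range(n):
            field = A.step_actin_field(field, ico1, np.empty(0, np.int64),
                                       p.dt, p)
        assert field.G[0] == pytest.approx(math.exp(-1.0), rel=2e-3)

    def test_source_sink_steady_state(self, ico1, params):
        """A source triangle with no diffusion approaches G* = k_gen/k_deg."""
        p = load_params(D_actin=1e-30)
        field = A.ActinField(G=np.zeros(ico1.n_triangles))
        src = np.array([0])
        for _ in range(2000):
            field = A.step_actin_field(field, ico1, src, 0.5, p)
        assert field.G[0] == pytest.approx(p.G_star, rel=1e-3)
        assert field.G[1:].max() < 1e-9 * p.G_star

    def test_positivity_preserved(self, ico1, params):
        rng = np.random.default_rng(0)
        field = A.ActinField(G=rng.uniform(0, 2 * params.G_star,
                                           ico1.n_triangles))
        for _ in range(200):
            field = A.step_actin_field(field, ico1, np.array([3, 7]),
                                       params.dt, params)
        assert field.G.min() >= 0.0

    def test_oversized_step_rejected_without_subcycling(self, ico1, params):
        field = A.ActinField(G=np.zeros(ico1.n_triangles))
        bound = A.stability_limit(ico1, params)
        with pytest.raises(A.StabilityError):
            A.step_actin_field(field, ico1, np.array([0]), 10 * bound,
                               params, subcycle=False)

    def test_matches_dense_graph_laplacian_oracle(self, params):
        """The vectorised update equals an independent dense-matrix
        integrator on a small fixture to near machine precision."""
        mesh = _flat_strip(10, 1e-6)
        T = len(mesh.triangles)
        rng = np.random.default_rng(5)
        g0 = rng.uniform(0, 1e12, T)
        src = np.array([0, 1])

        # dense oracle built by explicit loops
        areas, nb, w = A.diffusion_weights(mesh)
        L = np.zeros((T, T))
        for i in range(T):
            for k in range(3):
                j = nb[i, k]
                L[i, j] += w[i, k]
                L[i, i] -= w[i, k]
        s_vec = np.zeros(T)
        s_vec[src] = params.k_gen
        dt = 0.02
        g_dense = g0.copy()
        for _ in range(500):
            g_dense = g_dense + dt * (s_vec - params.k_deg * g_dense
                                      + params.D_actin / areas * (L @ g_dense))

        field = A.ActinField(G=g0.copy())
        for _ in range(500):
            field = A.step_actin_field(field, mesh, src, dt, params,
                                       subcycle=False)
        rel = np.abs(field.G - g_dense).max() / np.abs(g_dense).max()
        assert rel < 1e-8

    def test_steady_state_decay_length_on_flat_strip(self, params):
        """Steady-state G decays from a source edge with length scale
        sqrt(D/k_deg) (~2.24 um), within 10% of the 1D closed form."""
        h = 0.5e-6
        n = 60
        mesh = _flat_strip(n, h)
        src = np.array([0, 1])  # one end of the strip
        field = A.steady_state_actin(mesh, src, params)
        cent = mesh.tri_centroids()[:, 0]
        # fit exponential over an interior window away from both boundaries
        sel = (cent > 3e-6) & (cent < 20e-6) & (field.G > 0)
        slope = np.polyfit(cent[sel], np.log(field.G[sel]), 1)[0]
        ell = -1.0 / slope
        assert ell == pytest.approx(math.sqrt(params.D_actin / params.k_deg),
                                    rel=0.10)


class TestRegions:
    def test_periphery_is_closed_ring_on_spread_cell(self, spread_state):
        mesh = spread_state.mesh
        ring = A.identify_periphery(mesh)
        assert len(ring) > 0
        iface = mesh.interface_node[mesh.triangles].all(axis=1)
        for t in ring:
            assert iface[t]
            assert not iface[mesh.tri_neighbors[t]].all()

    def test_detached_cell_has_empty_periphery(self, ico2):
        ico2.interface_node[:] = False
        with pytest.warns(UserWarning):
            ring = A.identify_periphery(ico2)
        assert len(ring) == 0

    def test_demarcation_band_structure(self, spread_state, params):
        labels = spread_state.labels.labels
        mesh = spread_state.mesh
        iface = mesh.interface_node[mesh.triangles].all(axis=1)
        # Lp / Lm only on the interface; top only off it
        for code in (Region.LP, Region.FRONT_LM, Region.REAR_LM, Region.BODY):
            assert iface[labels == code].all()
        assert (~iface[labels == Region.TOP]).all()
        # Lp restricted to the front
        front = A.split_front_rear(mesh)
        assert front[labels == Region.LP].all()
        assert (labels == Region.LP).sum() > 0
        assert (labels == Region.FRONT_LM).sum() > 0
        assert (labels == Region.REAR_LM).sum() > 0

    def test_infinite_lp_threshold_leaves_only_lm(self, spread_state):
        p = load_params(theta_Lp=1e9, theta_Lm=0.09)
        labels = A.demarcate_regions(spread_state.field, spread_state.mesh, p)
        assert not labels.mask(Region.LP).any()
        assert labels.mask(Region.FRONT_LM).any()

    def test_inverted_thresholds_rejected(self, spread_state):
        from mechamigr.params import ParamValidationError
        with pytest.raises(ParamValidationError):
            load_params(theta_Lp=0.1, theta_Lm=0.2)

    def test_front_rear_split_symmetric_and_invariant(self, ico2):
        ico2.interface_node[:] = True
        front = A.split_front_rear(ico2)
        # near-balanced halves (ties on the split plane go to the front)
        assert abs(int(front.sum()) - int((~front).sum())) <= 0.1 * len(front)
        cent_x = ico2.tri_centroids()[:, 0]
        assert front[np.abs(cent_x) < 1e-12].all()  # tie -> front
        # translation invariance, on a tie-free configuration (exact ties are
        # sensitive to floating-point rounding of the centre of mass)
        rng = np.random.default_rng(0)
        ico2.positions[:, 0] += rng.normal(scale=1e-8, size=ico2.n_nodes)
        before = A.split_front_rear(ico2)
        ico2.positions[:, 0] += 5e-6
        assert np.array_equal(before, A.split_front_rear(ico2))

    def test_all_same_x_ties_break_to_front(self, ico2):
        ico2.interface_node[:] = True
        ico2.positions[:, 0] = 1.0e-6
        assert A.split_front_rear(ico2).all()


class TestPolarizationForces:
    def test_uniform_field_gives_zero_protrusion(self, spread_state, params):
        field = A.ActinField(G=np.full(spread_state.mesh.n_triangles,
                                       params.G_star))
        f = A.protrusion_forces(field, spread_state.labels,
                                spread_state.mesh, params)
        assert np.abs(f).max() == 0.0

    def test_protrusion_acts_only_on_lp(self, spread_state, params):
        f = A.protrusion_forces(spread_state.field, spread_state.labels,
                                spread_state.mesh, params)
        lp = spread_state.labels.mask(Region.LP)
        assert np.abs(f[~lp]).max() == 0.0
        assert np.linalg.norm(f[lp], axis=1).min() > 0.0
        # forces lie in the substrate-tangent plane
        assert np.abs(f[:, 2]).max() == 0.0

    def test_counter_force_balances_protrusion_exactly(self, spread_state,
                                                       params):
        f = A.protrusion_forces(spread_state.field, spread_state.labels,
                                spread_state.mesh, params)
        cnt = A.counter_force(f, spread_state.mesh)
        total = f.sum(axis=0) + cnt.sum(axis=0)
        assert np.abs(total).max() < 1e-24
        # every node receives the same counter share
        assert np.abs(cnt - cnt[0]).max() == 0.0

    def test_counter_force_division(self, ico2):
        prot = np.zeros((ico2.n_triangles, 3))
        prot[0] = [1e-9, 0.0, 0.0]
        cnt = A.counter_force(prot, ico2)
        assert cnt[0, 0] == pytest.approx(-1e-9 / 162)

    def test_no_lp_gives_zero_everywhere(self, ico2, params):
        labels = A.RegionLabels(labels=np.full(ico2.n_triangles, Region.TOP,
                                               dtype=np.int8))
        field = A.ActinField(G=np.ones(ico2.n_triangles))
        f = A.protrusion_forces(field, labels, ico2, params)
        assert np.abs(f).max() == 0.0
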