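"""Transient contact and focal-adhesion kinetics."""

import math

import numpy as np
import pytest

from mechamigr import adhesion as adh
from mechamigr.adhesion import (
    FocalAdhesion,
    RefractoryState,
    attempt_fa_formation,
    expected_lifetime,
    fa_disassembly_rate,
    fa_force,
    fa_forces_array,
    maugis_dugdale_contact,
    step_fa_population,
)
from mechamigr.params import Condition, Setup, load_params


class TestMaugisDugdaleContact:
    def test_zero_force_beyond_adhesive_range(self, ico2, params):
        ico2.positions[:, 2] += 20e-6  # far above the plane
        f_cell, f_subs = maugis_dugdale_contact(0, 0, ico2, params)
        assert np.allclose(f_cell, 0) and np.allclose(f_subs, 0)

    def test_action_reaction(self, ico2, params):
        ico2.positions[:, 2] += 8e-6 + 1e-7  # bottom near the plane
        # find the lowest triangle
        t = int(np.argmin(ico2.tri_centroids()[:, 2]))
        f_cell, f_subs = maugis_dugdale_contact(t, 0, ico2, params)
        assert np.allclose(f_cell, -f_subs)

    def test_zero_adhesion_matches_hertz_closed_form(self, ico2):
        """With the adhesive stress off, the repulsive branch equals the
        Hertz sphere-on-flat solution F = (4/3) E* sqrt(R) delta^(3/2)."""
        p = load_params(sigma0_contact=1e-30, k_wall=1e-30)
        ico2.positions[:, 2] += 8e-6 - 3e-7  # overlap at the bottom
        t = int(np.argmin(ico2.tri_centroids()[:, 2]))
        delta = -ico2.tri_centroids()[t, 2]
        assert delta > 0
        from mechamigr.geometry import fit_local_sphere
        R = min(fit_local_sphere(t, ico2), p.R_contact_max)
        f_cell, _ = maugis_dugdale_contact(t, 0, ico2, p)
        hertz = (4.0 / 3.0) * p.E_contact * math.sqrt(R) * delta**1.5
        assert f_cell[2] == pytest.approx(hertz, rel=1e-6)

    def test_adhesion_pulls_separated_triangle_down(self, ico2, params):
        ico2.positions[:, 2] += 8e-6 + 1e-7
        t = int(np.argmin(ico2.tri_centroids()[:, 2]))
        assert 0 < ico2.tri_centroids()[t, 2] < params.h_contact
        f_cell, _ = maugis_dugdale_contact(t, 0, ico2, params)
        assert f_cell[2] < 0


class TestFAFormation:
    def _setup(self, spread_state):
        mesh = spread_state.mesh
        labels = spread_state.labels
        from mechamigr.geometry import Region
        lm_nodes = np.unique(mesh.triangles[
            (mesh.region == Region.FRONT_LM) | (mesh.region == Region.REAR_LM)])
        node = next(int(n) for n in lm_nodes
                    if abs(mesh.positions[n, 2]) <= spread_state.mesh.positions[:, 2].max())
        return mesh, labels, lm_nodes

    def test_distance_gate(self, spread_state, params, substrate):
        mesh, labels, lm_nodes = self._setup(spread_state)
        node = int(lm_nodes[0])
        refr = RefractoryState(mesh.n_nodes)
        rng = np.random.default_rng(0)
        old_z = mesh.positions[node, 2]
        mesh.positions[node, 2] = 0.1e-6  # beyond 0.075 um
        for _ in range(200):
            assert attempt_fa_formation(node, mesh, substrate, refr, labels,
                                        params, rng) is None
        mesh.positions[node, 2] = old_z

    def test_refractory_node_never_binds(self, spread_state, params, substrate):
        mesh, labels, lm_nodes = self._setup(spread_state)
        node = int(lm_nodes[0])
        mesh.positions[node, 2] = 1e-8
        refr = RefractoryState(mesh.n_nodes)
        refr.start(node, params.lambda_ref)
        rng = np.random.default_rng(0)
        for _ in range(200):
            assert attempt_fa_formation(node, mesh, substrate, refr, labels,
                                        params, rng) is None

    def test_formation_probability_matches_rate(self, spread_state, params,
                                                substrate):
        """Empirical per-step formation frequency ~ 1 - exp(-r_on dt)."""
        mesh, labels, lm_nodes = self._setup(spread_state)
        node = int(lm_nodes[0])
        mesh.positions[node, 2] = 1e-8
        refr = RefractoryState(mesh.n_nodes)
        rng = np.random.default_rng(7)
        n_trials, hits = 40000, 0
        for _ in range(n_trials):
            fa = attempt_fa_formation(node, mesh, substrate, refr, labels,
                                      params, rng)
            if fa is not None:
                hits += 1
        p_expected = 1.0 - math.exp(-params.r_on_FA * params.dt)  # 2.4997e-4
        assert p_expected == pytest.approx(2.4997e-4, rel=1e-3)
        sigma = math.sqrt(n_trials * p_expected)
        assert abs(hits - n_trials * p_expected) < 4 * sigma

    def test_anchor_is_plane_projection(self, spread_state, params, substrate):
        mesh, labels, lm_nodes = self._setup(spread_state)
        node = int(lm_nodes[0])
        mesh.positions[node, 2] = 1e-8
        refr = RefractoryState(mesh.n_nodes)
        rng = np.random.default_rng(1)
        fa = None
        while fa is None:
            fa = attempt_fa_formation(node, mesh, substrate, refr, labels,
                                      params, rng)
        assert fa.anchor[2] == 0.0
        assert fa.anchor[0] == pytest.approx(mesh.positions[node, 0])
        assert fa.anchor[1] == pytest.approx(mesh.positions[node, 1])


class TestFAForce:
    def test_zero_at_rest_length(self, ico2, params):
        rest = params.L_FA0 + params.L_ECM0
        fa = FocalAdhesion(node_id=0, anchor=ico2.positions[0]
                           + np.array([0, 0, -rest]), birth_time=0.0)
        assert np.allclose(fa_force(fa, ico2, 0.5, params), 0.0)

    def test_no_compression_branch(self, ico2, params):
        fa = FocalAdhesion(node_id=0, anchor=ico2.positions[0].copy(),
                           birth_time=0.0)  # L = 0 < rest
        assert np.allclose(fa_force(fa, ico2, 0.5, params), 0.0)

    def test_series_stiffness_dominated_by_ligand(self, params):
        ks = params.series_stiffness(1e-3)
        assert ks == pytest.approx(9.99999e-4, rel=1e-6)

    def test_rupture_scale_stretch(self, ico2, params):
        """15.4 nm of stretch beyond rest at k_ECM = 0.5 N/m carries F_rup."""
        rest = params.L_FA0 + params.L_ECM0
        stretch = params.F_rup / params.series_stiffness(0.5)
        fa = FocalAdhesion(node_id=0,
                           anchor=ico2.positions[0] + np.array(
                               [0, 0, -(rest + stretch)]),
                           birth_time=0.0)
        f = fa_force(fa, ico2, 0.5, params)
        assert np.linalg.norm(f) == pytest.approx(7.7e-9, rel=1e-6)
        assert stretch == pytest.approx(15.4e-9, rel=1e-2)

    def test_vectorised_path_matches_scalar(self, ico2, params):
        rng = np.random.default_rng(2)
        nodes = rng.integers(0, ico2.n_nodes, 10)
        anchors = ico2.positions[nodes] + rng.normal(scale=2e-8, size=(10, 3))
        stacked = fa_forces_array(ico2.positions[nodes], anchors, 0.144, params)
        for k, n in enumerate(nodes):
            fa = FocalAdhesion(node_id=int(n), anchor=anchors[k], birth_time=0.0)
            assert np.allclose(stacked[k], fa_force(fa, ico2, 0.144, params))


class TestDisassemblyRate:
    COND = Condition(k_ECM=0.5, r_off_FA0=5e-4)

    def _fa(self, force_mag, tag):
        fa = FocalAdhesion(node_id=0, anchor=np.zeros(3), birth_time=0.0,
                           region_tag=tag)
        fa.force = np.array([force_mag, 0, 0])
        return fa

    def test_zero_force_identity(self, params):
        fa = self._fa(0.0, adh.TAG_FRONT)
        r = fa_disassembly_rate(fa, Setup(True, True), self.COND, params)
        assert r == pytest.approx(5e-4)

    def test_rear_front_ratio_is_two(self, params):
        for F in (0.0, 2e-9, 7e-9):
            rf = fa_disassembly_rate(self._fa(F, adh.TAG_FRONT),
                                     Setup(True, True), self.COND, params)
            rr = fa_disassembly_rate(self._fa(F, adh.TAG_REAR),
                                     Setup(True, True), self.COND, params)
            assert rr / rf == pytest.approx(2.0)

    def test_catch_bond_evaluation(self, params):
        """r = r0 exp(-zeta F): 5e-4 * exp(-1.21/nN * 7.7 nN) = 4.48e-8."""
        r = fa_disassembly_rate(self._fa(7.7e-9, adh.TAG_FRONT),
                                Setup(True, True), self.COND, params)
        assert r == pytest.approx(5e-4 * math.exp(-9.317), rel=1e-3)
        assert r == pytest.approx(4.48e-8, rel=1e-2)

    def test_monotone_decreasing_in_force_when_mat_on(self, params):
        forces = np.linspace(0, 7.7e-9, 30)
        rates = [fa_disassembly_rate(self._fa(F, adh.TAG_FRONT),
                                     Setup(True, True), self.COND, params)
                 for F in forces]
        assert np.all(np.diff(rates) < 0)

    def test_constant_in_force_when_mat_off(self, params):
        rates = [fa_disassembly_rate(self._fa(F, adh.TAG_FRONT),
                                      Setup(False, True), self.COND, params)
                 for F in (0.0, 3e-9, 7.7e-9)]
        assert all(r == pytest.approx(5e-4) for r in rates)

    def test_outside_lm_factor_of_ten(self, params):
        r_in = fa_disassembly_rate(self._fa(0.0, adh.TAG_FRONT),
                                   Setup(True, True), self.COND, params)
        r_out = fa_disassembly_rate(self._fa(0.0, adh.TAG_OUTSIDE),
                                    Setup(True, True), self.COND, params)
        assert r_out / r_in == pytest.approx(10.0)


class TestStepFAPopulation:
    COND = Condition(k_ECM=0.5, r_off_FA0=5e-4)

    def _population(self, forces, tags=None):
        fas = []
        for k, F in enumerate(forces):
            fa = FocalAdhesion(node_id=k, anchor=np.zeros(3), birth_time=0.0,
                               region_tag=adh.TAG_FRONT if tags is None
                               else tags[k], uid=k)
            fa.force = np.array([F, 0.0, 0.0])
            fas.append(fa)
        return fas

    def test_rupture_boundary_is_strict(self, params):
        fas = self._population([7.7e-9])  # exactly F_rup: no rupture
        rng = np.random.default_rng(0)
        surv, events = step_fa_population(fas, Setup(True, True), self.COND,
                                          params, rng, clock=0.0)
        assert not any(e.kind == "rupture" for e in events)

    def test_rupture_above_threshold_sets_refractory(self, params):
        fas = self._population([7.71e-9])
        refr = RefractoryState(4)
        rng = np.random.default_rng(0)
        surv, events = step_fa_population(fas, Setup(True, True), self.COND,
                                          params, rng, clock=5.0,
                                          refractory=refr)
        assert [e.kind for e in events] == ["rupture"]
        assert len(surv) == 0
        assert refr.timers[0] == pytest.approx(1800.0)

    def test_zero_rate_low_force_always_survives(self, params):
        cond = Condition(k_ECM=0.5, r_off_FA0=1e-12)
        fas = self._population([1e-9] * 20)
        rng = np.random.default_rng(0)
        for _ in range(100):
            fas, events = step_fa_population(fas, Setup(False, False), cond,
                                             params, rng, clock=0.0)
        assert len(fas) == 20

    def test_survival_matches_exponential_law(self, params):
        """10^4 force-free FAs: survivors after time t within 3 sigma of
        N exp(-r t) (binomial error)."""
        n0 = 10**4
        r0 = 5e-3
        cond = Condition(k_ECM=0.5, r_off_FA0=r0)
        fas = self._population([0.0] * n0)
        rng = np.random.default_rng(123)
        n_steps = 400  # t = 20 s
        for _ in range(n_steps):
            fas, _ = step_fa_population(fas, Setup(False, False), cond,
                                        params, rng, clock=0.0)
        t = n_steps * params.dt
        p_surv = math.exp(-r0 * t)
        expected = n0 * p_surv
        sigma = math.sqrt(n0 * p_surv * (1 - p_surv))
        assert abs(len(fas) - expected) < 3 * sigma


class TestExpectedLifetime:
    @pytest.mark.parametrize("rate,minutes", [
        (5e-2, 0.3), (1.08e-2, 1.5), (2.3e-3, 7.2), (5e-4, 33.3),
    ])
    def test_published_lifetime_table(self, rate, minutes):
        assert round(expected_lifetime(rate), 1) == minutes

    def test_small_rate_limit(self):
        # for r -> 0, <lambda> -> 1/r (1999.5 s vs 2000 s at r = 5e-4)
        assert expected_lifetime(5e-4) * 60 == pytest.approx(1999.5, abs=0.1)
        assert expected_lifetime(5e-4) * 60 == pytest.approx(1.0 / 5e-4,
                                                             rel=1e-3)

    @pytest.mark.parametrize("bad", [0.0, 1.0, 1.5, -0.1])
    def test_invalid_rates_rejected(self, bad):
        with pytest.raises(ValueError):
            expected_lifetime(bad)
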