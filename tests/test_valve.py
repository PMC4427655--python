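"""Mitral apparatus: strip equilibrium, contact mechanics, device effects
and the chordae-force traces."""

from dataclasses import replace

import numpy as np
import pytest

from cardiosim.valve import (
    ChordaSpec,
    ContactParams,
    DeviceGeometry,
    ValveGeometry,
    attach_device,
    chordae_force_trace,
    default_valve_geometry,
    solve_strip,
    solve_valve,
)
from cardiosim.valve import _StripProblem, _wrap_length
from cardiosim.ventricle import InfarctRegion


@pytest.fixture(scope="module")
def geom():
    return default_valve_geometry()


@pytest.fixture(scope="module")
def healthy_valve_trace(geom, healthy_cycle):
    g = replace(geom, annulus_ref_volume=healthy_cycle.EDV)
    return solve_valve(g, healthy_cycle, InfarctRegion(phi=0.0))


def strip_problem(geom, dP=10.0, diameter=28.0, pap=(4.0, 22.0), element=None):
    return _StripProblem(
        geom=geom,
        diameter=diameter,
        width=geom.strip_width(diameter),
        dP=dP,
        pap=np.asarray(pap, dtype=float),
        element=element,
        contact=ContactParams(),
    )


class TestStripMechanics:
    def test_unloaded_state_zero_forces(self, geom):
        sol = solve_strip(geom, 0.0, geom.pap_tips[0])
        assert all(f == 0.0 for f in sol.forces_N.values())
        assert sol.penetration_max <= 1e-9

    def test_gradient_consistent_with_conservative_energy(self, geom):
        # all terms except the free-edge pressure load derive from a
        # potential; central finite differences of that potential must match
        # the assembled residual away from the two free-end nodes
        prob = strip_problem(geom, element=(5.0, 12.0, 4.0))
        q = prob.initial_guess() + 0.3 * np.cos(np.arange(prob.initial_guess().size))
        _, g = prob.energy_grad(q)
        gfd = np.empty_like(g)
        h = 1e-6
        for k in range(q.size):
            qp, qm = q.copy(), q.copy()
            qp[k] += h
            qm[k] -= h
            gfd[k] = (prob.energy_grad(qp, want_grad=False)[0] - prob.energy_grad(qm, want_grad=False)[0]) / (2 * h)
        mask = np.ones(q.size, bool)
        na = prob.n_a
        mask[2 * na - 2 : 2 * na] = False  # anterior free-edge node
        mask[-2:] = False  # posterior free-edge node
        err = np.max(np.abs((g - gfd)[mask])) / np.max(np.abs(gfd))
        assert err < 1e-6

    def test_competent_closure_under_pressure(self, geom):
        sol = solve_strip(geom, 15.0, geom.pap_tips[0], diameter=26.0)
        assert sol.coaptation_len > 0.0
        assert sol.gap_width == 0.0
        assert sol.penetration_max <= ContactParams().gap_tol

    def test_equilibrium_reproduced_by_independent_root_solver(self, geom):
        # same residual, independent algorithm (MINPACK hybrid) from a
        # perturbed start converges to the same equilibrium
        from scipy.optimize import root

        sol = solve_strip(geom, 12.0, geom.pap_tips[0], diameter=28.0)
        prob = strip_problem(geom, dP=12.0, diameter=28.0)
        x0 = sol.q + 0.05 * np.sin(np.arange(sol.q.size))
        alt = root(lambda x: prob.energy_grad(x)[1], x0, method="hybr", options={"xtol": 1e-12})
        assert alt.success
        np.testing.assert_allclose(alt.x, sol.q, atol=5e-3)

    def test_extreme_tethering_opens_gap(self, geom):
        # papillary tip displaced beyond the posterior leaflet's reach
        pap = geom.pap_tips[0] + np.array([12.0, 30.0])
        sol = solve_strip(geom, 10.0, pap, diameter=28.0)
        assert sol.gap_width > 0.0
        assert sol.coaptation_len == 0.0

    def test_chordae_forces_never_negative(self, healthy_valve_trace):
        for sol in healthy_valve_trace.solutions:
            for st in sol.strips:
                assert all(f >= 0.0 for f in st.forces_N.values())

    def test_penetration_within_tolerance_everywhere(self, healthy_valve_trace):
        tol = ContactParams().gap_tol
        for sol in healthy_valve_trace.solutions:
            for st in sol.strips:
                assert st.penetration_max <= tol


class TestWrapGeometry:
    def test_wrap_length_exceeds_straight_chord(self):
        P1, P2, C = np.array([7.0, 28.0]), np.array([8.0, 4.0]), np.array([5.0, 12.0])
        L, _ = _wrap_length(P1, P2, C, 4.0)
        assert L > np.linalg.norm(P2 - P1)

    def test_pull_direction_matches_length_gradient(self):
        # taut-string property: dL/dP2 equals the unit vector along the
        # string at P2 (finite-difference oracle)
        P1, C, r = np.array([7.0, 28.0]), np.array([5.0, 12.0]), 4.0
        for P2 in (np.array([8.0, 4.0]), np.array([2.0, 3.0]), np.array([10.0, 6.0])):
            L, pull = _wrap_length(P1, P2, C, r)
            for k in range(2):
                e = np.zeros(2)
                e[k] = 1e-6
                fd = (_wrap_length(P1, P2 + e, C, r)[0] - _wrap_length(P1, P2 - e, C, r)[0]) / 2e-6
                assert fd == pytest.approx(pull[k], abs=1e-5)

    def test_clear_chord_is_straight(self):
        P1, P2 = np.array([0.0, 0.0]), np.array([10.0, 0.0])
        L, pull = _wrap_length(P1, P2, np.array([5.0, 10.0]), 2.0)
        assert L == pytest.approx(10.0)
        np.testing.assert_allclose(pull, [1.0, 0.0])


class TestValveTrace:
    def test_healthy_valve_competent_at_all_times(self, healthy_valve_trace):
        assert np.all(healthy_valve_trace.A_gap == 0.0)

    def test_gap_iff_no_coaptation(self, geom, healthy_cycle, sized_infarct):
        g = replace(geom, annulus_ref_volume=healthy_cycle.EDV)
        inf = replace(sized_infarct, pap_disp_scale=25.0)
        trace = solve_valve(g, healthy_cycle, inf)
        for sol in trace.solutions:
            every_strip_coapts = all(st.coaptation_len > 0 for st in sol.strips)
            assert (sol.A_gap == 0.0) == every_strip_coapts

    def test_infarct_opens_gap_on_posterior_sector(self, geom, infarcted_cycle, sized_infarct):
        g = replace(geom, annulus_ref_volume=71.0)
        inf = replace(sized_infarct, pap_disp_scale=12.0)
        trace = solve_valve(g, infarcted_cycle, inf)
        assert float(np.max(trace.A_gap)) > 0.0
        # once the valve is meaningfully loaded (above the quasi-static
        # closing transient), the gap comes from infarct-sector strips only
        loaded = [s for s in trace.solutions if s.dP > 2.0]
        gapped = {
            i for s in loaded for i, st in enumerate(s.strips) if st.gap_width > 0
        }
        assert gapped
        assert gapped <= set(g.infarct_strips)

    def test_normalization_identity(self, healthy_valve_trace):
        norm = chordae_force_trace(healthy_valve_trace)
        assert float(np.max(norm)) == pytest.approx(1.0)

    def test_determinism(self, geom, healthy_cycle):
        g = replace(geom, annulus_ref_volume=healthy_cycle.EDV)
        t1 = solve_valve(g, healthy_cycle, InfarctRegion(phi=0.0))
        t2 = solve_valve(g, healthy_cycle, InfarctRegion(phi=0.0))
        np.testing.assert_array_equal(t1.posterior_force, t2.posterior_force)
        np.testing.assert_array_equal(t1.A_gap, t2.A_gap)

    def test_a_gap_callable_zero_outside_window(self, healthy_valve_trace):
        fn = healthy_valve_trace.a_gap_callable()
        assert fn(0.0) == 0.0
        assert fn(0.99) == 0.0


class TestDevice:
    def test_attach_identity_when_inert(self, geom):
        device = DeviceGeometry(undersize_factor=1.0, enabled_subvalvular=False)
        attached = attach_device(geom, device)
        assert attached.annulus_diameter == geom.annulus_diameter
        assert attached.device == device

    def test_subvalvular_disabled_equals_ring_only(self, geom, infarcted_cycle, sized_infarct):
        g = replace(geom, annulus_ref_volume=71.0)
        inf = replace(sized_infarct, pap_disp_scale=12.0)
        ring_only = DeviceGeometry(enabled_subvalvular=False)
        disabled = solve_valve(g, infarcted_cycle, inf, device=ring_only)
        also_ring = solve_valve(
            g, infarcted_cycle, inf, device=replace(ring_only, subvalvular_depth=25.0)
        )
        np.testing.assert_array_equal(disabled.posterior_force, also_ring.posterior_force)
        np.testing.assert_array_equal(disabled.A_gap, also_ring.A_gap)

    def test_element_pushes_posterior_edge_anteriorly(self, geom):
        # unilateral contact: with the element the posterior free edge sits
        # at, or anterior of, its element-free position on contacted strips
        pap = geom.pap_tips[0] + np.array([1.0, 2.0])
        D = 0.85 * geom.annulus_diameter
        elem = (0.5 * D - 6.0, 12.0, 4.0)
        with_elem = solve_strip(geom, 12.0, pap, diameter=D, device_element=elem)
        without = solve_strip(geom, 12.0, pap, diameter=D)
        prob = strip_problem(geom, dP=12.0, diameter=D, pap=pap)
        _, p_with = prob.split(with_elem.q)
        _, p_without = prob.split(without.q)
        assert p_with[-1, 0] <= p_without[-1, 0] + 1e-6

    def test_device_reduces_gap_at_every_time(self, geom, infarcted_cycle, sized_infarct):
        g = replace(geom, annulus_ref_volume=71.0)
        inf = replace(sized_infarct, pap_disp_scale=12.0)
        no_dev = solve_valve(g, infarcted_cycle, inf)
        dev = solve_valve(g, infarcted_cycle, inf, device=DeviceGeometry())
        assert np.max(no_dev.A_gap) > 0
        assert np.all(dev.A_gap <= no_dev.A_gap)

    def test_undersize_factor_bounds(self):
        with pytest.raises(ValueError):
            DeviceGeometry(undersize_factor=1.4)


class TestGeometryValidation:
    def test_minimum_strip_count(self):
        with pytest.raises(ValueError):
            ValveGeometry(n_strips=4, pap_tips=np.zeros((4, 2)))

    def test_chorda_spec_validation(self):
        from cardiosim.materials import ExpLaw1D

        with pytest.raises(ValueError):
            ChordaSpec("strut", "posterior", 0.5, 10.0, ExpLaw1D(1.0, 10.0), 0.5)
        with pytest.raises(ValueError):
            ChordaSpec("basal", "posterior", 1.5, 10.0, ExpLaw1D(1.0, 10.0), 0.5)

    def test_scallop_labels(self, geom):
        assert geom.scallop_label(0) == "A1-P1"
        assert geom.scallop_label(11) == "A3-P3"
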