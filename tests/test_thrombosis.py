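"""Four-species thrombosis model: switches, sources, transport oracles,
boundary-flux gating, cycle ledger and the thrombus mask."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

import dissectsim as ds
from dissectsim.fem import P1Operators
from dissectsim.thrombosis import (CycleLedger, SpeciesSolver, SpeciesState,
                                   ThrombosisParams, coagulant_flux, phi_BP,
                                   shear_switch, source_terms, switching,
                                   thrombus_mask)

from conftest import l2_error


class TestSwitching:
    def test_midpoint(self):
        assert switching(10.0, 10.0) == pytest.approx(0.5)

    def test_zero(self):
        assert switching(0.0, 5.0) == 0.0

    def test_product_switch_at_both_midpoints(self, tparams):
        assert phi_BP(tparams.AP_t, tparams.C_t, tparams) == pytest.approx(0.25)

    @given(st.floats(0, 1e6), st.floats(1e-3, 1e3))
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_monotone(self, x, xt):
        phi = switching(x, xt)
        assert 0.0 <= phi <= 1.0
        assert switching(x + 1.0, xt) >= phi


class TestShearSwitch:
    def test_rest_value_is_one(self):
        assert shear_switch(0.0, 50.0) == pytest.approx(1.0)

    def test_midpoint_at_threshold(self):
        assert shear_switch(50.0, 50.0) == pytest.approx(0.5)

    def test_high_shear_limit(self):
        assert shear_switch(1e9, 50.0) == pytest.approx(0.0, abs=1e-10)

    def test_literal_variant_available(self):
        # the mixed-units printed form, exposed for sensitivity checks
        assert shear_switch(2500.0, 50.0, literal=True) == pytest.approx(0.5)

    @given(st.floats(0, 1e5))
    @settings(max_examples=50, deadline=None)
    def test_monotone_decreasing(self, g):
        assert shear_switch(g, 50.0) >= shear_switch(g + 1.0, 50.0)


class TestSourceTerms:
    def test_activation_rate_at_unit_concentrations(self, tparams):
        _, s_ap, _, _ = source_terms(1.0, 1.0, 0.0, 0.0, 1.0, tparams)
        assert s_ap == pytest.approx(3.0)

    def test_all_sources_vanish_without_activated_platelets(self, tparams):
        s = source_terms(1.0, 0.0, 5.0, 5.0, 0.7, tparams)
        assert all(v == 0.0 for v in s)

    def test_bound_platelet_saturating_limit(self, tparams):
        # AP >> AP_t, C >> C_t, zero shear -> S_BP/AP -> k_BP
        _, _, _, s_bp = source_terms(0.0, 1e6, 1e6, 0.0, 1.0, tparams)
        assert s_bp / 1e6 == pytest.approx(12.0, rel=1e-6)

    def test_coagulant_source_zero_when_switches_closed(self, tparams):
        _, _, s_c, _ = source_terms(1.0, 1.0, 0.0, 0.0, 1.0, tparams)
        assert s_c == 0.0

    def test_resting_platelet_depletion_sign(self, tparams):
        s_rp, _, _, _ = source_terms(2.0, 3.0, 0.0, 0.0, 1.0, tparams)
        assert s_rp < 0

    def test_invalid_sign_conventions_rejected(self):
        with pytest.raises(ValueError):
            ThrombosisParams(k_RP=0.15)
        with pytest.raises(ValueError):
            ThrombosisParams(k_C2=6.0)


class TestCoagulantWallFlux:
    def test_flux_on_when_both_gates_open(self, tparams):
        assert coagulant_flux(0.10, 5.0, tparams) == pytest.approx(16.0)

    def test_flux_off_at_high_tawss(self, tparams):
        assert coagulant_flux(0.30, 5.0, tparams) == 0.0

    def test_flux_off_once_thrombosed(self, tparams):
        assert coagulant_flux(0.10, 25.0, tparams) == 0.0


def make_species_solver(mesh, params, **kw):
    ops = P1Operators(mesh)
    return ops, SpeciesSolver(mesh, ops, params, **kw)


class TestSpeciesTransport:
    def test_advected_gaussian(self):
        """Pure-advection limit: a Gaussian blob translates with < 2% L2
        error at resolved mesh and time step."""
        mesh = ds.benchmark_channel(20.0, 8.0, 0.1)
        p = ThrombosisParams(D_AP=0.0, D_RP=0.0, inlet_value=0.0)
        ops, ss = make_species_solver(mesh, p, reactive_tags=())
        n = mesh.n_nodes
        x, y = mesh.nodes.T
        sig, x0, u0 = 1e-3, 5e-3, 0.05
        ap0 = np.exp(-((x - x0) ** 2 + (y - 4e-3) ** 2) / (2 * sig**2))
        sp = SpeciesState(np.zeros(n), ap0.copy(), np.zeros(n), np.zeros(n))
        u = np.zeros((n, 2)); u[:, 0] = u0
        w = np.zeros((n, 2)); gam = np.zeros(n)
        led = CycleLedger(len(mesh.edges), n)
        dt, T = 5e-4, 0.2
        for _ in range(int(T / dt)):
            sp = ss.step(sp, u, w, gam, led, dt)
        ap_ex = np.exp(-((x - x0 - u0 * T) ** 2 + (y - 4e-3) ** 2) / (2 * sig**2))
        assert l2_error(ops, sp.AP, ap_ex) < 0.02
        assert np.all(sp.AP >= 0)

    def test_diffusing_gaussian_coagulant(self):
        """Diffusion-only C in quiescent flow follows the heat kernel with
        variance 2 D t, < 2% L2."""
        mesh = ds.benchmark_channel(6.0, 6.0, 0.1)
        p = ThrombosisParams(inlet_value=0.0)
        ops, ss = make_species_solver(mesh, p, reactive_tags=(), inlet_tag=None)
        n = mesh.n_nodes
        x, y = mesh.nodes.T
        sig0, D, T = 0.4e-3, 1e-8, 8.0
        c0 = np.exp(-((x - 3e-3) ** 2 + (y - 3e-3) ** 2) / (2 * sig0**2))
        sp = SpeciesState(np.zeros(n), np.zeros(n), c0.copy(), np.zeros(n))
        u = np.zeros((n, 2)); w = np.zeros((n, 2)); gam = np.zeros(n)
        led = CycleLedger(len(mesh.edges), n)
        dt = 0.02
        for _ in range(int(T / dt)):
            sp = ss.step(sp, u, w, gam, led, dt)
        s2 = sig0**2 + 2 * D * T
        c_ex = (sig0**2 / s2) * np.exp(-((x - 3e-3) ** 2 + (y - 3e-3) ** 2) / (2 * s2))
        assert l2_error(ops, sp.C, c_ex) < 0.02

    def test_uniform_reaction_matches_ode(self):
        """Uniform fields with no flow: the PDE solution tracks a
        high-accuracy ODE integration of the platelet kinetics to < 0.5%."""
        mesh = ds.benchmark_channel(4.0, 4.0, 0.5)
        p = ThrombosisParams()
        ops, ss = make_species_solver(mesh, p, reactive_tags=(), inlet_tag=None)
        n = mesh.n_nodes
        sp = SpeciesState(np.ones(n), np.ones(n), np.zeros(n), np.zeros(n))
        u = np.zeros((n, 2)); w = np.zeros((n, 2)); gam = np.zeros(n)
        led = CycleLedger(len(mesh.edges), n)
        dt, T = 1e-3, 1.5
        for _ in range(int(T / dt)):
            sp = ss.step(sp, u, w, gam, led, dt)

        def rhs(_, yv):
            return source_terms(yv[0], yv[1], yv[2], yv[3], 1.0, p)

        sol = solve_ivp(rhs, (0, T), [1, 1, 0, 0], rtol=1e-10, atol=1e-12)
        rp_ref, ap_ref = sol.y[0, -1], sol.y[1, -1]
        assert abs(sp.RP[0] - rp_ref) / ap_ref < 0.005
        assert abs(sp.AP[0] - ap_ref) / ap_ref < 0.005
        assert np.allclose(sp.AP, sp.AP[0])  # stays uniform

    def test_coagulant_is_never_advected(self):
        """C with zero diffusivity and closed switches is frozen even in a
        nonzero velocity field."""
        mesh = ds.benchmark_channel(10.0, 4.0, 0.2)
        p = ThrombosisParams(D_C_base=0.0, inlet_value=0.0)
        ops, ss = make_species_solver(mesh, p, reactive_tags=())
        n = mesh.n_nodes
        x = mesh.nodes[:, 0]
        c0 = np.where(x < 5e-3, 7.0, 1.0)
        sp = SpeciesState(np.zeros(n), np.zeros(n), c0.copy(), np.zeros(n))
        u = np.zeros((n, 2)); u[:, 0] = 0.1
        w = np.zeros((n, 2)); gam = np.zeros(n)
        led = CycleLedger(len(mesh.edges), n)
        for _ in range(100):
            sp = ss.step(sp, u, w, gam, led, 1e-3)
        assert np.array_equal(sp.C, c0)

    def test_bound_platelets_never_transported(self):
        mesh = ds.benchmark_channel(10.0, 4.0, 0.2)
        p = ThrombosisParams(inlet_value=0.0)
        ops, ss = make_species_solver(mesh, p, reactive_tags=())
        n = mesh.n_nodes
        bp0 = np.where(mesh.nodes[:, 0] < 5e-3, 30.0, 0.0)
        sp = SpeciesState(np.zeros(n), np.zeros(n), np.zeros(n), bp0.copy())
        u = np.zeros((n, 2)); u[:, 0] = 0.1
        w = np.zeros((n, 2)); gam = np.zeros(n)
        led = CycleLedger(len(mesh.edges), n)
        for _ in range(100):
            sp = ss.step(sp, u, w, gam, led, 1e-3)
        assert np.array_equal(sp.BP, bp0)  # AP = 0 -> S_BP = 0, no transport

    def test_cascade_cannot_self_start(self):
        """With the wall flux disabled and C = BP = 0 initially, C and BP
        stay identically zero (k_C1 needs BP, k_C2 needs C)."""
        mesh = ds.benchmark_channel(10.0, 4.0, 0.25)
        p = ThrombosisParams()
        ops, ss = make_species_solver(mesh, p, reactive_tags=())
        n = mesh.n_nodes
        sp = SpeciesState.initial(n)
        u = np.zeros((n, 2)); w = np.zeros((n, 2)); gam = np.zeros(n)
        led = CycleLedger(len(mesh.edges), n)  # flux off (no reactive walls)
        for _ in range(200):
            sp = ss.step(sp, u, w, gam, led, 2e-3)
        assert np.all(sp.C == 0.0)
        assert np.all(sp.BP == 0.0)
        assert sp.AP.max() > 3.0  # platelet activation still proceeds

    def test_bp_monotone_under_active_kinetics(self):
        """BP is non-decreasing at every node and every step (no lysis)."""
        mesh = ds.benchmark_channel(10.0, 4.0, 0.25)
        p = ThrombosisParams()
        ops, ss = make_species_solver(mesh, p)
        n = mesh.n_nodes
        sp = SpeciesState.initial(n)
        sp.C[:] = 20.0
        u = np.zeros((n, 2)); w = np.zeros((n, 2)); gam = np.full(n, 10.0)
        led = CycleLedger(len(mesh.edges), n)
        led.tawss_prev[:] = 0.05  # activate the wall flux
        prev = sp.BP.copy()
        for _ in range(100):
            sp = ss.step(sp, u, w, gam, led, 2e-3)
            assert np.all(sp.BP >= prev - 1e-15)
            prev = sp.BP.copy()
        assert sp.BP.max() > 0


class TestWallFluxBoundary:
    def test_flux_applied_only_where_gated(self, tparams):
        mesh = ds.benchmark_channel(10.0, 2.0, 0.25)
        ops, ss = make_species_solver(mesh, tparams)
        n = mesh.n_nodes
        sp = SpeciesState.initial(n)
        led = CycleLedger(len(mesh.edges), n)
        # low TAWSS on the lower wall only
        mids = mesh.edge_midpoints()
        led.tawss_prev[:] = 1.0
        lower = (mesh.edge_tags == 3) & (mids[:, 1] < 1e-6)  # outer_wall, y=0
        led.tawss_prev[lower] = 0.05
        flux = ss.apply_species_bcs(sp, led)
        y = mesh.nodes[:, 1]
        assert flux[(y < 1e-9)].sum() > 0
        assert np.allclose(flux[y > 1e-9], 0.0)

    def test_first_cycle_flux_disabled(self, tparams):
        mesh = ds.benchmark_channel(10.0, 2.0, 0.25)
        ops, ss = make_species_solver(mesh, tparams)
        sp = SpeciesState.initial(mesh.n_nodes)
        led = CycleLedger(len(mesh.edges), mesh.n_nodes)  # tawss_prev = +inf
        assert np.allclose(ss.apply_species_bcs(sp, led), 0.0)

    def test_wall_concentration_applied(self, tparams):
        mesh = ds.benchmark_channel(10.0, 2.0, 0.25)
        ops, ss = make_species_solver(mesh, tparams)
        sp = SpeciesState.initial(mesh.n_nodes)
        led = CycleLedger(len(mesh.edges), mesh.n_nodes)
        ss.apply_species_bcs(sp, led)
        walls = mesh.boundary_node_set("outer_wall")
        assert np.allclose(sp.RP[walls], 2.0)
        assert np.allclose(sp.AP[walls], 2.0)


class TestCycleLedger:
    def test_constant_wss_average(self):
        led = CycleLedger(4, 3)
        for _ in range(100):
            led.accumulate(np.full(4, 0.3), np.zeros(3), np.zeros(3),
                           np.zeros(3), 0.01)
        led.complete_cycle()
        assert np.allclose(led.tawss_prev, 0.3)

    def test_rectified_sine_average(self):
        led = CycleLedger(1, 1)
        T, n = 1.0, 2000
        dt = T / n
        for k in range(n):
            t = (k + 0.5) * dt
            led.accumulate(np.array([2.0 * abs(np.sin(2 * np.pi * t / T))]),
                           np.zeros(1), np.zeros(1), np.zeros(1), dt)
        led.complete_cycle()
        assert led.tawss_prev[0] == pytest.approx(2 * 2.0 / np.pi, rel=1e-4)

    def test_first_cycle_policy_is_infinite_tawss(self):
        led = CycleLedger(5, 2)
        assert np.all(np.isinf(led.tawss_prev))

    def test_accumulators_reset_after_publication(self):
        led = CycleLedger(2, 2)
        led.accumulate(np.ones(2), np.ones(2), np.ones(2), np.ones(2), 0.5)
        led.complete_cycle()
        assert led._t_acc == 0.0
        assert led.cycle_index == 1


class TestThrombusMask:
    def test_zero_bp_zero_volume(self, channel_mesh, channel_ops):
        _, vol = thrombus_mask(np.zeros(channel_mesh.n_nodes), 20.0, channel_ops)
        assert vol == 0.0

    def test_half_domain_volume(self, channel_mesh, channel_ops):
        bp = np.where(channel_mesh.nodes[:, 0] < 10e-3, 25.0, 0.0)
        _, vol = thrombus_mask(bp, 20.0, channel_ops)
        half = 0.5 * channel_mesh.area() * 1e6  # cm^3 at unit depth
        assert vol == pytest.approx(half, rel=0.02)

    def test_volume_monotone_in_bp(self, channel_mesh, channel_ops):
        rng = np.random.default_rng(42)
        bp = 15.0 * rng.random(channel_mesh.n_nodes)
        _, v1 = thrombus_mask(bp, 20.0, channel_ops)
        _, v2 = thrombus_mask(bp + 10.0, 20.0, channel_ops)
        assert v2 >= v1
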