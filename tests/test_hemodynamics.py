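"""Flow-solver verification: classical channel-flow oracles, Windkessel,
waveform, momentum sink and wall shear stress."""

import numpy as np
import pytest

import dissectsim as ds
from dissectsim.hemodynamics import wall_shear_stress

RHO, MU = 1060.0, 3.5e-3
NU = MU / RHO


class TestFictitiousForce:
    def test_no_clot_no_force(self):
        F = ds.fictitious_force(0.0, np.array([1.0, 2.0]))
        assert np.allclose(F, 0.0)

    def test_half_saturation_at_threshold(self):
        # |F|/|u| = k_M/2 = 5e6 at BP = BP_t
        F = ds.fictitious_force(20.0, np.array([1.0, 0.0]), k_M=1e7, BP_t=20.0)
        assert F[0] == pytest.approx(5e6)

    def test_saturation_limit(self):
        F = ds.fictitious_force(1e9, np.array([1.0, 0.0]), k_M=1e7, BP_t=20.0)
        assert F[0] == pytest.approx(1e7, rel=1e-6)

    def test_antiparallel_to_velocity(self):
        u = np.array([[0.3, -0.4], [1.0, 2.0]])
        F = ds.fictitious_force(np.array([5.0, 50.0]), u)
        assert np.allclose(F[:, 0] * u[:, 1] - F[:, 1] * u[:, 0], 0.0)
        assert np.all((F * u).sum(axis=1) >= 0)  # applied with minus sign


class TestWindkessel:
    def test_steady_state_pressure(self):
        wk = ds.WindkesselParams(C=2e-7, R_p=7.2e6, R_c=4e5, P_wk=0.0)
        q = 1.75e-3
        for _ in range(200000):
            p = ds.windkessel_step(q, wk, 1e-3)
        assert p == pytest.approx(q * (7.2e6 + 4e5), rel=1e-6)

    def test_exponential_decay(self):
        wk = ds.WindkesselParams(C=2e-7, R_p=7.2e6, R_c=4e5, P_wk=1000.0)
        tau = 7.2e6 * 2e-7
        t, dt = 0.0, 1e-3
        for _ in range(1000):
            ds.windkessel_step(0.0, wk, dt)
            t += dt
        assert wk.P_wk == pytest.approx(1000.0 * np.exp(-t / tau), rel=1e-9)

    def test_zero_everything_stays_zero(self):
        wk = ds.WindkesselParams(P_wk=0.0)
        for _ in range(100):
            assert ds.windkessel_step(0.0, wk, 1e-2) == 0.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ds.WindkesselParams(C=-1.0)


class TestInletWaveform:
    def test_periodicity(self):
        wf = ds.InletWaveform()
        for t in (0.1, 0.37, 0.8):
            assert ds.inlet_velocity(t, wf, 0.02) == pytest.approx(
                ds.inlet_velocity(t + 1 / 1.02, wf, 0.02), rel=1e-9)

    def test_zero_amplitude(self):
        wf = ds.InletWaveform(mean_velocity=0.0)
        assert ds.inlet_velocity(0.3, wf, 0.02) == 0.0

    def test_cycle_mean_matches_configuration(self):
        wf = ds.InletWaveform(mean_velocity=0.09)
        t = np.linspace(0, wf.period, 20001)[:-1]
        mean = np.mean(wf.velocity(t))
        assert mean == pytest.approx(0.09, rel=1e-3)

    def test_flat_profile_integrates_to_flow_rate(self):
        wf = ds.InletWaveform()
        width = 0.0194
        q = wf.flow_rate(0.2, width)
        assert ds.inlet_velocity(0.2, wf, width) * width == pytest.approx(q)

    def test_has_systolic_peak_and_reverse_phase(self):
        wf = ds.InletWaveform()
        t = np.linspace(0, wf.period, 2000)
        s = wf.shape(t)
        assert s.max() > 2.0  # pronounced systolic peak
        assert s.min() < 0.0  # brief reverse flow


def run_channel(mesh, fluid, bc, dt, n, body_accel=None, BP=None,
                stabilize=True):
    solver = ds.FlowSolver(mesh, fluid, bc=bc, body_accel=body_accel,
                           stabilize=stabilize)
    if BP is not None:
        solver.BP = BP
    for _ in range(n):
        solver.step(dt)
    return solver


class TestChannelOracles:
    def test_poiseuille_profile(self, newtonian):
        """Pressure-driven steady channel flow reproduces the parabola to
        < 1% max pointwise error at 20 cells across."""
        mesh = ds.benchmark_channel(1.0, 1.0, 0.05)
        dp, L, W = 10.0, 1e-3, 1e-3
        solver = run_channel(mesh, newtonian,
                             {"inlet": ("pressure", dp),
                              "tl_outlet": ("pressure", 0.0)}, 5e-4, 1600)
        G = dp / L
        y = mesh.nodes[:, 1]
        u_exact = G / (2 * MU) * y * (W - y)
        err = np.max(np.abs(solver.u[:, 0] - u_exact)) / u_exact.max()
        assert err < 0.01

    def test_womersley_profiles(self, newtonian):
        """Oscillatory channel flow matches the analytic Womersley series
        to < 3% L2 over a cycle."""
        W, omega, Gamp = 2e-3, 40.0, 4240.0
        mesh = ds.benchmark_channel(1.0, 2.0, 0.05)
        T = 2 * np.pi / omega
        dt = T / 200
        solver = run_channel(
            mesh, newtonian,
            {"inlet": ("pressure", 0.0), "tl_outlet": ("pressure", 0.0)},
            dt, 200 * 6, stabilize=False,
            body_accel=lambda t: (Gamp / RHO * np.cos(omega * t), 0.0))

        lam = np.sqrt(1j * omega / NU)
        c = W / 2

        def exact(y, t):
            prof = (Gamp / (1j * RHO * omega)) * (
                1 - np.cosh(lam * (y - c)) / np.cosh(lam * c))
            return np.real(prof * np.exp(1j * omega * t))

        x, y = mesh.nodes.T
        col = np.isclose(x, 0.5e-3)
        num = den = 0.0
        for _ in range(20):
            for _ in range(10):
                solver.step(dt)
            ue = exact(y[col], solver.t)
            num += np.sum((solver.u[col, 0] - ue) ** 2)
            den += np.sum(ue**2)
        assert np.sqrt(num / den) < 0.03

    def test_brinkman_channel_flux(self, newtonian):
        """Fully thrombosed channel at fixed pressure drop matches the
        analytic Brinkman flux with sink coefficient k_M to < 2%."""
        mesh = ds.benchmark_channel(0.5, 2.0, 0.05)
        dp, L, W, kM = 100.0, 0.5e-3, 2e-3, 1e7
        BP = np.full(mesh.n_nodes, 1e6)
        solver = run_channel(mesh, newtonian,
                             {"inlet": ("pressure", dp),
                              "tl_outlet": ("pressure", 0.0)},
                             1e-4, 300, BP=BP, stabilize=False)
        G = dp / L
        phi = 1e12 / (1e12 + 400.0)
        k = kM * phi
        alpha = np.sqrt(k / MU)
        q_exact = (G / k) * (W - 2 * np.tanh(alpha * W / 2) / alpha)
        q_num = solver.boundary_flow("tl_outlet")
        assert q_num == pytest.approx(q_exact, rel=0.02)

    def test_momentum_sink_collapses_flow(self, newtonian):
        """With BP >> BP_t the steady flux drops by orders of magnitude
        relative to the clot-free channel at identical forcing."""
        mesh = ds.benchmark_channel(0.5, 2.0, 0.1)
        bc = {"inlet": ("pressure", 1.0), "tl_outlet": ("pressure", 0.0)}
        free = run_channel(mesh, newtonian, bc, 2e-4, 800)
        clot = run_channel(mesh, newtonian, bc, 1e-4, 200,
                           BP=np.full(mesh.n_nodes, 1e6))
        assert clot.boundary_flow("tl_outlet") < 1e-2 * free.boundary_flow("tl_outlet")

    def test_uniform_translation_preserved_on_moving_mesh(self, newtonian):
        """Galilean/GCL check: u = w = const on a translating mesh is a
        steady state of the ALE scheme."""
        mesh = ds.benchmark_channel(2.0, 1.0, 0.1)
        w0 = np.array([0.03, 0.0])
        solver = ds.FlowSolver(
            mesh, newtonian,
            bc={"inlet": ("velocity", tuple(w0)),
                "tl_outlet": ("velocity", tuple(w0)),
                "outer_wall": ("velocity", tuple(w0))})
        solver.u[:] = w0
        solver.w[:] = w0
        dt = 1e-3
        for _ in range(20):
            mesh.nodes = mesh.nodes + w0 * dt
            solver.mesh_updated()
            solver.step(dt)
        assert np.allclose(solver.u, w0, atol=1e-10)

    def test_mass_conservation(self, newtonian):
        mesh = ds.benchmark_channel(2.0, 1.0, 0.05)
        solver = run_channel(mesh, newtonian,
                             {"inlet": ("pressure", 20.0),
                              "tl_outlet": ("pressure", 0.0)}, 5e-4, 400)
        q_in = -solver.boundary_flow("inlet")  # inward positive
        q_out = solver.boundary_flow("tl_outlet")
        assert abs(q_in - q_out) / max(abs(q_in), 1e-12) < 1e-3

    def test_energy_bounded_under_pulsatile_forcing(self, newtonian):
        mesh = ds.benchmark_channel(2.0, 1.0, 0.1)
        wf = ds.InletWaveform(mean_velocity=0.05)
        solver = ds.FlowSolver(
            mesh, newtonian,
            bc={"inlet": ("velocity", lambda t: ds.inlet_velocity(t, wf, 1e-3)),
                "tl_outlet": ("pressure", 0.0)}, stabilize=True)
        dt = wf.period / 400
        ke = []
        for _ in range(3 * 400):
            solver.step(dt)
            ke.append(solver.log["kinetic_energy"])
        assert np.isfinite(ke).all()
        # periodic regime: last-cycle peak within 2x of previous cycle's
        assert max(ke[-400:]) < 2.0 * max(ke[-800:-400]) + 1e-12


class TestWallShearStress:
    def test_poiseuille_wss(self, newtonian):
        """WSS = 6 mu U / W at both walls of a developed channel, < 2%."""
        mesh = ds.benchmark_channel(1.0, 1.0, 0.05)
        dp, L, W = 10.0, 1e-3, 1e-3
        solver = run_channel(mesh, newtonian,
                             {"inlet": ("pressure", dp),
                              "tl_outlet": ("pressure", 0.0)}, 5e-4, 1600)
        idx = mesh.edges_with_tag("outer_wall")
        wss = wall_shear_stress(solver, idx)
        assert np.median(wss) == pytest.approx(dp / L * W / 2, rel=0.02)

    def test_quiescent_fluid_zero_wss(self, newtonian):
        mesh = ds.benchmark_channel(2.0, 1.0, 0.1)
        solver = ds.FlowSolver(mesh, newtonian)
        idx = mesh.edges_with_tag("outer_wall")
        assert np.allclose(wall_shear_stress(solver, idx), 0.0)

    def test_wss_linearity_in_flow(self, newtonian):
        mesh = ds.benchmark_channel(1.0, 1.0, 0.05)
        bc1 = {"inlet": ("pressure", 5.0), "tl_outlet": ("pressure", 0.0)}
        bc2 = {"inlet": ("pressure", 10.0), "tl_outlet": ("pressure", 0.0)}
        s1 = run_channel(mesh, newtonian, bc1, 5e-4, 1200)
        s2 = run_channel(mesh, newtonian, bc2, 5e-4, 1200)
        idx = mesh.edges_with_tag("outer_wall")
        w1 = np.median(wall_shear_stress(s1, idx))
        w2 = np.median(wall_shear_stress(s2, idx))
        assert w2 == pytest.approx(2 * w1, rel=0.02)
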