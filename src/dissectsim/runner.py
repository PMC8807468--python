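"""Simulation orchestration: the coupled flow-flap-thrombosis time loop,
the rigid/stiffer/flexible comparison driver, fixtures and checkpointing.

Per-step order: inlet & Windkessel update -> flap load/solve/mesh move ->
flow step (with the thrombus momentum sink) -> species step -> ledger
update.  Thrombosis is switched on after the configured number of
flow-only pre-cycles; the run stops early once per-cycle thrombus growth
falls below the configured fraction of the FL volume.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import postprocess as post
from .config import SimulationConfig
from .fem import P1Operators
from .flap import FlapState, flap_displacement_at, move_mesh, solve_flap
from .geometry import (DissectionGeometry, Mesh, build_dissection_geometry,
                       benchmark_channel, generate_mesh)
from .hemodynamics import FlowSolver, inlet_velocity, windkessel_step
from .io import atomic_write_text, write_csv, write_vtk
from .thrombosis import CycleLedger, SpeciesSolver, SpeciesState, thrombus_mask

log = logging.getLogger("dissectsim")


@dataclass
class RunManifest:
    config_hash: str
    code_version: str
    cycles: list[dict] = field(default_factory=list)
    termination: str = "running"

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1, sort_keys=True)


class Simulation:
    """A configured simulation with explicit state, steppable per cycle."""

    def __init__(self, config: SimulationConfig):
        self.config = config
        geo = config.geometry
        self.domain = build_dissection_geometry(geo)
        self.mesh = generate_mesh(self.domain, config.mesh.target_edge_length,
                                  config.mesh.wall_layers)
        self.fluid = config.fluid.build()
        self.waveform = config.waveform.build()
        self.wk = config.windkessel.build()
        self.tparams = config.thrombosis.build()
        self.force = config.thrombosis.build_force()
        self.fparams = config.flap.build(geo)
        for name, (dflt, val) in config.overridden_fields().items():
            log.info("config override: %s = %r (default %r)", name, val, dflt)

        self._p_out = self.wk.P_wk  # current Windkessel outlet pressure
        inlet_w = geo.tl_width * 1e-3

        def inlet_fn(t: float) -> float:
            return inlet_velocity(t, self.waveform, inlet_w)

        self.solver = FlowSolver(
            self.mesh, self.fluid,
            bc={"inlet": ("velocity", inlet_fn),
                "tl_outlet": ("pressure", lambda t: self._p_out)},
            force=self.force,
        )
        self.ops: P1Operators = self.solver.ops
        self.species_solver = SpeciesSolver(self.mesh, self.ops, self.tparams)
        self.species = SpeciesState.initial(self.mesh.n_nodes)
        self.ledger = CycleLedger(len(self.mesh.edges), self.mesh.n_nodes)
        self.flap_state = FlapState.zero(
            np.linspace(0.0, self.fparams.span, self.fparams.n_stations))
        self.wall_edge_idx = self.species_solver.wall_edge_idx
        self.masks = post.region_cell_masks(self.mesh, self.ops)
        self.fl_volume_cm3 = float(self.ops.area[self.masks["FL"]].sum()) * 1e6

        # flap-face pressure sampling: station x -> nearest flap-side wall node
        self._flap_nodes_tl = self._flap_face_nodes("flap_tl_side")
        self._flap_nodes_fl = self._flap_face_nodes("flap_fl_side")

        # start from the stored Windkessel pressure so the outlet condition
        # is not an impulsive load on the flap at t = 0
        self.solver.p[:] = self.wk.P_wk
        # flap increments are rate-limited to a fraction of the smallest
        # cell so mesh velocity stays benign during startup transients
        self._max_disp_step = 0.25 * float(self.ops.hcell.min())

        self.cycle = 0
        self.step_count = 0
        self.displacement_history: list[np.ndarray] = []
        self.cycle_max_disp: list[float] = []
        self.traces: list[dict] = []
        self.manifest = RunManifest(config.config_hash(), "dissectsim-0.1.0")
        self.thrombosis_active = False
        self._relaxed_disp = np.zeros(self.fparams.n_stations)
        self._load_filtered = np.zeros(self.fparams.n_stations)
        self._fl_vol_prev = 0.0

    # -- helpers -------------------------------------------------------------
    def _flap_face_nodes(self, tag: str) -> np.ndarray:
        nodes = self.mesh.boundary_node_set(tag)
        order = np.argsort(self.mesh.ref_nodes[nodes, 0])
        return nodes[order]

    def _sample_flap_load(self) -> np.ndarray:
        """Transmural dP per beam station from the two flap faces."""
        xd0 = self.mesh.x_marks_m[0]
        st = self.flap_state.stations
        p = self.solver.p
        xt = self.mesh.ref_nodes[self._flap_nodes_tl, 0] - xd0
        xf = self.mesh.ref_nodes[self._flap_nodes_fl, 0] - xd0
        p_tl = np.interp(st, xt, p[self._flap_nodes_tl])
        p_fl = np.interp(st, xf, p[self._flap_nodes_fl])
        from .flap import transmural_load
        tears = [((a * 1e-3) - xd0, (b * 1e-3) - xd0)
                 for a, b in self.config.geometry.tear_intervals()]
        return transmural_load(p_tl, p_fl, st, tears)

    def _flap_update(self, dt: float) -> None:
        if self.fparams.rigid or not self.config.flap.fsi:
            return
        load = self._sample_flap_load()
        # low-pass the load (tau ~ T/8): the quasi-static beam responds to
        # the cycle-scale transmural pressure, and the filter damps the
        # step-scale partitioned-coupling feedback
        tau = 0.125 * self.waveform.period
        self._load_filtered += (dt / tau) * (load - self._load_filtered)
        target = solve_flap(
            self._load_filtered, self.fparams,
            tear_intervals=[((a * 1e-3) - self.mesh.x_marks_m[0],
                             (b * 1e-3) - self.mesh.x_marks_m[0])
                            for a, b in self.config.geometry.tear_intervals()],
            stations=self.flap_state.stations,
        )
        # cap the quasi-static target first: the per-unit-depth beam is far
        # softer than a 3D tethered flap, so the cap is what keeps the
        # excursion at a physiological fraction of the lumen
        tdisp = target.displacement
        cap = self.fparams.displacement_cap
        if cap is not None:
            amax = np.max(np.abs(tdisp))
            if amax > cap:
                tdisp = tdisp * (cap / amax)
                log.debug("flap target capped at %.3g m (cycle %d)",
                          cap, self.cycle)
        ur = self.fparams.under_relaxation
        new = self._relaxed_disp + ur * (tdisp - self._relaxed_disp)
        # per-step increment limiter (mesh-velocity guard)
        inc = new - self._relaxed_disp
        imax = np.max(np.abs(inc))
        if imax > self._max_disp_step:
            new = self._relaxed_disp + inc * (self._max_disp_step / imax)
        self.flap_state.velocity = (new - self._relaxed_disp) / dt
        self._relaxed_disp = new
        self.flap_state.displacement = new
        self.flap_state.load = load
        w_mesh = move_mesh(self.mesh, self.flap_state, dt)
        self.solver.w = w_mesh
        self.solver.mesh_updated()

    def _flow_step_with_retry(self, dt: float, depth: int = 0) -> None:
        """Advance the flow by dt, halving the step (up to 3 times) if the
        solve diverges."""
        u0, p0 = self.solver.u.copy(), self.solver.p.copy()
        t0 = self.solver.t
        try:
            self.solver.step(dt)
        except FloatingPointError:
            if depth >= 3:
                raise
            self.solver.u, self.solver.p, self.solver.t = u0, p0, t0
            log.warning("flow step diverged at t=%.4g; retrying at dt/2", t0)
            self._flow_step_with_retry(dt / 2, depth + 1)
            self._flow_step_with_retry(dt / 2, depth + 1)

    # -- stepping ------------------------------------------------------------
    def run_cycle(self) -> dict:
        cfg = self.config.run
        T = self.waveform.period
        dt = T / cfg.steps_per_cycle
        t_wall0 = time.perf_counter()
        vol0 = self.ledger.volume_trace[-1][1] if self.ledger.volume_trace else 0.0
        for k in range(cfg.steps_per_cycle):
            q_out = self.solver.boundary_flow("tl_outlet")
            self._p_out = windkessel_step(q_out, self.wk, dt)
            self._flap_update(dt)
            self._flow_step_with_retry(dt)
            st = self.solver.state()
            if self.thrombosis_active:
                self.species = self.species_solver.step(
                    self.species, st.u, st.w, st.gamma_nodal, self.ledger, dt)
                self.solver.BP = self.species.BP
            if k % cfg.wss_every == 0:
                wss = np.zeros(len(self.mesh.edges))
                from .hemodynamics import wall_shear_stress
                wss[self.wall_edge_idx] = wall_shear_stress(
                    self.solver, self.wall_edge_idx)
                self.ledger.accumulate(wss, st.gamma_nodal, self.species.AP,
                                       st.mu_nodal, dt * cfg.wss_every)
            self.step_count += 1
            if cfg.output_every and self.step_count % cfg.output_every == 0:
                self._write_snapshot(st)
            self.traces.append({
                "t": self.solver.t,
                "inlet_velocity": inlet_velocity(
                    self.solver.t, self.waveform,
                    self.config.geometry.tl_width * 1e-3),
                "outlet_pressure": self._p_out,
                "q_out": q_out,
                "max_disp_mm": float(np.max(np.abs(self._relaxed_disp)) * 1e3),
                **{f"dp_{k2}": v for k2, v in
                   (post.cut_plane_dp(self.mesh, self.solver.p).items()
                    if self.mesh.y_levels_m else {})},
            })
        self.ledger.complete_cycle()
        ind, vol = thrombus_mask(self.species.BP, self.tparams.BP_t, self.ops)
        # FL-restricted volume: the primary comparative metric
        frac_cell = ind[self.mesh.tris].mean(axis=1)
        vol_fl = float(np.sum(frac_cell[self.masks["FL"]]
                              * self.ops.area[self.masks["FL"]])) * 1e6
        self.ledger.volume_trace.append(
            (self.solver.t, vol, vol_fl / self.fl_volume_cm3))
        self.displacement_history.append(self._relaxed_disp.copy())
        self.cycle_max_disp.append(float(np.max(np.abs(self._relaxed_disp)) * 1e3))
        self.cycle += 1
        row = {
            "cycle": self.cycle,
            "t": self.solver.t,
            "thrombus_cm3": vol,
            "fl_thrombus_cm3": vol_fl,
            "fl_fraction": vol_fl / self.fl_volume_cm3,
            "growth_cm3": vol - vol0,
            "fl_growth_cm3": vol_fl - self._fl_vol_prev,
            "max_disp_mm": self.cycle_max_disp[-1],
            "wall_seconds": time.perf_counter() - t_wall0,
            "clip_events": self.species_solver.clip_events,
            "cfl": self.solver.log.get("cfl", 0.0),
            "mass_residual": self.solver.log.get("mass_residual", 0.0),
            "tawss_low_fraction": float(np.mean(
                self.ledger.tawss_prev[self.wall_edge_idx]
                < self.tparams.tawss_threshold)),
        }
        self._fl_vol_prev = vol_fl
        self.manifest.cycles.append(row)
        return row

    def _write_snapshot(self, st) -> None:
        outdir = Path(self.config.run.outdir)
        ind, _ = thrombus_mask(self.species.BP, self.tparams.BP_t, self.ops)
        write_vtk(outdir / f"snapshot_{self.step_count:07d}.vtk", self.mesh,
                  point_data={"u": st.u, "p": st.p, "mu": st.mu_nodal,
                              "gamma": st.gamma_nodal, "RP": self.species.RP,
                              "AP": self.species.AP, "C": self.species.C,
                              "BP": self.species.BP, "thrombus": ind,
                              "vorticity": post.vorticity_field(self.ops, st.u)},
                  cell_data={"lambda2": post.lambda2_field(self.ops, st.u)})

    # -- checkpointing -------------------------------------------------------
    def save_checkpoint(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(
            path,
            config_hash=self.manifest.config_hash,
            t=self.solver.t, cycle=self.cycle, step_count=self.step_count,
            u=self.solver.u, p=self.solver.p, w=self.solver.w,
            BP_sink=self.solver.BP, nodes=self.mesh.nodes,
            rp=self.species.RP, ap=self.species.AP, c=self.species.C,
            bp=self.species.BP, p_wk=self.wk.P_wk, p_out=self._p_out,
            tawss_prev=self.ledger.tawss_prev,
            relaxed_disp=self._relaxed_disp,
            load_filtered=self._load_filtered,
            fl_vol_prev=self._fl_vol_prev,
            volume_trace=np.asarray(self.ledger.volume_trace, float).reshape(-1, 3),
            thrombosis_active=self.thrombosis_active,
        )

    def load_checkpoint(self, path: str | Path) -> None:
        z = np.load(path, allow_pickle=False)
        if str(z["config_hash"]) != self.manifest.config_hash:
            raise ValueError("checkpoint was produced by a different config")
        self.solver.t = float(z["t"])
        self.cycle = int(z["cycle"])
        self.step_count = int(z["step_count"])
        self.solver.u = z["u"]
        self.solver.p = z["p"]
        self.solver.w = z["w"]
        self.solver.BP = z["BP_sink"]
        self.mesh.nodes = z["nodes"]
        self.solver.mesh_updated()
        self.species = SpeciesState(z["rp"], z["ap"], z["c"], z["bp"])
        self.wk.P_wk = float(z["p_wk"])
        self._p_out = float(z["p_out"])
        self.ledger.tawss_prev = z["tawss_prev"]
        self._relaxed_disp = z["relaxed_disp"]
        self._load_filtered = z["load_filtered"]
        self._fl_vol_prev = float(z["fl_vol_prev"])
        self.flap_state.displacement = self._relaxed_disp.copy()
        self.ledger.volume_trace = [tuple(r) for r in z["volume_trace"]]
        self.thrombosis_active = bool(z["thrombosis_active"])


def run(config: SimulationConfig) -> tuple[RunManifest, Simulation]:
    """Execute a full simulation per the configured protocol and write all
    outputs (traces CSV, per-cycle summary, manifest) to run.outdir."""
    sim = Simulation(config)
    cfg = config.run
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.save(outdir / "config.yaml")
    termination = "cycles done"
    try:
        for _ in range(cfg.pre_cycles):
            sim.run_cycle()
        sim.thrombosis_active = config.thrombosis.enabled
        for _ in range(cfg.cycles):
            row = sim.run_cycle()
            atomic_write_text(outdir / "manifest.json", sim.manifest.to_json())
            if cfg.checkpoint_every_cycles and \
                    sim.cycle % cfg.checkpoint_every_cycles == 0:
                sim.save_checkpoint(outdir / f"checkpoint_{sim.cycle:03d}.npz")
            if (sim.thrombosis_active
                    and row["fl_growth_cm3"] < cfg.growth_tolerance * sim.fl_volume_cm3
                    and row["fl_thrombus_cm3"] > 0):
                termination = "converged (no further growth)"
                break
    except Exception as exc:  # checkpoint for post-mortem, then re-raise
        sim.save_checkpoint(outdir / "checkpoint_abort.npz")
        sim.manifest.termination = f"error: {exc}"
        atomic_write_text(outdir / "manifest.json", sim.manifest.to_json())
        raise
    sim.manifest.termination = termination
    write_csv(outdir / "traces.csv", sim.traces)
    write_csv(outdir / "cycles.csv", sim.manifest.cycles)
    write_csv(outdir / "volume_trace.csv",
              [{"t": a, "volume_cm3": b, "fl_fraction": c}
               for a, b, c in sim.ledger.volume_trace])
    atomic_write_text(outdir / "manifest.json", sim.manifest.to_json())
    return sim.manifest, sim


def run_comparison(base: SimulationConfig,
                   presets: list[str] = ("rigid", "stiffer", "flexible")
                   ) -> dict:
    """Run each flap preset from the same base config; report plateau
    volumes, max displacements and the displacement-volume regression."""
    report: dict = {"runs": {}, "regression": None, "failures": {}}
    points = []
    for preset in presets:
        cfg = SimulationConfig.from_dict(base.to_dict())
        cfg.flap.preset = preset
        cfg.run.outdir = str(Path(base.run.outdir) / preset)
        try:
            manifest, sim = run(cfg)
        except Exception as exc:
            report["failures"][preset] = str(exc)
            continue
        trace = sim.ledger.volume_trace
        plateau = trace[-1][1] if trace else 0.0
        max_disp = max(sim.cycle_max_disp, default=0.0)
        report["runs"][preset] = {
            "plateau_cm3": plateau,
            "fl_fraction": trace[-1][2] if trace else 0.0,
            "max_disp_mm": max_disp,
            "termination": manifest.termination,
            "volume_trace": [list(r) for r in trace],
        }
        points.append((max_disp, plateau))
    if len(points) >= 2 and len({round(p[0], 12) for p in points}) >= 2:
        report["regression"] = post.displacement_volume_regression(points)
    outdir = Path(base.run.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    atomic_write_text(outdir / "comparison.json",
                      json.dumps(report, indent=1, sort_keys=True))
    return report


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


def mini_dissection_config(outdir: str = "runs/mini") -> SimulationConfig:
    """Coarse desk-scale dissection case (< 5k cells) for minutes-scale
    end-to-end runs: same physics and constants, shorter extensions and a
    coarse mesh."""
    cfg = SimulationConfig()
    cfg.geometry = DissectionGeometry(
        dissected_length=200.0, inlet_extension=10.0, outlet_extension=10.0)
    cfg.mesh.target_edge_length = 2.5
    cfg.run.steps_per_cycle = 400
    cfg.run.pre_cycles = 1
    cfg.run.cycles = 8
    cfg.run.outdir = outdir
    return cfg


def manufactured_solution() -> dict:
    """Analytic fields for the advection-diffusion convergence study:
    c(x, y, t) = exp(-t) sin(pi x) sin(pi y) on [0,1]^2 with uniform
    velocity (ax, ay); returns callables for c and the matching source."""
    ax, ay = 0.7, 0.3
    D = 1e-2

    def c(x, y, t):
        return np.exp(-t) * np.sin(np.pi * x) * np.sin(np.pi * y)

    def source(x, y, t):
        e = np.exp(-t)
        s, cx = np.sin, np.cos
        return e * (
            -s(np.pi * x) * s(np.pi * y)
            + ax * np.pi * cx(np.pi * x) * s(np.pi * y)
            + ay * np.pi * s(np.pi * x) * cx(np.pi * y)
            + 2 * D * np.pi**2 * s(np.pi * x) * s(np.pi * y)
        )

    return {"velocity": (ax, ay), "diffusivity": D, "c": c, "source": source}


def generate_fixtures(kind: str, outdir: str | Path = "fixtures") -> Path:
    """Write the named deterministic fixture for the test suite.

    Kinds: benchmark_channel, manufactured_solution, frozen_flow_thrombosis,
    mini_dissection.  Re-invocation produces byte-identical files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if kind == "benchmark_channel":
        mesh = benchmark_channel(10.0, 1.0, 0.1)
        write_vtk(outdir / "benchmark_channel.vtk", mesh)
        return outdir / "benchmark_channel.vtk"
    if kind == "manufactured_solution":
        ms = manufactured_solution()
        meta = {"velocity": list(ms["velocity"]), "diffusivity": ms["diffusivity"],
                "form": "c = exp(-t) sin(pi x) sin(pi y)"}
        p = outdir / "manufactured_solution.json"
        atomic_write_text(p, json.dumps(meta, indent=1, sort_keys=True))
        return p
    if kind == "frozen_flow_thrombosis":
        # stored Poiseuille-like velocity/shear field on a channel mesh so
        # the thrombosis module is testable without the flow solver
        mesh = benchmark_channel(20.0, 2.0, 0.25)
        W = 2.0e-3
        y = mesh.nodes[:, 1]
        u = 6 * 0.05 * (y / W) * (1 - y / W)
        gamma = np.abs(6 * 0.05 / W * (1 - 2 * y / W))
        rows = [{"x": float(x), "y": float(yy), "u": float(uu), "v": 0.0,
                 "gamma": float(g)}
                for (x, yy), uu, g in zip(mesh.nodes, u, gamma)]
        p = outdir / "frozen_flow_thrombosis.csv"
        write_csv(p, rows)
        write_vtk(outdir / "frozen_flow_mesh.vtk", mesh)
        return p
    if kind == "mini_dissection":
        cfg = mini_dissection_config()
        domain = build_dissection_geometry(cfg.geometry)
        mesh = generate_mesh(domain, cfg.mesh.target_edge_length)
        write_vtk(outdir / "mini_dissection.vtk", mesh)
        cfg.save(outdir / "mini_dissection.yaml")
        return outdir / "mini_dissection.vtk"
    raise ValueError(f"unknown fixture kind: {kind!r}")
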