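"""Simulation orchestration: a full heartbeat with moving walls and valve.

Couples the geometry, valve dynamics, flow solver, scalar transport and
metrics into one time loop.  The standard measurement protocol simulates a
startup cycle (systole + diastole), marks the ventricular blood at end
systole, and continues through the next systole so that the regurgitation
metrics come from a flow-developed systole and the residual volume is
measured one full cycle after marking.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as vio
from .config import RunConfig
from .errors import SolverDivergenceError
from .geometry import (DILATED_LV, HEALTHY_LV, compose_domain,
                       dilated_waveform, healthy_waveform, interpolate_valve,
                       make_lv_surface, make_mv_family)
from .immersed import (FLUID, SurfaceSampler, bin_surface,
                       face_boundary_conditions, tag_immersed_cells)
from .metrics import (annulus_flow, build_report, extract_orifice, mvo_area,
                      old_blood_flow, orifice_flow)
from .sampling import sample_scalar, sample_velocity
from .scalar import init_marker, lv_fluid_volume, residual_volume
from .solver import (FlowState, MaskedPoisson, PoissonSolver,
                     StaggeredGrid, advance, stable_dt)
from .valve_dynamics import (AorticValveState, ValveState,
                             update_aortic_valve, valve_rates)

#: cap on leaflet angular rates (rad/s); a full swing in ~30 ms, the scale
#: of physiologic valve closure -- regularizes the inertia-free model
RATE_MAX = 60.0

log = logging.getLogger("ventriflow")

HALF_PI = 0.5 * np.pi


class Simulation:
    """One configured case: geometry, flow state and measurement series."""

    def __init__(self, config: RunConfig):
        self.config = config
        gc = config.geometry
        period = config.physics.period
        self.waveform = (healthy_waveform(period) if gc.lv == "healthy"
                         else dilated_waveform(period))
        shape = HEALTHY_LV if gc.lv == "healthy" else DILATED_LV
        self.lv = make_lv_surface(shape, self.waveform, gc.lv_n_theta, gc.lv_n_s)
        self.family = make_mv_family(gc.mv, gc.severity, gc.mv_n_theta,
                                     gc.mv_n_s, base_z=self.lv.base_z)
        gr = config.grid
        self.domain = compose_domain(self.lv, self.family,
                                     pad_xy=gr.pad_xy, pad_bottom=gr.pad_bottom,
                                     tube_height=gr.tube_height)
        self.grid = StaggeredGrid(self.domain.box_lo, self.domain.box_hi,
                                  gr.nx, gr.ny, gr.nz, gr.z_mode)
        self.poisson = PoissonSolver(self.grid)
        self.nu = config.physics.nu
        self.kappa = (config.physics.kappa if config.physics.kappa is not None
                      else self.nu)
        h = min(self.grid.hx, self.grid.hy, self.grid.hz)
        self._h = h
        self._lv_sampler = SurfaceSampler(self.lv.at(0.0), h)
        ant, post = interpolate_valve(self.family, 0.0, 0.0)
        self._ant_sampler = SurfaceSampler(ant, h)
        self._post_sampler = SurfaceSampler(post, h)
        self._static = [bin_surface(self.grid, SurfaceSampler(s, h), s)
                        for s in (self.domain.basal_surface,
                                  self.domain.atrium_tube,
                                  self.domain.aorta_tube)]
        self._av_plate = bin_surface(self.grid,
                                     SurfaceSampler(self.domain.av_plate, h),
                                     self.domain.av_plate)
        self.valve = ValveState()
        self.av = AorticValveState(False)
        self._prev_rates = np.zeros(2)
        self.state = FlowState.zeros(self.grid)
        self.eoa = mvo_area(extract_orifice(interpolate_valve(self.family, 0, 0)))
        self._leaflets = None
        self._retag(self.state, 0.0)
        self._rows: list[dict] = []
        self.marked = False
        self.mark_time: float | None = None
        self.mark_ref_volume: float | None = None
        self.measure_time: float | None = None
        self.residual: float | None = None
        self.n_steps = 0
        self._record_row()

    # -- geometry tagging ------------------------------------------------

    def _retag(self, state: FlowState, t: float) -> None:
        ant, post = interpolate_valve(self.family, self.valve.phi1,
                                      self.valve.phi2,
                                      rates=(self.valve.dphi1, self.valve.dphi2))
        ant.name, post.name = "mv_anterior", "mv_posterior"
        self._leaflets = (ant, post)
        surfs = [(self._lv_sampler, self.lv.at(t)),
                 (self._ant_sampler, ant), (self._post_sampler, post)]
        surfs += self._static
        if not self.av.open:
            surfs.append(self._av_plate)
        mask, bvel, prio = tag_immersed_cells(self.grid, surfs,
                                              return_priority=True)
        # discrete geometric conservation: rescale the ventricle-wall
        # velocities so the staircase wall sweeps exactly dV/dt
        from .immersed import PRIORITY, prescribed_flux_into_fluid
        lv_cells = prio == PRIORITY["lv_wall"]
        f_wall = prescribed_flux_into_fluid(self.grid, mask, bvel, lv_cells)
        target = -float(self.waveform.dvolume_dt(t))
        if abs(f_wall) > 1.0 and abs(target) > 1.0:
            lam = np.clip(target / f_wall, 0.5, 2.0)
            bvel[lv_cells] *= lam
        state.mask, state.bvel = mask, bvel
        state.face_bc = face_boundary_conditions(mask, bvel)
        old = getattr(state, "masked_poisson", None)
        mp = MaskedPoisson(self.grid, self.poisson, mask == FLUID,
                           state.face_bc)
        if old is not None:
            mp.last_phi = old.last_phi  # warm start across retags
        state.masked_poisson = mp

    # -- valve/flow coupling ---------------------------------------------

    def _fluid_sampler_of(self, state: FlowState):
        def sampler(points, **_):
            return sample_velocity(state, points)
        return sampler

    def _fluid_cell_weight(self, state: FlowState, points: np.ndarray
                           ) -> np.ndarray:
        """1.0 where a point lies in a genuine fluid cell, else 0."""
        g = self.grid
        idx = np.floor((points - g.lo) / np.array([g.hx, g.hy, g.hz])
                       ).astype(np.int64)
        idx[:, 0] %= g.nx
        idx[:, 1] %= g.ny
        idx[:, 2] = np.clip(idx[:, 2], 0, g.nz - 1)
        return (state.mask[idx[:, 0], idx[:, 1], idx[:, 2]] == FLUID
                ).astype(float)

    def _valve_sampler_of(self, flow: FlowState):
        """Leaflet-context sampler for the valve model.

        Samples the velocity field off the leaflet surface (both sides,
        along the normal) and keeps only samples that land in fluid cells,
        so the model sees the evolved flow, never its own forced boundary
        layer.
        """
        from .valve_dynamics import _leaflet_quadrature

        def sampler(points, state=None, leaflet=None):
            if state is None or leaflet is None:
                return sample_velocity(flow, points)
            _, ndA, _ = _leaflet_quadrature(self.family,
                                            (state.phi1, state.phi2), leaflet)
            mag = np.linalg.norm(ndA, axis=-1, keepdims=True)
            n = ndA / np.maximum(mag, 1e-300)
            vsum = np.zeros_like(points)
            wsum = np.zeros(len(points))
            for sgn in (+1.0, -1.0):
                for k in (1.5, 2.5):
                    pts = points + sgn * k * self._h * n
                    w = self._fluid_cell_weight(flow, pts)
                    vsum += w[:, None] * sample_velocity(flow, pts)
                    wsum += w
            return vsum / np.maximum(wsum, 1.0)[:, None]

        return sampler

    def _plane_flux(self, center, radius: float) -> float:
        """Discrete upward face flux through the basal plane inside a disk.

        Sums the staggered w-faces of the face layer at the basal plane over
        columns within the disk; this is the exact flux the solver transports
        across the plane (midpoint quadrature on the faces themselves).
        """
        g = self.grid
        k = int(round((self.domain.base_z - g.lo[2]) / g.hz))
        k = min(max(k, 0), g.nz)
        xc, yc = g.xc(), g.yc()
        inside = ((xc[:, None] - center[0]) ** 2
                  + (yc[None, :] - center[1]) ** 2) <= radius ** 2
        return float(self.state.w[:, :, k][inside].sum() * g.hx * g.hy)

    def _aortic_outflow_velocity(self) -> float:
        ao = self.domain.aortic
        z = self.domain.base_z + 1.5 * self.grid.hz
        q = annulus_flow(self._fluid_sampler_of(self.state), ao.center,
                         0.8 * ao.radius, z, normal=(0, 0, 1))
        return q / (np.pi * (0.8 * ao.radius) ** 2)

    def step(self, dt: float | None = None) -> float:
        tc = self.config.time
        if dt is None:
            dt = tc.dt_fixed or stable_dt(self.state, self.nu, tc.cfl_max,
                                          tc.dt_max)
        for ev in (self.mark_time, self.measure_time):
            if ev is not None and self.state.t < ev - 1e-12 \
                    and self.state.t + dt > ev:
                dt = ev - self.state.t
        if dt < 1e-7:
            raise SolverDivergenceError(
                f"time step collapsed to {dt:.2e} s at t = {self.state.t:.4f}")
        self.av = update_aortic_valve(self.valve,
                                      self._aortic_outflow_velocity(),
                                      previous=self.av)
        phi0 = self.valve.angles
        stage_rates = {}

        in_systole = bool(self.waveform.in_systole(self.state.t))

        def pre_stage(istage, state, _dt):
            if istage > 0:
                # reuse the step's rates: the under-relaxed valve coupling
                # is first-order anyway and the solve is a cost center
                stage_rates[istage] = stage_rates[0]
                return
            r = np.array(valve_rates(self.family, self.valve,
                                     self._valve_sampler_of(state),
                                     rate_max=RATE_MAX))
            # under-relax against the previous step's rates: damps the
            # acoustic-like flutter of the inertia-free leaflet coupled to
            # the explicit flow update
            r = 0.5 * r + 0.5 * self._prev_rates
            if in_systole:
                # systolic ratchet: the model carries no transvalvular
                # pressure force, so once ventricular pressure has shut a
                # leaflet it must not be reopened by local recirculation;
                # closure (negative rates) stays fully flow-driven
                r = np.minimum(r, 0.0)
            self._prev_rates = r
            stage_rates[istage] = r

        weights = ((1.0, 0.0), (0.25, 0.75), (2.0 / 3.0, 1.0 / 3.0))

        def stage_hook(istage, state, ddt):
            r = stage_rates[istage]
            wnew, wold = weights[istage]
            phi = self.valve.angles
            phinew = np.clip(wnew * (phi + ddt * r) + wold * phi0, 0.0, HALF_PI)
            # a leaflet held at a stop is not moving: its surface velocity
            # (used for the immersed-boundary forcing) must be zero there
            reff = r.copy()
            for k in range(2):
                if (phinew[k] <= 0.0 and r[k] < 0) or \
                        (phinew[k] >= HALF_PI and r[k] > 0):
                    reff[k] = 0.0
            self.valve = ValveState(float(phinew[0]), float(phinew[1]),
                                    float(reff[0]), float(reff[1]))

        advance(self.state, dt, self.nu, self.poisson,
                retag=self._retag, cfl_max=max(tc.cfl_max * 2.0, 1.0),
                scalar_kappa=self.kappa if self.marked else None,
                pre_stage=pre_stage, stage_hook=stage_hook,
                filter_eps=0.01)
        self.n_steps += 1
        self._handle_events()
        self._record_row()
        return dt

    def _handle_events(self) -> None:
        t = self.state.t
        if (self.mark_time is not None and not self.marked
                and t >= self.mark_time - 1e-9):
            init_marker(self.state, self.domain.base_z, self.waveform)
            self.mark_ref_volume = lv_fluid_volume(self.state, self.domain.base_z)
            self.marked = True
            log.info("marker initialized at t=%.4f, LV volume %.2f cm^3",
                     t, self.mark_ref_volume)
        if (self.measure_time is not None and self.residual is None
                and t >= self.measure_time - 1e-9):
            self.residual = residual_volume(self.state, self.domain.base_z,
                                            self.mark_ref_volume)
            log.info("residual volume %.1f %% at t=%.4f",
                     100 * self.residual, t)

    def run(self, until: float, outdir: Path | None = None) -> None:
        oc = self.config.output
        while self.state.t < until - 1e-10:
            remaining = until - self.state.t
            tc = self.config.time
            dt = tc.dt_fixed or stable_dt(self.state, self.nu, tc.cfl_max,
                                          tc.dt_max)
            taken = self.step(min(dt, remaining))
            if outdir is not None and oc.snapshot_every > 0 \
                    and self.n_steps % oc.snapshot_every == 0:
                vio.write_vtk_imagedata(
                    self.state, Path(outdir) / f"snap_{self.n_steps:06d}.vtk")
            if outdir is not None and oc.checkpoint_every > 0 \
                    and self.n_steps % oc.checkpoint_every == 0:
                self.save_checkpoint(Path(outdir) / f"chk_{self.n_steps:06d}.h5")
            if self.n_steps % 200 == 0:
                log.info("t=%.4f dt=%.2e phi=(%.2f, %.2f) AV=%s",
                         self.state.t, taken, self.valve.phi1,
                         self.valve.phi2, self.av.open)

    # -- measurements -----------------------------------------------------

    def _record_row(self) -> None:
        st = self.state
        t = st.t
        orif = extract_orifice(self._leaflets)
        fs = self._fluid_sampler_of(st)
        cs = lambda pts: sample_scalar(st, pts)  # noqa: E731
        zb = self.domain.base_z
        z_probe = zb + 0.75 * self.grid.hz
        fam = self.family
        qmv = orifice_flow(fs, orif)
        qmva = self._plane_flux(fam.annulus_center[:2], fam.annulus_radius)
        qlv = -self._plane_flux((0.0, 0.0), self.lv.base_radius)
        qold = old_blood_flow(fs, cs, orif) if self.marked else 0.0
        fluid = st.mask == FLUID
        cmin = float(st.C[fluid].min()) if fluid.any() else 0.0
        cmax = float(st.C[fluid].max()) if fluid.any() else 0.0
        self._rows.append(dict(
            t=t, mvo=mvo_area(orif), qmv=qmv, qmva=qmva, qlv=qlv,
            qmv_old=qold, dvdt=float(self.waveform.dvolume_dt(t)),
            phi1=self.valve.phi1, phi2=self.valve.phi2,
            dphi1=self.valve.dphi1, dphi2=self.valve.dphi2,
            av_open=float(self.av.open),
            systole=float(bool(self.waveform.in_systole(t))),
            c_min=cmin, c_max=cmax))

    def series(self) -> pd.DataFrame:
        return pd.DataFrame(self._rows)

    def save_checkpoint(self, path) -> None:
        mp = getattr(self.state, "masked_poisson", None)
        aux = {}
        if mp is not None and mp.last_phi is not None:
            aux["phi_warm"] = mp.last_phi
        aux["prev_rates"] = self._prev_rates
        vio.save_checkpoint(path, self.state, extra=dict(
            phi1=self.valve.phi1, phi2=self.valve.phi2,
            dphi1=self.valve.dphi1, dphi2=self.valve.dphi2,
            av_open=self.av.open, marked=self.marked,
            mark_ref_volume=self.mark_ref_volume,
            mark_time=self.mark_time, measure_time=self.measure_time,
            n_steps=self.n_steps), aux_fields=aux)

    def restore_checkpoint(self, path) -> None:
        state, extra, aux = vio.load_checkpoint(path)
        self.state = state
        self.valve = ValveState(extra["phi1"], extra["phi2"],
                                extra["dphi1"], extra["dphi2"])
        self.av = AorticValveState(extra["av_open"])
        self.marked = extra["marked"]
        self.mark_ref_volume = extra["mark_ref_volume"]
        self.mark_time = extra["mark_time"]
        self.measure_time = extra["measure_time"]
        self.n_steps = extra["n_steps"]
        self._prev_rates = np.asarray(aux.get("prev_rates", np.zeros(2)))
        self._retag(self.state, self.state.t)
        if "phi_warm" in aux:
            self.state.masked_poisson.last_phi = aux["phi_warm"]
        self._rows = [r for r in self._rows if r["t"] <= self.state.t + 1e-12]


@dataclass
class SimulationResult:
    """Handle returned by the run drivers."""

    series: pd.DataFrame
    report: object | None
    sim: Simulation | None


def run_report_case(config: RunConfig, washout: bool = True) -> SimulationResult:
    """Standard measurement protocol for one case.

    ``washout=True``: simulate startup systole + diastole, mark at end
    systole, continue through the second systole; regurgitation metrics come
    from the second systole and the residual volume one cycle after marking.
    ``washout=False``: a single systole from quiescent end diastole (used
    for severity sweeps).
    """
    sim = Simulation(config)
    wf = sim.waveform
    T, ts = wf.period, wf.t_sys
    if washout:
        sim.mark_time = ts
        sim.measure_time = ts + T
        sim.run(T + ts)
        sys_window = (T, T + ts)
        dia_window = (ts, T)
        vres = sim.residual
    else:
        sim.run(ts)
        sys_window = (0.0, ts)
        dia_window = None
        vres = None
    report = build_report(sim.series(), mva=sim.family.mva, eoa=sim.eoa,
                          sv=wf.sv, vresidual=vres,
                          sys_window=sys_window, dia_window=dia_window)
    return SimulationResult(sim.series(), report, sim)


def run_cycle(config: RunConfig) -> SimulationResult:
    """Run ``config.time.n_cycles`` heartbeats and report the last cycle.

    Marks the ventricular blood at the first end systole; with zero cycles
    an empty result is returned.
    """
    n = config.time.n_cycles
    if n == 0:
        return SimulationResult(pd.DataFrame(), None, None)
    sim = Simulation(config)
    wf = sim.waveform
    sim.mark_time = wf.t_sys
    sim.measure_time = wf.t_sys + wf.period
    sim.run(n * wf.period + (wf.t_sys if n == 1 else 0.0))
    last_sys = ((n - 1) * wf.period if n > 1 else wf.period,
                (n - 1) * wf.period + wf.t_sys if n > 1 else wf.period + wf.t_sys)
    report = build_report(sim.series(), mva=sim.family.mva, eoa=sim.eoa,
                          sv=wf.sv, vresidual=sim.residual,
                          sys_window=last_sys,
                          dia_window=(wf.t_sys, wf.period))
    return SimulationResult(sim.series(), report, sim)


def mass_balance_error(sim: Simulation) -> float:
    """|diastolic LV-annulus inflow - SV| / SV over the first diastole."""
    from .metrics import integrate_phase
    wf = sim.waveform
    vlva = integrate_phase(sim.series(), "diastole", "qlv",
                           (wf.t_sys, wf.period))
    return abs(vlva - wf.sv) / wf.sv


def severity_sweep(config: RunConfig, severities) -> pd.DataFrame:
    """Run a series of coaptation-defect severities (single-systole runs).

    Returns one row per severity with EOA/MVA and Vreg/SV (both %), for the
    proportionality analysis between structural and functional severity.
    """
    rows = []
    for sev in severities:
        cfg = config.model_copy(deep=True)
        cfg.geometry.severity = float(sev)
        res = run_report_case(cfg, washout=False)
        r = res.report
        rows.append(dict(severity=float(sev), eoa=r.eoa, mva=r.mva,
                         eoa_mva_pct=r.eoa_mva_pct, vreg=r.vreg,
                         vreg_sv_pct=r.vreg_sv_pct,
                         vreg_mva=r.vreg_mva, vreg_false=r.vreg_false))
    return pd.DataFrame(rows)


def write_outputs(result: SimulationResult, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if result.sim is not None:
        result.series.to_csv(outdir / "series.csv", index=False)
        cfg = result.sim.config
        (outdir / "manifest.json").write_text(json.dumps(dict(
            config=cfg.model_dump(),
            n_steps=result.sim.n_steps), indent=2))
    if result.report is not None:
        (outdir / "report.json").write_text(
            json.dumps(result.report.to_dict(), indent=2))
        pd.DataFrame([result.report.to_dict()]).to_csv(
            outdir / "report.csv", index=False)
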