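"""Staggered-grid solver: operators, Poisson, projection, time stepping."""

import numpy as np
import pytest

from ventriflow.errors import StepSizeError, WatertightnessError
from ventriflow.immersed import (BOUNDARY, EXTERIOR, FLUID, SurfaceSampler,
                                 face_boundary_conditions, tag_immersed_cells)
from ventriflow.solver import (FlowState, MaskedPoisson, PoissonSolver,
                               advance, build_grid, divergence,
                               kinetic_energy, project, project_masked,
                               rk3_step, solve_poisson, stable_dt)
from ventriflow.surfaces import StructuredSurface


def sphere_surface(radius=1.0, center=(0, 0, 0), n=48, velocity=None):
    th = np.linspace(0, 2 * np.pi, n + 1)
    ps = np.linspace(0, np.pi, n)
    T, P = np.meshgrid(th, ps, indexing="ij")
    pos = np.stack([np.sin(P) * np.cos(T), np.sin(P) * np.sin(T),
                    np.cos(P)], axis=-1) * radius + np.asarray(center, float)
    vel = None
    if velocity is not None:
        vel = np.broadcast_to(np.asarray(velocity, float), pos.shape).copy()
    return StructuredSurface(pos, vel, closed_theta=True)


class TestGrid:
    def test_spacings(self):
        g = build_grid((4.0, 4.0, 8.0), 32, 32, 64)
        assert g.hx == g.hy == g.hz == 0.125

    def test_face_coordinate_roundtrip(self):
        g = build_grid((2.0, 3.0, 4.0), 8, 12, 16)
        assert np.allclose(np.diff(g.xf()), g.hx)
        assert g.zf()[0] == g.lo[2]
        assert g.zf()[-1] == pytest.approx(g.hi[2])
        assert len(g.zf()) == g.nz + 1

    def test_box_volume(self):
        g = build_grid((2.0, 3.0, 4.0), 8, 8, 8)
        assert g.box_volume() == pytest.approx(24.0)
        assert g.cell_volume * 8 * 8 * 8 == pytest.approx(24.0)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            build_grid((1, 1, 1), 0, 4, 4)


class TestPoisson:
    def test_zero_rhs_gives_zero(self):
        g = build_grid((1.0, 1.0, 1.0), 8, 8, 8)
        assert np.abs(solve_poisson(g, np.zeros((8, 8, 8)))).max() == 0.0

    @pytest.mark.parametrize("z_mode", ["wall_open", "open_wall", "periodic"])
    def test_discrete_operator_inverted_exactly(self, z_mode, rng):
        n = 10
        g = build_grid((1.0, 1.3, 0.9), n, n, n, z_mode=z_mode)
        rhs = rng.standard_normal((n, n, n))
        if z_mode == "periodic":
            rhs -= rhs.mean()
        phi = solve_poisson(g, rhs)
        lap = (np.roll(phi, -1, 0) - 2 * phi + np.roll(phi, 1, 0)) / g.hx ** 2
        lap += (np.roll(phi, -1, 1) - 2 * phi + np.roll(phi, 1, 1)) / g.hy ** 2
        lz = np.zeros_like(phi)
        lz[:, :, 1:-1] = (phi[:, :, 2:] - 2 * phi[:, :, 1:-1]
                          + phi[:, :, :-2]) / g.hz ** 2
        if z_mode == "periodic":
            lz[:, :, 0] = (phi[:, :, 1] - 2 * phi[:, :, 0]
                           + phi[:, :, -1]) / g.hz ** 2
            lz[:, :, -1] = (phi[:, :, 0] - 2 * phi[:, :, -1]
                            + phi[:, :, -2]) / g.hz ** 2
        elif z_mode == "wall_open":
            lz[:, :, 0] = (phi[:, :, 1] - phi[:, :, 0]) / g.hz ** 2
            lz[:, :, -1] = (phi[:, :, -2] - 3 * phi[:, :, -1]) / g.hz ** 2
        else:
            lz[:, :, 0] = (phi[:, :, 1] - 3 * phi[:, :, 0]) / g.hz ** 2
            lz[:, :, -1] = (phi[:, :, -2] - phi[:, :, -1]) / g.hz ** 2
        assert np.abs(lap + lz - rhs).max() < 1e-10 * max(np.abs(rhs).max(), 1)

    def test_manufactured_solution_second_order(self):
        def err(n):
            g = build_grid((1.0, 1.0, 1.0), n, n, n)
            kx, kz = 2 * np.pi, np.pi / 2
            phi = (np.cos(kx * g.xc())[:, None, None]
                   * np.cos(kz * g.zc())[None, None, :]
                   * np.ones((1, n, 1)))
            sol = solve_poisson(g, -(kx ** 2 + kz ** 2) * phi)
            return np.abs(sol - phi).max()

        assert 3.5 < err(16) / err(32) < 4.5

    def test_projection_kills_divergence(self, rng):
        n = 16
        g = build_grid((1.0, 1.0, 1.0), n, n, n)
        st = FlowState.zeros(g)
        st.u = rng.standard_normal((n, n, n))
        st.v = rng.standard_normal((n, n, n))
        st.w = rng.standard_normal((n, n, n + 1))
        st.w[:, :, 0] = 0.0
        project(st, 1e-3, PoissonSolver(g))
        assert np.abs(divergence(st)).max() < 1e-8
        assert np.abs(st.w[:, :, 0]).max() == 0.0  # wall untouched


class TestTimeStepping:
    def test_rk3_third_order_on_linear_ode(self):
        errs = []
        for nst in (10, 20):
            y, dt = 1.0, 1.0 / nst
            for i in range(nst):
                y = rk3_step(y, lambda t, z: -z, i * dt, dt)
            errs.append(abs(y - np.exp(-1.0)))
        assert errs[0] / errs[1] == pytest.approx(8.0, rel=0.2)

    def test_zero_velocity_is_equilibrium(self):
        g = build_grid((1.0, 1.0, 1.0), 8, 8, 8)
        st = FlowState.zeros(g)
        advance(st, 1e-3, 0.04, PoissonSolver(g))
        assert np.abs(st.u).max() == 0.0
        assert np.abs(st.w).max() == 0.0

    def test_cfl_violation_raises(self):
        g = build_grid((1.0, 1.0, 1.0), 8, 8, 8)
        st = FlowState.zeros(g)
        st.u += 100.0
        with pytest.raises(StepSizeError):
            advance(st, 1.0, 0.04, PoissonSolver(g), cfl_max=0.5)

    def test_taylor_green_decay(self):
        # 2D Taylor-Green columns in a periodic box: KE ~ exp(-4 nu t)
        nu, n = 0.04, 32
        g = build_grid((2 * np.pi, 2 * np.pi, 2 * np.pi), n, n, n,
                       z_mode="periodic")
        st = FlowState.zeros(g)
        st.u = (np.sin(g.xf())[:, None, None] * np.cos(g.yc())[None, :, None]
                * np.ones((1, 1, n)))
        st.v = (-np.cos(g.xc())[:, None, None] * np.sin(g.yf())[None, :, None]
                * np.ones((1, 1, n)))
        ps = PoissonSolver(g)
        e0 = kinetic_energy(st)
        t_end = 0.1
        while st.t < t_end - 1e-12:
            dt = min(stable_dt(st, nu, 0.5, 1.0), t_end - st.t)
            advance(st, dt, nu, ps, cfl_max=1.0)
        ratio = kinetic_energy(st) / e0
        assert ratio == pytest.approx(np.exp(-4 * nu * t_end), rel=1e-2)
        assert np.abs(divergence(st)).max() < 1e-8

    def test_unforced_energy_decays_monotonically(self, rng):
        nu, n = 0.1, 16
        g = build_grid((2 * np.pi,) * 3, n, n, n, z_mode="periodic")
        st = FlowState.zeros(g)
        st.u = rng.standard_normal((n, n, n))
        st.v = rng.standard_normal((n, n, n))
        st.w[:, :, :-1] = rng.standard_normal((n, n, n))
        st.w[:, :, -1] = st.w[:, :, 0]
        ps = PoissonSolver(g)
        project(st, 1e-3, ps)
        energies = [kinetic_energy(st)]
        for _ in range(20):
            advance(st, stable_dt(st, nu, 0.4, 5e-3), nu, ps, cfl_max=1.0)
            energies.append(kinetic_energy(st))
        assert np.all(np.diff(energies) < 0)


class TestImmersedTagging:
    @pytest.fixture
    def grid(self):
        return build_grid(((-2.0, -2.0, -2.0), (2.0, 2.0, 2.0)), 32, 32, 32)

    def test_static_sphere_boundary_count(self, grid):
        s = sphere_surface(radius=1.0)
        mask, _ = tag_immersed_cells(
            grid, [(SurfaceSampler(s, grid.hx), s)], check_leaks=False)
        n_bound = int((mask == BOUNDARY).sum())
        # cut-cell count between area/h^2 and the sqrt(3) oblique-crossing
        # bound
        lo = 4 * np.pi / grid.hx ** 2
        hi = lo * np.sqrt(3)
        assert lo <= n_bound <= 1.1 * hi
        # interior classified as fluid, far corner as exterior
        c = grid.nx // 2
        assert mask[c, c, c] == FLUID
        assert mask[0, 0, 0] == EXTERIOR

    def test_holed_sphere_interior_becomes_exterior(self, grid):
        # a leaking enclosure is absorbed by the outside flood fill
        s = sphere_surface(radius=1.0)
        mask = np.ones((s.shape[0] - 1, s.shape[1] - 1), dtype=bool)
        mask[10:20, 20:30] = False
        s.facet_mask = mask
        tags, _ = tag_immersed_cells(
            grid, [(SurfaceSampler(s, grid.hx), s)], check_leaks=False)
        c = grid.nx // 2
        assert tags[c, c, c] == EXTERIOR

    def test_translating_sphere_velocity_on_boundary(self, grid):
        vel = (3.0, -1.0, 2.0)
        s = sphere_surface(radius=1.0, velocity=vel)
        mask, bvel = tag_immersed_cells(
            grid, [(SurfaceSampler(s, grid.hx), s)], check_leaks=False)
        b = mask == BOUNDARY
        assert np.abs(bvel[b] - np.asarray(vel)).max() < 1e-9

    def test_face_bc_from_mask(self, grid):
        s = sphere_surface(radius=1.0, velocity=(1.0, 0.0, 0.0))
        mask, bvel = tag_immersed_cells(
            grid, [(SurfaceSampler(s, grid.hx), s)], check_leaks=False)
        (mu, uval), _, (mw, wval) = face_boundary_conditions(mask, bvel)
        assert uval[mu].max() == pytest.approx(1.0)
        assert np.abs(wval[mw]).max() < 1e-9


class TestMaskedProjection:
    def test_moving_wall_flux_exits_through_opening(self, rng):
        """A contracting box (moving lid) must push its volume through an
        orifice, not through the walls: the masked projection conserves the
        prescribed wall flux."""
        n = 24
        g = build_grid(((-1.0, -1.0, 0.0), (1.0, 1.0, 2.0)), n, n, n)
        st = FlowState.zeros(g)
        mask = np.zeros((n, n, n), dtype=np.int8)
        # box walls: one-cell shell, open at the top center
        mask[0], mask[-1] = BOUNDARY, BOUNDARY
        mask[:, 0], mask[:, -1] = BOUNDARY, BOUNDARY
        mask[:, :, 0] = BOUNDARY
        lid = np.ones((n, n), dtype=bool)
        lid[n // 2 - 3:n // 2 + 3, n // 2 - 3:n // 2 + 3] = False
        mask[:, :, -1][lid] = BOUNDARY
        bvel = np.zeros((n, n, n, 3))
        bvel[:, :, 0, 2] = 1.0    # floor moving up at 1 cm/s
        st.mask = mask
        st.bvel = bvel
        st.face_bc = face_boundary_conditions(mask, bvel)
        from ventriflow.solver import impose_face_bc
        impose_face_bc(st)
        mp = MaskedPoisson(g, PoissonSolver(g), mask == FLUID, st.face_bc)
        project_masked(st, 1e-3, mp)
        fluid = mask == FLUID
        assert np.abs(divergence(st))[fluid].max() < 1e-4
        # flux out of the top opening ~ floor area * speed
        floor_flux = (n - 2) ** 2 * g.hx * g.hy * 1.0
        top_flux = st.w[:, :, -1][~lid].sum() * g.hx * g.hy
        assert top_flux == pytest.approx(floor_flux, rel=0.05)
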