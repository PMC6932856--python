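"""Incompressible Navier-Stokes on a staggered Cartesian grid.

Second-order centered finite differences on a uniform MAC grid, explicit
third-order Runge-Kutta (SSP) time stepping, and a fractional-step pressure
projection solved by FFT in the periodic x/y directions and a tridiagonal
solve along z.  Moving walls enter through direct forcing: cells cut by an
immersed surface carry the surface velocity (see :mod:`ventriflow.immersed`).

Box boundary conditions: periodic in x and y; along z either
``wall_open`` (zero normal velocity at the bottom face, zero pressure at the
open top face, the default -- the tubes vent through the top), the mirrored
``open_wall`` reading, or fully ``periodic`` (used for verification cases
without immersed bodies).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SolverDivergenceError, StepSizeError
from .immersed import BOUNDARY

Z_MODES = ("wall_open", "open_wall", "periodic")


@dataclass
class StaggeredGrid:
    """Uniform staggered grid over a rectangular box (cm)."""

    lo: np.ndarray
    hi: np.ndarray
    nx: int
    ny: int
    nz: int
    z_mode: str = "wall_open"

    def __post_init__(self) -> None:
        self.lo = np.asarray(self.lo, dtype=float)
        self.hi = np.asarray(self.hi, dtype=float)
        if self.nx <= 0 or self.ny <= 0 or self.nz <= 0:
            raise ValueError("cell counts must be positive")
        if np.any(self.hi <= self.lo):
            raise ValueError("box must have positive extent")
        if self.z_mode not in Z_MODES:
            raise ValueError(f"z_mode must be one of {Z_MODES}")
        self.hx = (self.hi[0] - self.lo[0]) / self.nx
        self.hy = (self.hi[1] - self.lo[1]) / self.ny
        self.hz = (self.hi[2] - self.lo[2]) / self.nz

    # coordinate accessors ------------------------------------------------

    def xc(self):
        return self.lo[0] + (np.arange(self.nx) + 0.5) * self.hx

    def yc(self):
        return self.lo[1] + (np.arange(self.ny) + 0.5) * self.hy

    def zc(self):
        return self.lo[2] + (np.arange(self.nz) + 0.5) * self.hz

    def xf(self):
        """x faces: u[i] lives at xf[i] (left face of cell i)."""
        return self.lo[0] + np.arange(self.nx) * self.hx

    def yf(self):
        return self.lo[1] + np.arange(self.ny) * self.hy

    def zf(self):
        """z faces: w[..., k] lives at zf[k], k = 0..nz."""
        return self.lo[2] + np.arange(self.nz + 1) * self.hz

    @property
    def cell_volume(self) -> float:
        return self.hx * self.hy * self.hz

    def box_volume(self) -> float:
        return float(np.prod(self.hi - self.lo))


def build_grid(box, nx: int, ny: int, nz: int, z_mode: str = "wall_open") -> StaggeredGrid:
    """Build a staggered grid; ``box`` is (lo, hi) or (Lx, Ly, Lz) from 0."""
    box = np.asarray(box, dtype=float)
    if box.shape == (3,):
        lo, hi = np.zeros(3), box
    else:
        lo, hi = box
    return StaggeredGrid(lo, hi, nx, ny, nz, z_mode)


@dataclass
class FlowState:
    """Velocity/pressure/scalar state on a staggered grid.

    u, v are (nx, ny, nz) face-normal components (u[i] at the left x-face of
    cell i); w is (nx, ny, nz+1) with w[..., 0] the bottom box face.  p is
    the cell-centred kinematic pressure and C the passive-scalar
    concentration.  ``mask`` classifies cells fluid/boundary/exterior.
    """

    grid: StaggeredGrid
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    p: np.ndarray
    C: np.ndarray
    t: float = 0.0
    mask: np.ndarray | None = None
    bvel: np.ndarray | None = None
    face_bc: tuple | None = None

    @classmethod
    def zeros(cls, grid: StaggeredGrid, t: float = 0.0) -> "FlowState":
        nx, ny, nz = grid.nx, grid.ny, grid.nz
        return cls(grid, np.zeros((nx, ny, nz)), np.zeros((nx, ny, nz)),
                   np.zeros((nx, ny, nz + 1)), np.zeros((nx, ny, nz)),
                   np.zeros((nx, ny, nz)), t=t,
                   mask=np.zeros((nx, ny, nz), dtype=np.int8))

    def cfl(self, dt: float) -> float:
        g = self.grid
        return float((np.abs(self.u).max() / g.hx + np.abs(self.v).max() / g.hy
                      + np.abs(self.w).max() / g.hz) * dt)

    def copy(self) -> "FlowState":
        return FlowState(self.grid, self.u.copy(), self.v.copy(), self.w.copy(),
                         self.p.copy(), self.C.copy(), self.t,
                         None if self.mask is None else self.mask.copy(),
                         None if self.bvel is None else self.bvel.copy(),
                         self.face_bc)


# ----------------------------------------------------------------------
# finite-difference operators
# ----------------------------------------------------------------------

def _pad_z_center(a: np.ndarray, mode: str) -> np.ndarray:
    """Pad a cell-centred (in z) array with one ghost plane on each side."""
    if mode == "periodic":
        return np.concatenate([a[:, :, -1:], a, a[:, :, :1]], axis=2)
    # zero-gradient (free-slip) closure at both z ends for tangential comps
    return np.concatenate([a[:, :, :1], a, a[:, :, -1:]], axis=2)


def divergence(state: FlowState) -> np.ndarray:
    g = state.grid
    du = (np.roll(state.u, -1, axis=0) - state.u) / g.hx
    dv = (np.roll(state.v, -1, axis=1) - state.v) / g.hy
    dw = (state.w[:, :, 1:] - state.w[:, :, :-1]) / g.hz
    return du + dv + dw


def momentum_rhs(state: FlowState, nu: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """-(v . grad) v + nu lap v for the three staggered components.

    Advection uses the skew-symmetric form (average of the divergence and
    advective forms, realized as the central-flux divergence form minus half
    the face-interpolated velocity divergence), which keeps the discrete
    advection energy-neutral even where the boundary-cell layer leaves the
    field slightly non-solenoidal.
    """
    g = state.grid
    u, v, w = state.u, state.v, state.w
    hx, hy, hz = g.hx, g.hy, g.hz
    per_z = g.z_mode == "periodic"

    # helpers: cell-centred and corner averages
    def av(a, ax):          # a[i-1]+a[i] average toward lower index
        return 0.5 * (a + np.roll(a, 1, axis=ax))

    def avf(a, ax):         # a[i]+a[i+1] average toward upper index
        return 0.5 * (a + np.roll(a, -1, axis=ax))

    # z-face average of a z-centred array (result on nz+1 faces)
    def to_zface(a):
        ap = _pad_z_center(a, "periodic" if per_z else "zg")
        return 0.5 * (ap[:, :, :-1] + ap[:, :, 1:])

    # ---- u momentum ----
    ucc = avf(u, 0)                       # u at cell centres
    Fuu = ucc * ucc
    adv_u = (Fuu - np.roll(Fuu, 1, axis=0)) / hx
    u_cor = av(u, 1)                      # u at (face i, face j) corners
    v_cor = av(v, 0)
    G = u_cor * v_cor
    adv_u += (np.roll(G, -1, axis=1) - G) / hy
    u_zf = to_zface(u)                    # u averaged to z faces (nz+1)
    w_xf = av(w, 0)                       # w averaged to x faces
    H = u_zf * w_xf
    if not per_z and g.z_mode == "wall_open":
        H[:, :, 0] = 0.0                  # bottom wall: w = 0
    if not per_z and g.z_mode == "open_wall":
        H[:, :, -1] = 0.0
    adv_u += (H[:, :, 1:] - H[:, :, :-1]) / hz

    # ---- v momentum ----
    vcc = avf(v, 1)
    Fvv = vcc * vcc
    adv_v = (Fvv - np.roll(Fvv, 1, axis=1)) / hy
    Gv = av(u, 1) * av(v, 0)
    adv_v += (np.roll(Gv, -1, axis=0) - Gv) / hx
    v_zf = to_zface(v)
    w_yf = av(w, 1)
    Hv = v_zf * w_yf
    if not per_z and g.z_mode == "wall_open":
        Hv[:, :, 0] = 0.0
    if not per_z and g.z_mode == "open_wall":
        Hv[:, :, -1] = 0.0
    adv_v += (Hv[:, :, 1:] - Hv[:, :, :-1]) / hz

    # ---- w momentum (interior z faces; boundary faces handled by BC) ----
    u_zf = to_zface(u)
    Fwu = u_zf * av(w, 0)
    adv_w = (np.roll(Fwu, -1, axis=0) - Fwu) / hx
    Fwv = to_zface(v) * av(w, 1)
    adv_w += (np.roll(Fwv, -1, axis=1) - Fwv) / hy
    wcc = 0.5 * (w[:, :, :-1] + w[:, :, 1:])   # at cell centres, (nz,)
    Fww = wcc * wcc
    dFww = np.empty_like(w)
    dFww[:, :, 1:-1] = (Fww[:, :, 1:] - Fww[:, :, :-1]) / hz
    if per_z:
        dFww[:, :, 0] = (Fww[:, :, 0] - Fww[:, :, -1]) / hz
        dFww[:, :, -1] = dFww[:, :, 0]
    else:
        # boundary faces handled kinematically (wall: w = 0; open face:
        # zero-gradient before projection), no explicit update here
        dFww[:, :, 0] = 0.0
        dFww[:, :, -1] = 0.0
    adv_w += dFww

    # skew-symmetric form: average of divergence and advective forms, i.e.
    # div form minus half the face-interpolated velocity divergence times
    # the component -- energy-neutral even where the discrete field is not
    # exactly solenoidal (boundary-cell layer)
    D = divergence(state)
    adv_u -= 0.5 * u * 0.5 * (D + np.roll(D, 1, axis=0))
    adv_v -= 0.5 * v * 0.5 * (D + np.roll(D, 1, axis=1))
    Dw = np.zeros_like(w)
    Dw[:, :, 1:-1] = 0.5 * (D[:, :, :-1] + D[:, :, 1:])
    if per_z:
        Dw[:, :, 0] = 0.5 * (D[:, :, -1] + D[:, :, 0])
        Dw[:, :, -1] = Dw[:, :, 0]
    adv_w -= 0.5 * w * Dw

    lap_u = _laplacian_center_z(u, g, per_z)
    lap_v = _laplacian_center_z(v, g, per_z)
    lap_w = _laplacian_face_z(w, g, per_z)
    return (-adv_u + nu * lap_u, -adv_v + nu * lap_v, -adv_w + nu * lap_w)


def _laplacian_center_z(a: np.ndarray, g: StaggeredGrid, per_z: bool) -> np.ndarray:
    out = (np.roll(a, -1, axis=0) - 2 * a + np.roll(a, 1, axis=0)) / g.hx ** 2
    out += (np.roll(a, -1, axis=1) - 2 * a + np.roll(a, 1, axis=1)) / g.hy ** 2
    ap = _pad_z_center(a, "periodic" if per_z else "zg")
    out += (ap[:, :, 2:] - 2 * ap[:, :, 1:-1] + ap[:, :, :-2]) / g.hz ** 2
    return out


def _laplacian_face_z(w: np.ndarray, g: StaggeredGrid, per_z: bool) -> np.ndarray:
    out = (np.roll(w, -1, axis=0) - 2 * w + np.roll(w, 1, axis=0)) / g.hx ** 2
    out += (np.roll(w, -1, axis=1) - 2 * w + np.roll(w, 1, axis=1)) / g.hy ** 2
    lz = np.zeros_like(w)
    lz[:, :, 1:-1] = (w[:, :, 2:] - 2 * w[:, :, 1:-1] + w[:, :, :-2]) / g.hz ** 2
    if per_z:
        lz[:, :, 0] = (w[:, :, 1] - 2 * w[:, :, 0] + w[:, :, -2]) / g.hz ** 2
        lz[:, :, -1] = lz[:, :, 0]
    out += lz
    return out


# ----------------------------------------------------------------------
# Poisson solver (FFT in x/y, tridiagonal in z)
# ----------------------------------------------------------------------

class PoissonSolver:
    """lap(phi) = rhs with periodic x/y and the grid's z closure.

    ``wall_open``: Neumann at the bottom face, Dirichlet phi = 0 at the open
    top face (never singular).  ``open_wall`` mirrors this.  ``periodic``
    uses a 3D FFT with the mean mode pinned to zero.
    """

    def __init__(self, grid: StaggeredGrid):
        self.g = grid
        nx, ny = grid.nx, grid.ny
        kx = np.fft.fftfreq(nx) * nx
        ky = np.fft.rfftfreq(ny) * ny
        lx = (2 * np.cos(2 * np.pi * kx / nx) - 2) / grid.hx ** 2
        ly = (2 * np.cos(2 * np.pi * ky / ny) - 2) / grid.hy ** 2
        self.lam_xy = lx[:, None] + ly[None, :]         # (nx, ny//2+1)
        if grid.z_mode == "periodic":
            kxf = np.fft.fftfreq(nx) * nx
            kyf = np.fft.fftfreq(ny) * ny
            kzr = np.fft.rfftfreq(grid.nz) * grid.nz
            lxf = (2 * np.cos(2 * np.pi * kxf / nx) - 2) / grid.hx ** 2
            lyf = (2 * np.cos(2 * np.pi * kyf / ny) - 2) / grid.hy ** 2
            lzr = (2 * np.cos(2 * np.pi * kzr / grid.nz) - 2) / grid.hz ** 2
            self.lam_3d = (lxf[:, None, None] + lyf[None, :, None]
                           + lzr[None, None, :])
        else:
            hz2 = grid.hz ** 2
            nz = grid.nz
            diag = np.full(nz, -2.0 / hz2)
            if grid.z_mode == "wall_open":
                diag[0] = -1.0 / hz2    # Neumann bottom
                diag[-1] = -3.0 / hz2   # Dirichlet (face) top
            else:
                diag[0] = -3.0 / hz2
                diag[-1] = -1.0 / hz2
            self.diag = diag
            self.off = 1.0 / hz2

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        g = self.g
        if g.z_mode == "periodic":
            rh = np.fft.rfftn(rhs)
            lam = self.lam_3d.copy()
            lam[0, 0, 0] = 1.0
            rh /= lam
            rh[0, 0, 0] = 0.0
            return np.fft.irfftn(rh, s=rhs.shape, axes=(0, 1, 2))
        # Neumann-wall / Dirichlet-open-face closure along z diagonalizes in
        # the DCT-IV basis cos((j+1/2)(k+1/2)pi/nz) (wall side at j = 0)
        from scipy.fft import dct
        flip = g.z_mode == "open_wall"
        if flip:
            rhs = rhs[:, :, ::-1]
        rh = np.fft.rfft2(rhs, axes=(0, 1))
        nz = g.nz
        th = (np.arange(nz) + 0.5) * np.pi / nz
        lam_z = (2 * np.cos(th) - 2) / g.hz ** 2
        rh = dct(rh, type=4, axis=2, norm="ortho")
        rh /= self.lam_xy[:, :, None] + lam_z[None, None, :]
        rh = dct(rh, type=4, axis=2, norm="ortho")
        phi = np.fft.irfft2(rh, s=rhs.shape[:2], axes=(0, 1))
        return phi[:, :, ::-1] if flip else phi


def solve_poisson(grid: StaggeredGrid, rhs: np.ndarray,
                  solver: PoissonSolver | None = None) -> np.ndarray:
    """One-shot Poisson solve (builds the solver if not supplied)."""
    return (solver or PoissonSolver(grid)).solve(rhs)


class MaskedPoisson:
    """Pressure Poisson operator restricted to the fluid region.

    Divergence is enforced on fluid cells only, and pressure corrections act
    only across open (fluid-fluid) faces, so prescribed wall velocities are
    Neumann boundaries of the projection: moving walls stay impermeable and
    the volume they displace exits through the orifices, not through the
    wall.  Solved by conjugate gradients preconditioned with the unmasked
    FFT solver; a fluid component sealed off from the open box face (both
    valves closed) gets its incompatible mean source removed, the discrete
    analogue of the pressure spike in a sealed chamber.
    """

    def __init__(self, grid: StaggeredGrid, base: PoissonSolver,
                 fluid: np.ndarray, face_bc):
        from scipy import ndimage
        self.g = grid
        self.base = base
        self.fluid = fluid
        (mu, _), (mv, _), (mw, _) = face_bc
        self.cx = (~mu & fluid & np.roll(fluid, 1, axis=0)) / grid.hx ** 2
        self.cy = (~mv & fluid & np.roll(fluid, 1, axis=1)) / grid.hy ** 2
        cz = ~mw[:, :, 1:-1] & fluid[:, :, 1:] & fluid[:, :, :-1]
        self.cz = cz / grid.hz ** 2
        if grid.z_mode == "wall_open":
            self.top_open = fluid[:, :, -1] & ~mw[:, :, -1]
            self.bot_open = np.zeros_like(self.top_open)
        else:
            self.bot_open = fluid[:, :, 0] & ~mw[:, :, 0]
            self.top_open = np.zeros_like(self.bot_open)
        # sealed fluid components (no open box face): remove the null-space
        # source so the system stays compatible
        labels, nlab = ndimage.label(fluid)
        open_cells = np.zeros_like(fluid)
        open_cells[:, :, -1] = self.top_open
        open_cells[:, :, 0] |= self.bot_open
        open_labels = set(np.unique(labels[open_cells])) - {0}
        sealed = [lab for lab in range(1, nlab + 1) if lab not in open_labels]
        self.sealed_masks = [labels == lab for lab in sealed]
        self.last_phi: np.ndarray | None = None

    def apply(self, phi: np.ndarray) -> np.ndarray:
        g = self.g
        cx, cy, cz = self.cx, self.cy, self.cz
        out = cx * (np.roll(phi, 1, axis=0) - phi)
        out += np.roll(cx, -1, axis=0) * (np.roll(phi, -1, axis=0) - phi)
        out += cy * (np.roll(phi, 1, axis=1) - phi)
        out += np.roll(cy, -1, axis=1) * (np.roll(phi, -1, axis=1) - phi)
        dz = phi[:, :, :-1] - phi[:, :, 1:]
        out[:, :, 1:] += cz * dz
        out[:, :, :-1] -= cz * dz
        out[:, :, -1] -= self.top_open * 2.0 * phi[:, :, -1] / g.hz ** 2
        out[:, :, 0] -= self.bot_open * 2.0 * phi[:, :, 0] / g.hz ** 2
        return np.where(self.fluid, out, phi)

    def solve(self, rhs: np.ndarray, rtol: float = 1e-7,
              maxiter: int = 400) -> np.ndarray:
        fluid = self.fluid
        rhs = np.where(fluid, rhs, 0.0)
        for sm in self.sealed_masks:
            rhs[sm] -= rhs[sm].mean()
        x = np.zeros_like(rhs) if self.last_phi is None else self.last_phi.copy()
        r = rhs - self.apply(x)
        norm0 = np.sqrt((rhs * rhs).sum())
        if norm0 == 0.0:
            return x * 0.0
        z = np.where(fluid, self.base.solve(np.where(fluid, r, 0.0)), 0.0)
        p = z
        rz = (r * z).sum()
        self.last_iters = 0
        for self.last_iters in range(maxiter):
            rn = np.sqrt((r * r)[fluid].sum())
            if rn <= rtol * norm0:
                break
            Ap = self.apply(p)
            pap = (p * Ap).sum()
            if pap == 0.0:
                break
            al = rz / pap
            x = x + al * p
            r = r - al * Ap
            z = np.where(fluid, self.base.solve(np.where(fluid, r, 0.0)), 0.0)
            rz2 = (r * z).sum()
            p = z + (rz2 / rz) * p
            rz = rz2
        self.last_phi = x
        return x


def project_masked(state: FlowState, dt: float, mp: MaskedPoisson,
                   rtol: float = 1e-7) -> None:
    """Masked fractional-step projection (corrections on open faces only)."""
    g = state.grid
    div = divergence(state)
    phi = mp.solve(div / dt, rtol=rtol)
    hx2cx = mp.cx > 0
    state.u -= dt * np.where(hx2cx, (phi - np.roll(phi, 1, axis=0)) / g.hx, 0.0)
    state.v -= dt * np.where(mp.cy > 0, (phi - np.roll(phi, 1, axis=1)) / g.hy, 0.0)
    gz = (phi[:, :, 1:] - phi[:, :, :-1]) / g.hz
    state.w[:, :, 1:-1] -= dt * np.where(mp.cz > 0, gz, 0.0)
    state.w[:, :, -1] -= dt * np.where(mp.top_open, -2.0 * phi[:, :, -1] / g.hz, 0.0)
    state.w[:, :, 0] -= dt * np.where(mp.bot_open, 2.0 * phi[:, :, 0] / g.hz, 0.0)
    state.p = phi / dt


def project(state: FlowState, dt: float, solver: PoissonSolver) -> None:
    """Fractional-step projection: make the velocity discretely solenoidal."""
    g = state.grid
    div = divergence(state)
    phi = solver.solve(div / dt)
    gx = (phi - np.roll(phi, 1, axis=0)) / g.hx
    gy = (phi - np.roll(phi, 1, axis=1)) / g.hy
    state.u -= dt * gx
    state.v -= dt * gy
    gzi = (phi[:, :, 1:] - phi[:, :, :-1]) / g.hz
    state.w[:, :, 1:-1] -= dt * gzi
    if g.z_mode == "periodic":
        gz0 = (phi[:, :, 0] - phi[:, :, -1]) / g.hz
        state.w[:, :, 0] -= dt * gz0
        state.w[:, :, -1] = state.w[:, :, 0]
    elif g.z_mode == "wall_open":
        # Dirichlet phi=0 at the top face: ghost = -phi[-1]
        state.w[:, :, -1] -= dt * (-2.0 * phi[:, :, -1]) / g.hz
        # bottom face: wall, no correction (Neumann)
    else:  # open_wall
        state.w[:, :, 0] -= dt * (2.0 * phi[:, :, 0]) / g.hz
    state.p = phi / dt


def impose_face_bc(state: FlowState) -> None:
    if state.face_bc is None:
        return
    (mu, uval), (mv, vval), (mw, wval) = state.face_bc
    state.u[mu] = uval[mu]
    state.v[mv] = vval[mv]
    state.w[mw] = wval[mw]
    if state.grid.z_mode == "wall_open":
        state.w[:, :, 0] = 0.0
    elif state.grid.z_mode == "open_wall":
        state.w[:, :, -1] = 0.0


# ----------------------------------------------------------------------
# time stepping
# ----------------------------------------------------------------------

#: SSP-RK3 (Shu-Osher) convex combinations: y1 = y + dt f(y);
#: y2 = 3/4 y + 1/4 (y1 + dt f(y1)); y3 = 1/3 y + 2/3 (y2 + dt f(y2)).
SSP_WEIGHTS = ((1.0, 0.0), (0.25, 0.75), (2.0 / 3.0, 1.0 / 3.0))
SSP_STAGE_TIMES = (0.0, 1.0, 0.5)


def rk3_step(y, f, t, dt):
    """Generic SSP-RK3 step for dy/dt = f(t, y) (third-order accurate)."""
    y1 = y + dt * f(t, y)
    y2 = 0.75 * y + 0.25 * (y1 + dt * f(t + dt, y1))
    return y / 3.0 + 2.0 / 3.0 * (y2 + dt * f(t + 0.5 * dt, y2))


def advance(state: FlowState, dt: float, nu: float,
            solver: PoissonSolver,
            retag=None, cfl_max: float = 0.9,
            scalar_kappa: float | None = None,
            pre_stage=None, stage_hook=None,
            filter_eps: float | None = None) -> FlowState:
    """One RK3 step of the flow (and optionally the passive scalar).

    Parameters
    ----------
    retag : callable(state, stage_time) -> None, optional
        Re-imposes the immersed-boundary mask/face constraints for the stage
        time (moving geometry); also expected to refresh ``state.face_bc``.
    pre_stage : callable(stage_index, state, dt), optional
        Called before the stage's right-hand side is evaluated (used to
        sample valve rates from the same stage velocity as the momentum
        update).
    stage_hook : callable(stage_index, state, dt), optional
        Called after the velocity combination, before retagging/projection
        (used to apply the valve-angle Runge-Kutta combination).
    """
    if dt <= 0:
        raise StepSizeError("dt must be positive")
    if state.cfl(dt) > cfl_max + 1e-12:
        raise StepSizeError(f"CFL {state.cfl(dt):.3f} exceeds {cfl_max}")
    from .scalar import extend_into_boundary, scalar_rhs  # avoid an import cycle

    g = state.grid
    t0 = state.t
    old = (state.u.copy(), state.v.copy(), state.w.copy(), state.C.copy())
    for istage, ((wnew, wold), ct) in enumerate(zip(SSP_WEIGHTS, SSP_STAGE_TIMES)):
        if pre_stage is not None:
            pre_stage(istage, state, dt)
        ru, rv, rw = momentum_rhs(state, nu)
        fu = state.u + dt * ru
        fv = state.v + dt * rv
        fw = state.w.copy()
        fw[:, :, 1:-1] += dt * rw[:, :, 1:-1]
        if g.z_mode == "periodic":
            fw[:, :, 0] += dt * rw[:, :, 0]
            fw[:, :, -1] = fw[:, :, 0]
        elif g.z_mode == "wall_open":
            fw[:, :, -1] = fw[:, :, -2]   # zero-gradient at the open face
        else:
            fw[:, :, 0] = fw[:, :, 1]
        if scalar_kappa is not None:
            if state.mask is not None and (state.mask == BOUNDARY).any():
                extend_into_boundary(state)
            rc = scalar_rhs(state, scalar_kappa)
            fc = state.C + dt * rc
        state.u = wnew * fu + wold * old[0]
        state.v = wnew * fv + wold * old[1]
        state.w = wnew * fw + wold * old[2]
        if scalar_kappa is not None:
            state.C = np.clip(wnew * fc + wold * old[3], 0.0, 1.0)
        if filter_eps and istage == 2:
            # low-pass the provisional velocity before the final projection
            # so the projected field is both filtered and solenoidal
            filter_velocity(state, filter_eps)
        stage_t = t0 + dt  # geometry evaluated at the stage's target time
        if istage == 1:
            stage_t = t0 + 0.5 * dt
        if stage_hook is not None:
            stage_hook(istage, state, dt)
        if retag is not None and istage == 0:
            # tag once per step at the end-of-step geometry: the boundary
            # moves a small fraction of a cell per step, and the cut-cell
            # representation is itself O(h)
            retag(state, t0 + dt)
        impose_face_bc(state)
        mp = getattr(state, "masked_poisson", None)
        if mp is not None:
            # masked projection: corrections act on open faces only, so the
            # prescribed wall velocities survive and the displaced volume
            # exits through the orifices.  The iterative solve is the cost
            # center: intermediate stages use a looser tolerance, the final
            # stage a tight one.
            project_masked(state, dt, mp,
                           rtol=1e-7 if istage == 2 else 3e-4)
        else:
            project(state, dt, solver)
        state.t = stage_t
    state.t = t0 + dt
    if not np.isfinite(state.u).all() or not np.isfinite(state.w).all():
        raise SolverDivergenceError(f"non-finite velocity at t = {state.t:.4f}")
    return state


def filter_velocity(state: FlowState, eps: float = 0.03) -> None:
    """Fourth-difference low-pass filter on the velocity components.

    Damps the two-grid-point mode by ~16 eps per direction per application
    while leaving well-resolved scales essentially untouched (attenuation
    scales as (kh)^4).  Used once per time step to keep marginally resolved
    jets stable under the otherwise non-dissipative central discretization;
    boundary conditions are re-imposed afterwards.
    """
    per_z = state.grid.z_mode == "periodic"

    def d4(a, axis):
        return (np.roll(a, 2, axis) - 4 * np.roll(a, 1, axis) + 6 * a
                - 4 * np.roll(a, -1, axis) + np.roll(a, -2, axis))

    for name in ("u", "v", "w"):
        a = getattr(state, name)
        out = a - eps * (d4(a, 0) + d4(a, 1))
        if per_z:
            out = out - eps * d4(a, 2)
        else:
            dz = np.zeros_like(a)
            dz[:, :, 2:-2] = (a[:, :, :-4] - 4 * a[:, :, 1:-3] + 6 * a[:, :, 2:-2]
                              - 4 * a[:, :, 3:-1] + a[:, :, 4:])
            out = out - eps * dz
        setattr(state, name, out)
    impose_face_bc(state)


def stable_dt(state: FlowState, nu: float, cfl_max: float = 0.5,
              dt_max: float = 2e-3) -> float:
    g = state.grid
    speed = (np.abs(state.u).max() / g.hx + np.abs(state.v).max() / g.hy
             + np.abs(state.w).max() / g.hz)
    dt_adv = cfl_max / speed if speed > 0 else np.inf
    dt_visc = 0.3 * min(g.hx, g.hy, g.hz) ** 2 / max(nu, 1e-12)
    return float(min(dt_adv, dt_visc, dt_max))


def kinetic_energy(state: FlowState) -> float:
    """Volume-integrated kinetic energy (cm^5/s^2)."""
    g = state.grid
    e = 0.5 * (np.sum(state.u ** 2) + np.sum(state.v ** 2))
    if g.z_mode == "periodic":
        e += 0.5 * np.sum(state.w[:, :, :-1] ** 2)
    else:
        e += 0.5 * np.sum(0.5 * (state.w[:, :, :-1] ** 2 + state.w[:, :, 1:] ** 2))
    return float(e * g.cell_volume)
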