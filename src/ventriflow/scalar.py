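"""Passive-scalar blood-transit tracking.

A concentration field C in [0, 1] marks blood present in the ventricle at
end systole (C = 1) versus fresh atrial blood (C = 0).  C obeys an
advection-diffusion equation solved alongside the flow: flux-form
second-order advection with monotonized-central limited slopes (keeps C
bounded) and
explicit central diffusion.  By default the diffusivity equals the kinematic
viscosity (Schmidt number 1).
"""

from __future__ import annotations

import numpy as np

from .errors import PhaseError
from .immersed import BOUNDARY, EXTERIOR, FLUID
from .solver import FlowState


def _mc_slope(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Monotonized-central (MC) limited slope from one-sided differences.

    minmod of the central slope and twice each one-sided slope: TVD yet far
    less compressive than the harmonic limiter, which matters for long
    advection distances (a full rotation must not drift the blob).
    """
    s = 0.5 * (np.sign(a) + np.sign(b))
    return s * np.minimum(np.abs(0.5 * (a + b)),
                          np.minimum(2.0 * np.abs(a), 2.0 * np.abs(b)))


def _flux_1d(C: np.ndarray, uf: np.ndarray, axis: int, periodic: bool) -> np.ndarray:
    """Upwind MUSCL face flux along one periodic axis (x or y layout).

    ``uf`` holds the face-normal velocity at face i (between cells i-1, i).
    """
    Cm = np.roll(C, 1, axis=axis)
    dp = np.roll(C, -1, axis=axis) - C
    dm = C - Cm
    slope = _mc_slope(dm, dp)
    slope_m = np.roll(slope, 1, axis=axis)
    c_up = Cm + 0.5 * slope_m       # donor below the face
    c_dn = C - 0.5 * slope          # donor above the face
    cf = np.where(uf >= 0, c_up, c_dn)
    return uf * cf


def _flux_z(C: np.ndarray, w: np.ndarray, periodic: bool,
            inflow_value: float = 0.0) -> np.ndarray:
    """Face fluxes along z on the (nx, ny, nz+1) face layout."""
    if periodic:
        Cm = np.roll(C, 1, axis=2)
        dp = np.roll(C, -1, axis=2) - C
        dm = C - Cm
        slope = _mc_slope(dm, dp)
        c_up = Cm + 0.5 * np.roll(slope, 1, axis=2)
        c_dn = C - 0.5 * slope
        f = np.empty_like(w)
        f[:, :, :-1] = np.where(w[:, :, :-1] >= 0, c_up, c_dn) * w[:, :, :-1]
        f[:, :, -1] = f[:, :, 0]
        return f
    nz = C.shape[2]
    Cp = np.concatenate([C[:, :, :1], C, C[:, :, -1:]], axis=2)  # ghosts
    dC = np.diff(Cp, axis=2)                      # (nz+1) one-sided diffs
    slope = _mc_slope(dC[:, :, :-1], dC[:, :, 1:])  # per cell
    f = np.zeros_like(w)
    wi = w[:, :, 1:-1]
    c_up = C[:, :, :-1] + 0.5 * slope[:, :, :-1]
    c_dn = C[:, :, 1:] - 0.5 * slope[:, :, 1:]
    f[:, :, 1:-1] = np.where(wi >= 0, c_up, c_dn) * wi
    # bottom face: wall (w = 0) or open; one-sided donor either way
    f[:, :, 0] = np.where(w[:, :, 0] >= 0, inflow_value, C[:, :, 0]) * w[:, :, 0]
    # top face: outflow carries the local value, inflow brings fresh blood
    f[:, :, -1] = np.where(w[:, :, -1] >= 0, C[:, :, -1], inflow_value) * w[:, :, -1]
    return f


def scalar_rhs(state: FlowState, kappa: float) -> np.ndarray:
    """dC/dt = -div(v C) + kappa lap C (flux form, limited)."""
    g = state.grid
    per = g.z_mode == "periodic"
    C = state.C
    fx = _flux_1d(C, state.u, 0, True)
    fy = _flux_1d(C, state.v, 1, True)
    fz = _flux_z(C, state.w, per)
    rhs = -((np.roll(fx, -1, axis=0) - fx) / g.hx
            + (np.roll(fy, -1, axis=1) - fy) / g.hy
            + (fz[:, :, 1:] - fz[:, :, :-1]) / g.hz)
    if kappa > 0:
        lap = (np.roll(C, -1, axis=0) - 2 * C + np.roll(C, 1, axis=0)) / g.hx ** 2
        lap += (np.roll(C, -1, axis=1) - 2 * C + np.roll(C, 1, axis=1)) / g.hy ** 2
        if per:
            lap += (np.roll(C, -1, axis=2) - 2 * C + np.roll(C, 1, axis=2)) / g.hz ** 2
        else:
            Cp = np.concatenate([C[:, :, :1], C, C[:, :, -1:]], axis=2)
            lap += (Cp[:, :, 2:] - 2 * Cp[:, :, 1:-1] + Cp[:, :, :-2]) / g.hz ** 2
        if state.mask is not None and (state.mask != FLUID).any():
            lap = _masked_laplacian(C, state.mask, g, per)
        rhs += kappa * lap
    return rhs


def _masked_laplacian(C: np.ndarray, mask: np.ndarray, g, per: bool) -> np.ndarray:
    """Laplacian with zero diffusive flux through non-fluid faces."""
    fl = (mask == FLUID).astype(float)
    out = np.zeros_like(C)
    for ax, h2 in ((0, g.hx ** 2), (1, g.hy ** 2)):
        open_lo = fl * np.roll(fl, 1, axis=ax)     # face to lower neighbour
        open_hi = fl * np.roll(fl, -1, axis=ax)
        out += (open_hi * (np.roll(C, -1, axis=ax) - C)
                - open_lo * (C - np.roll(C, 1, axis=ax))) / h2
    if per:
        open_lo = fl * np.roll(fl, 1, axis=2)
        open_hi = fl * np.roll(fl, -1, axis=2)
        out += (open_hi * (np.roll(C, -1, axis=2) - C)
                - open_lo * (C - np.roll(C, 1, axis=2))) / g.hz ** 2
    else:
        flp = np.concatenate([np.zeros_like(fl[:, :, :1]), fl,
                              np.zeros_like(fl[:, :, :1])], axis=2)
        Cp = np.concatenate([C[:, :, :1], C, C[:, :, -1:]], axis=2)
        open_lo = fl * flp[:, :, :-2]
        open_hi = fl * flp[:, :, 2:]
        out += (open_hi * (Cp[:, :, 2:] - C)
                - open_lo * (C - Cp[:, :, :-2])) / g.hz ** 2
    return out


def extend_into_boundary(state: FlowState) -> None:
    """Copy the mean neighbouring fluid concentration into boundary cells.

    Advective fluxes across wall faces then carry the local concentration,
    which is the discrete analogue of an impermeable moving wall.
    """
    if state.mask is None:
        return
    mask = state.mask
    C = state.C
    fl = (mask == FLUID).astype(float)
    num = np.zeros_like(C)
    den = np.zeros_like(C)
    for ax in (0, 1, 2):
        for sh in (1, -1):
            num += np.roll(C * fl, sh, axis=ax)
            den += np.roll(fl, sh, axis=ax)
    isb = mask == BOUNDARY
    C[isb] = np.where(den[isb] > 0, num[isb] / np.maximum(den[isb], 1.0), 0.0)
    C[mask == EXTERIOR] = 0.0


def advance_scalar(C: np.ndarray, state: FlowState, dt: float,
                   kappa: float) -> np.ndarray:
    """Standalone SSP-RK3 scalar step with frozen velocities (for analysis).

    Returns the updated concentration; ``state`` provides the grid and the
    (divergence-free) velocity field.
    """
    work = state.copy()
    work.C = np.asarray(C, dtype=float).copy()
    c0 = work.C.copy()
    c1 = np.clip(c0 + dt * scalar_rhs(work, kappa), 0.0, 1.0)
    work.C = c1
    c2 = np.clip(0.75 * c0 + 0.25 * (c1 + dt * scalar_rhs(work, kappa)), 0.0, 1.0)
    work.C = c2
    return np.clip(c0 / 3.0 + 2.0 / 3.0 * (c2 + dt * scalar_rhs(work, kappa)),
                   0.0, 1.0)


def init_marker(state: FlowState, base_z: float,
                waveform=None, tol: float = 0.02) -> None:
    """Mark all ventricular blood: C = 1 in LV fluid cells below the base.

    Raises :class:`PhaseError` if a waveform is supplied and the current
    time is not end systole (within ``tol`` of the systole end, in s).
    """
    if waveform is not None:
        ts = np.mod(state.t, waveform.period)
        if abs(ts - waveform.t_sys) > tol:
            raise PhaseError(
                f"marker must be initialized at end systole (t_sys = "
                f"{waveform.t_sys}), got cycle time {ts:.3f}")
    g = state.grid
    zc = g.zc()
    below = zc[None, None, :] < base_z
    fluid = state.mask == FLUID if state.mask is not None else np.ones_like(state.C, bool)
    state.C = np.where(fluid & below, 1.0, 0.0)


def lv_fluid_volume(state: FlowState, base_z: float) -> float:
    """Discrete cavity volume: fluid cells below the basal plane (cm^3)."""
    g = state.grid
    below = g.zc()[None, None, :] < base_z
    fluid = state.mask == FLUID if state.mask is not None else np.ones_like(state.C, bool)
    return float((fluid & below).sum() * g.cell_volume)


def residual_volume(state: FlowState, base_z: float,
                    reference_volume: float | None = None) -> float:
    """Fraction of marked blood still in the LV (0..1).

    Integrates C over the ventricular fluid region and normalizes with the
    reference volume (the discrete end-systolic cavity volume at marking
    time; defaults to the current cavity volume).
    """
    g = state.grid
    below = g.zc()[None, None, :] < base_z
    fluid = state.mask == FLUID if state.mask is not None else np.ones_like(state.C, bool)
    sel = fluid & below
    total = float(state.C[sel].sum() * g.cell_volume)
    ref = reference_volume if reference_volume is not None \
        else float(sel.sum() * g.cell_volume)
    return min(total / ref, 1.0) if ref > 0 else 0.0
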