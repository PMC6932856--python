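"""Trilinear sampling of staggered-grid fields at arbitrary points.

Consistent with the solver's second-order accuracy; x and y wrap
periodically, z clamps to the box.
"""

from __future__ import annotations

import numpy as np

from .solver import FlowState


def _axis_weights(x: np.ndarray, origin: float, h: float, n: int,
                  periodic: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    s = (np.asarray(x, float) - origin) / h
    i0 = np.floor(s).astype(np.int64)
    f = s - i0
    if periodic:
        i0m = np.mod(i0, n)
        i1 = np.mod(i0 + 1, n)
    else:
        i0m = np.clip(i0, 0, n - 2)
        f = np.clip(s - i0m, 0.0, 1.0)
        i1 = i0m + 1
    return i0m, i1, f


def trilinear(arr: np.ndarray, pts: np.ndarray, origins, spacings,
              periodic=(True, True, False)) -> np.ndarray:
    """Sample ``arr`` (nx, ny, nz) at ``pts`` (N, 3)."""
    pts = np.atleast_2d(pts)
    ix0, ix1, fx = _axis_weights(pts[:, 0], origins[0], spacings[0],
                                 arr.shape[0], periodic[0])
    iy0, iy1, fy = _axis_weights(pts[:, 1], origins[1], spacings[1],
                                 arr.shape[1], periodic[1])
    iz0, iz1, fz = _axis_weights(pts[:, 2], origins[2], spacings[2],
                                 arr.shape[2], periodic[2])
    c000 = arr[ix0, iy0, iz0]
    c100 = arr[ix1, iy0, iz0]
    c010 = arr[ix0, iy1, iz0]
    c110 = arr[ix1, iy1, iz0]
    c001 = arr[ix0, iy0, iz1]
    c101 = arr[ix1, iy0, iz1]
    c011 = arr[ix0, iy1, iz1]
    c111 = arr[ix1, iy1, iz1]
    c00 = c000 * (1 - fx) + c100 * fx
    c10 = c010 * (1 - fx) + c110 * fx
    c01 = c001 * (1 - fx) + c101 * fx
    c11 = c011 * (1 - fx) + c111 * fx
    c0 = c00 * (1 - fy) + c10 * fy
    c1 = c01 * (1 - fy) + c11 * fy
    return c0 * (1 - fz) + c1 * fz


def sample_velocity(state: FlowState, pts: np.ndarray) -> np.ndarray:
    """Fluid velocity vectors at points (N, 3) by component-wise trilinear."""
    g = state.grid
    per_z = g.z_mode == "periodic"
    half = 0.5
    u = trilinear(state.u, pts,
                  (g.lo[0], g.lo[1] + half * g.hy, g.lo[2] + half * g.hz),
                  (g.hx, g.hy, g.hz), (True, True, per_z))
    v = trilinear(state.v, pts,
                  (g.lo[0] + half * g.hx, g.lo[1], g.lo[2] + half * g.hz),
                  (g.hx, g.hy, g.hz), (True, True, per_z))
    w_arr = state.w[:, :, :-1] if per_z else state.w
    w = trilinear(w_arr, pts,
                  (g.lo[0] + half * g.hx, g.lo[1] + half * g.hy, g.lo[2]),
                  (g.hx, g.hy, g.hz), (True, True, per_z))
    return np.stack([u, v, w], axis=-1)


def sample_scalar(state: FlowState, pts: np.ndarray) -> np.ndarray:
    """Cell-centred scalar (concentration) at points (N, 3)."""
    g = state.grid
    per_z = g.z_mode == "periodic"
    return trilinear(state.C, pts,
                     (g.lo[0] + 0.5 * g.hx, g.lo[1] + 0.5 * g.hy,
                      g.lo[2] + 0.5 * g.hz),
                     (g.hx, g.hy, g.hz), (True, True, per_z))
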