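"""Immersed-boundary cell tagging.

The moving surfaces are rasterized onto the fixed Cartesian grid: every cell
cut by a surface becomes a *boundary* cell carrying the local surface
velocity; cells outside the closed cavity/tube region are *exterior*; the
rest is *fluid*.  Classification is by dense facet sampling followed by a
flood fill from a known-outside corner (with periodic wrap in x and y).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import WatertightnessError
from .surfaces import StructuredSurface

FLUID, BOUNDARY, EXTERIOR = 0, 1, 2

# cut-cell priority when several surfaces intersect one cell: the valve must
# dominate flow blockage, then the basal plate, the LV wall, and the tubes
PRIORITY = {"mv_closed": 40, "mv_open": 40, "mv_anterior": 40, "mv_posterior": 40,
            "av_plate": 35, "basal_plate": 30, "lv_wall": 20,
            "atrium_tube": 10, "aorta_tube": 10}


class SurfaceSampler:
    """Pre-computed dense sample stencil for one structured surface.

    The bilinear weights on each facet are fixed by the grid topology, so a
    deforming surface (same connectivity, new node positions) is resampled by
    a single tensor contraction.
    """

    def __init__(self, surface: StructuredSurface, h: float):
        self.shape = surface.positions.shape[:2]
        p00, p10, p01, p11 = surface.facet_corners()
        if surface.facet_mask is not None:
            keep = surface.facet_mask
        else:
            keep = np.ones(p00.shape[:2], dtype=bool)
        self.keep = keep
        e = max(np.linalg.norm(p10 - p00, axis=-1)[keep].max(initial=0.0),
                np.linalg.norm(p01 - p00, axis=-1)[keep].max(initial=0.0),
                np.linalg.norm(p11 - p00, axis=-1)[keep].max(initial=0.0))
        k = int(np.ceil(e / (0.5 * h))) + 1
        self.k = min(max(k, 2), 10)
        q = (np.arange(self.k) + 0.5) / self.k
        a, b = np.meshgrid(q, q, indexing="ij")
        a, b = a.ravel(), b.ravel()
        # weights for corners (00, 10, 01, 11)
        self.w = np.stack([(1 - a) * (1 - b), a * (1 - b), (1 - a) * b, a * b],
                          axis=0)  # (4, k^2)

    def sample(self, surface: StructuredSurface) -> tuple[np.ndarray, np.ndarray]:
        """Sample points and velocities, (N, 3) each."""
        pts = []
        for arr in (surface.positions, surface.velocities):
            c = np.stack([q[self.keep] for q in _corners(arr)], axis=0)  # (4, F, 3)
            s = np.einsum("kq,kfc->fqc", self.w, c).reshape(-1, 3)
            pts.append(s)
        return pts[0], pts[1]


def _corners(arr: np.ndarray):
    return arr[:-1, :-1], arr[1:, :-1], arr[:-1, 1:], arr[1:, 1:]


def _union_periodic(labels: np.ndarray) -> dict[int, int]:
    """Union-find map joining label components across periodic x/y faces."""
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for a, b in ((labels[0], labels[-1]), (labels[:, 0], labels[:, -1])):
        pair = (a > 0) & (b > 0)
        if not pair.any():
            continue
        uniq = np.unique(np.stack([a[pair], b[pair]]), axis=1)
        for x, y in uniq.T:
            union(int(x), int(y))
    return {x: find(x) for x in set(parent)}


class BinnedSurface:
    """A surface pre-rasterized onto a grid (cell indices + mean velocity).

    Static surfaces (tubes, plates) are binned once and reused every step.
    """

    __slots__ = ("flat", "vavg", "priority")

    def __init__(self, flat: np.ndarray, vavg: np.ndarray, priority: int):
        self.flat = flat
        self.vavg = vavg
        self.priority = priority


def bin_surface(grid, sampler: SurfaceSampler, surface: StructuredSurface
                ) -> BinnedSurface:
    """Rasterize a surface: unique cut-cell indices and mean sample velocity."""
    nx, ny, nz = grid.nx, grid.ny, grid.nz
    pts, vels = sampler.sample(surface)
    inv_h = 1.0 / np.array([grid.hx, grid.hy, grid.hz])
    idx = np.floor((pts - grid.lo) * inv_h).astype(np.int64)
    idx[:, 0] %= nx
    idx[:, 1] %= ny
    inz = (idx[:, 2] >= 0) & (idx[:, 2] < nz)
    idx, vels = idx[inz], vels[inz]
    flat = (idx[:, 0] * ny + idx[:, 1]) * nz + idx[:, 2]
    ncell = nx * ny * nz
    cnt = np.bincount(flat, minlength=ncell)
    hit = np.flatnonzero(cnt)
    vavg = np.empty((len(hit), 3))
    for c in range(3):
        vavg[:, c] = np.bincount(flat, weights=vels[:, c],
                                 minlength=ncell)[hit] / cnt[hit]
    return BinnedSurface(hit, vavg, PRIORITY.get(surface.name, 25))


def prescribed_flux_into_fluid(grid, mask: np.ndarray, bvel: np.ndarray,
                               cell_sel: np.ndarray) -> float:
    """Net volumetric flux (cm^3/s) pushed into the fluid by selected
    boundary cells through their fluid-adjacent faces.

    Used to enforce the discrete geometric conservation law: the staircase
    wall must sweep exactly the volume rate of the smooth surface it
    represents.
    """
    isb = (mask == BOUNDARY) & cell_sel
    fl = mask == FLUID
    flux = 0.0
    areas = (grid.hy * grid.hz, grid.hx * grid.hz, grid.hx * grid.hy)
    for ax, comp in ((0, 0), (1, 1)):
        v = bvel[..., comp]
        # fluid cell on the high side of the face owned by a boundary cell
        hi = np.roll(fl, -1, axis=ax) & isb
        flux += float((v[hi]).sum()) * areas[ax]
        lo = np.roll(fl, 1, axis=ax) & isb
        flux -= float((v[lo]).sum()) * areas[ax]
    w = bvel[..., 2]
    hi = np.roll(fl, -1, axis=2) & isb
    hi[:, :, -1] = False
    flux += float((w[hi]).sum()) * areas[2]
    lo = np.roll(fl, 1, axis=2) & isb
    lo[:, :, 0] = False
    flux -= float((w[lo]).sum()) * areas[2]
    return flux


def tag_immersed_cells(grid, samplers_and_surfaces, check_leaks: bool = True,
                       exterior_seed: tuple[int, int, int] = (0, 0, 0),
                       return_priority: bool = False):
    """Classify grid cells against a set of immersed surfaces.

    Parameters
    ----------
    grid : StaggeredGrid
    samplers_and_surfaces : list of (SurfaceSampler, StructuredSurface) or
        pre-rasterized :class:`BinnedSurface` entries.  Surfaces are applied
        in ascending priority so the highest-priority surface's velocity
        wins in multiply cut cells.

    Returns
    -------
    mask : int8 array (nx, ny, nz) with values FLUID/BOUNDARY/EXTERIOR
    bvel : float array (nx, ny, nz, 3), surface velocity on boundary cells
    """
    nx, ny, nz = grid.nx, grid.ny, grid.nz
    mask = np.zeros((nx, ny, nz), dtype=np.int8)
    bvel = np.zeros((nx, ny, nz, 3))
    prio = np.full((nx, ny, nz), -1, dtype=np.int16)
    binned = [src if isinstance(src, BinnedSurface)
              else bin_surface(grid, src[0], src[1])
              for src in samplers_and_surfaces]
    mask_f = mask.reshape(-1)
    bvel_f = bvel.reshape(-1, 3)
    prio_f = prio.reshape(-1)
    for b in sorted(binned, key=lambda b: b.priority):
        mask_f[b.flat] = BOUNDARY
        take = b.priority >= prio_f[b.flat]
        cells = b.flat[take]
        bvel_f[cells] = b.vavg[take]
        prio_f[cells] = b.priority

    free = mask == FLUID
    labels, nlab = ndimage.label(free)
    if nlab == 0:
        return (mask, bvel, prio) if return_priority else (mask, bvel)
    remap = _union_periodic(labels)
    si, sj, sk = exterior_seed
    seed_label = labels[si, sj, sk]
    if seed_label == 0:
        raise WatertightnessError("exterior seed cell is a boundary cell")
    root = remap.get(seed_label, seed_label)
    exterior_labels = {lab for lab in range(1, nlab + 1)
                       if remap.get(lab, lab) == root}
    ext = np.isin(labels, sorted(exterior_labels))
    mask[ext] = EXTERIOR
    if check_leaks:
        fl = mask == FLUID
        if fl.any():
            exter = mask == EXTERIOR
            leak = False
            for ax in range(3):
                a = np.roll(fl, 1, axis=ax) & exter
                b = np.roll(fl, -1, axis=ax) & exter
                if ax == 2:  # z is not periodic: drop the wrap faces
                    a[:, :, 0] = False
                    b[:, :, -1] = False
                if a.any() or b.any():
                    leak = True
                    break
            if leak:
                raise WatertightnessError(
                    "fluid region touches the exterior through a non-boundary face")
    return (mask, bvel, prio) if return_priority else (mask, bvel)


def face_boundary_conditions(mask: np.ndarray, bvel: np.ndarray):
    """Face-centred velocity constraints implied by the cell mask.

    A face adjacent to a boundary cell is prescribed the mean boundary
    velocity of its flanking boundary cells; faces between/into exterior
    cells are frozen at zero.  Returns ((mu, uval), (mv, vval), (mw, wval))
    with the w arrays on the (nx, ny, nz+1) face layout.
    """
    nx, ny, nz = mask.shape
    isb = mask == BOUNDARY
    ise = mask == EXTERIOR
    out = []
    for ax, comp in ((0, 0), (1, 1)):
        b_hi = isb
        b_lo = np.roll(isb, 1, axis=ax)   # cell on the low side of face i
        e_hi = ise
        e_lo = np.roll(ise, 1, axis=ax)
        v_hi = bvel[..., comp]
        v_lo = np.roll(bvel[..., comp], 1, axis=ax)
        cnt = b_hi.astype(float) + b_lo.astype(float)
        val = np.where(cnt > 0,
                       (np.where(b_hi, v_hi, 0.0) + np.where(b_lo, v_lo, 0.0))
                       / np.maximum(cnt, 1.0), 0.0)
        m = b_hi | b_lo | e_hi | e_lo
        out.append((m, np.where(cnt > 0, val, 0.0)))
    # w faces: k = 0..nz, face k sits below cell k
    bz = np.zeros((nx, ny, nz + 1), dtype=bool)
    vz = np.zeros((nx, ny, nz + 1))
    cnt = np.zeros((nx, ny, nz + 1))
    acc = np.zeros((nx, ny, nz + 1))
    # contributions from the cell above each face (face k, cell k) and the
    # cell below it (face k+1, cell k)
    acc[:, :, :nz] += np.where(isb, bvel[..., 2], 0.0)
    cnt[:, :, :nz] += isb
    acc[:, :, 1:] += np.where(isb, bvel[..., 2], 0.0)
    cnt[:, :, 1:] += isb
    bz[:, :, :nz] |= isb | ise
    bz[:, :, 1:] |= isb | ise
    vz = np.where(cnt > 0, acc / np.maximum(cnt, 1.0), 0.0)
    out.append((bz, vz))
    return out
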