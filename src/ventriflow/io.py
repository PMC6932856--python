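"""Surface import/export (STL/PLY via trimesh), legacy-VTK and HDF5 output."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import trimesh

from .errors import MeshImportError
from .solver import FlowState, StaggeredGrid
from .surfaces import StructuredSurface


# ----------------------------------------------------------------------
# triangulation helpers
# ----------------------------------------------------------------------

def surface_to_trimesh(surface: StructuredSurface, cap_ends: bool = False
                       ) -> trimesh.Trimesh:
    """Triangulate a structured surface (optionally capping open end rows)."""
    nt, ns = surface.shape
    p = surface.positions
    if surface.closed_theta:
        verts = p[:-1].reshape(-1, 3)
        nrow = nt - 1

        def vid(i, j):
            return (i % nrow) * ns + j
    else:
        verts = p.reshape(-1, 3)
        nrow = nt

        def vid(i, j):
            return i * ns + j

    faces = []
    mask = surface.facet_mask
    for i in range(nt - 1):
        for j in range(ns - 1):
            if mask is not None and not mask[i, j]:
                continue
            a, b, c, d = vid(i, j), vid(i + 1, j), vid(i + 1, j + 1), vid(i, j + 1)
            faces.append((a, b, c))
            faces.append((a, c, d))
    verts = np.asarray(verts, dtype=float)
    extra = []
    if cap_ends and surface.closed_theta:
        for j, flip in ((0, True), (ns - 1, False)):
            ring = p[:-1, j]
            if np.abs(ring - ring.mean(axis=0)).max() < 1e-7:
                continue
            cidx = len(verts) + len(extra)
            extra.append(ring.mean(axis=0))
            for i in range(nt - 1):
                a, b = vid(i, j), vid((i + 1), j)
                faces.append((b, a, cidx) if flip else (a, b, cidx))
    if extra:
        verts = np.vstack([verts, np.asarray(extra)])
    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
    mesh.merge_vertices()
    return mesh


def export_surface(surface: StructuredSurface, path, cap_ends: bool = False) -> None:
    """Write STL or PLY (by extension)."""
    mesh = surface_to_trimesh(surface, cap_ends=cap_ends)
    mesh.export(str(path))


def import_surface(path, n_theta: int = 48, n_s: int = 40,
                   fmt: str | None = None) -> StructuredSurface:
    """Import an STL/PLY mesh and resample it onto a structured (theta, s) grid.

    The mesh is parameterized spherically about its centroid: for every
    (theta, psi) direction the farthest ray/mesh intersection becomes the
    grid node, so star-shaped cavities (ventricles, spheres) resample
    faithfully.  The maximum resampling deviation (distance from the new
    nodes to the source mesh) is stored on the returned surface as
    ``resample_deviation``.

    Raises :class:`MeshImportError` for empty, multi-component or
    non-manifold inputs.
    """
    path = Path(path)
    try:
        mesh = trimesh.load_mesh(str(path), file_type=fmt)
    except Exception as exc:
        raise MeshImportError(f"cannot read {path}: {exc}") from exc
    if isinstance(mesh, trimesh.Scene):
        geoms = list(mesh.geometry.values())
        if len(geoms) != 1:
            raise MeshImportError("mesh has multiple components")
        mesh = geoms[0]
    if mesh.is_empty or len(mesh.faces) == 0:
        raise MeshImportError(f"{path} contains no triangles")
    if mesh.body_count > 1:
        raise MeshImportError("mesh has multiple connected components")
    center = mesh.centroid
    theta = np.linspace(0.0, 2 * np.pi, n_theta + 1)
    psi = np.linspace(1e-6, np.pi - 1e-6, n_s)
    T, P = np.meshgrid(theta, psi, indexing="ij")
    dirs = np.stack([np.sin(P) * np.cos(T), np.sin(P) * np.sin(T), np.cos(P)],
                    axis=-1).reshape(-1, 3)
    tri = mesh.triangles
    radii = _farthest_ray_hits(np.asarray(center, float), dirs, tri)
    if not np.isfinite(radii).any():
        raise MeshImportError("no ray intersections; is the mesh closed?")
    pts = center + radii[:, None] * dirs
    missed = ~np.isfinite(radii)
    pts[missed] = 0.0
    if missed.any():
        # fill isolated misses from the nearest valid neighbour along theta
        pts_g = pts.reshape(n_theta + 1, n_s, 3)
        ok_g = (~missed).reshape(n_theta + 1, n_s)
        if ok_g.sum() < 0.9 * ok_g.size:
            raise MeshImportError("mesh is not star-shaped about its centroid")
        for j in range(n_s):
            bad = ~ok_g[:, j]
            if bad.any():
                good = np.flatnonzero(ok_g[:, j])
                if len(good) == 0:
                    raise MeshImportError("entire parametric row missed the mesh")
                for i in np.flatnonzero(bad):
                    pts_g[i, j] = pts_g[good[np.argmin(np.abs(good - i))], j]
        pts = pts_g.reshape(-1, 3)
    grid = pts.reshape(n_theta + 1, n_s, 3)
    grid[-1] = grid[0]  # exact seam closure
    surf = StructuredSurface(grid, closed_theta=True, name=path.stem)
    # ray hits lie exactly on the mesh; only neighbour-filled misses deviate
    if missed.any():
        filled = grid.reshape(-1, 3)[missed]
        surf.resample_deviation = float(
            _point_mesh_distance(filled, tri).max())
    else:
        surf.resample_deviation = 0.0
    return surf


def _farthest_ray_hits(origin: np.ndarray, dirs: np.ndarray,
                       tri: np.ndarray) -> np.ndarray:
    """Farthest positive ray parameter per direction (Moller-Trumbore).

    Vectorized over all triangles, chunked over rays; returns +inf-free
    array with NaN for rays that miss every triangle.
    """
    v0, e1, e2 = tri[:, 0], tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
    out = np.full(len(dirs), np.nan)
    for s in range(0, len(dirs), 256):
        d = dirs[s:s + 256]                      # (R, 3)
        p = np.cross(d[:, None, :], e2[None, :, :])       # (R, T, 3)
        det = np.einsum("tc,rtc->rt", e1, p)
        ok = np.abs(det) > 1e-12
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        tvec = origin - v0                        # (T, 3)
        u = np.einsum("tc,rtc->rt", tvec, p) * inv
        q = np.cross(tvec, e1)                    # (T, 3)
        v = np.einsum("rc,tc->rt", d, q) * inv
        t = np.einsum("tc,tc->t", e2, q)[None, :] * inv
        hit = ok & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9) & (t > 1e-9)
        t = np.where(hit, t, -np.inf)
        best = t.max(axis=1)
        out[s:s + 256] = np.where(np.isfinite(best), best, np.nan)
    return out


def _point_mesh_distance(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Distance from points to a triangle soup (exact, chunked brute force)."""
    out = np.empty(len(points))
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac = b - a, c - a
    for i, p in enumerate(points):
        ap = p - a
        d1 = np.einsum("tc,tc->t", ab, ap)
        d2 = np.einsum("tc,tc->t", ac, ap)
        d00 = np.einsum("tc,tc->t", ab, ab)
        d01 = np.einsum("tc,tc->t", ab, ac)
        d11 = np.einsum("tc,tc->t", ac, ac)
        denom = np.maximum(d00 * d11 - d01 * d01, 1e-300)
        v = np.clip((d11 * d1 - d01 * d2) / denom, 0.0, 1.0)
        w = np.clip((d00 * d2 - d01 * d1) / denom, 0.0, 1.0)
        s = np.clip(v + w, 0.0, 1.0)
        v = np.where(v + w > 1, v / np.maximum(v + w, 1e-300), v)
        w = s - v
        proj = a + v[:, None] * ab + w[:, None] * ac
        out[i] = np.sqrt(((p - proj) ** 2).sum(axis=1).min())
    return out


# ----------------------------------------------------------------------
# legacy-VTK writers (plain-text)
# ----------------------------------------------------------------------

def write_vtk_polydata(surfaces, path) -> None:
    """Write one or more structured surfaces as legacy-ASCII VTK PolyData."""
    if isinstance(surfaces, StructuredSurface):
        surfaces = [surfaces]
    verts, polys, vels = [], [], []
    offset = 0
    for s in surfaces:
        nt, ns = s.shape
        verts.append(s.positions.reshape(-1, 3))
        vels.append(s.velocities.reshape(-1, 3))
        for i in range(nt - 1):
            for j in range(ns - 1):
                if s.facet_mask is not None and not s.facet_mask[i, j]:
                    continue
                a = offset + i * ns + j
                polys.append((a, a + ns, a + ns + 1, a + 1))
        offset += nt * ns
    verts = np.vstack(verts)
    vels = np.vstack(vels)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nventriflow surfaces\nASCII\n")
        f.write("DATASET POLYDATA\n")
        f.write(f"POINTS {len(verts)} float\n")
        np.savetxt(f, verts, fmt="%.6g")
        f.write(f"POLYGONS {len(polys)} {5 * len(polys)}\n")
        for q in polys:
            f.write(f"4 {q[0]} {q[1]} {q[2]} {q[3]}\n")
        f.write(f"POINT_DATA {len(verts)}\nVECTORS velocity float\n")
        np.savetxt(f, vels, fmt="%.6g")


def write_vtk_imagedata(state: FlowState, path) -> None:
    """Cell-centred flow snapshot as legacy-ASCII VTK structured points."""
    g = state.grid
    nx, ny, nz = g.nx, g.ny, g.nz
    uc = 0.5 * (state.u + np.roll(state.u, -1, axis=0))
    vc = 0.5 * (state.v + np.roll(state.v, -1, axis=1))
    wc = 0.5 * (state.w[:, :, :-1] + state.w[:, :, 1:])
    vel = np.stack([uc, vc, wc], axis=-1)
    mask = state.mask if state.mask is not None else np.zeros((nx, ny, nz), np.int8)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nventriflow snapshot\nASCII\n")
        f.write("DATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        f.write(f"ORIGIN {g.lo[0] + g.hx / 2:g} {g.lo[1] + g.hy / 2:g} "
                f"{g.lo[2] + g.hz / 2:g}\n")
        f.write(f"SPACING {g.hx:g} {g.hy:g} {g.hz:g}\n")
        f.write(f"POINT_DATA {nx * ny * nz}\n")
        f.write("VECTORS velocity float\n")
        np.savetxt(f, vel.transpose(2, 1, 0, 3).reshape(-1, 3), fmt="%.6g")
        f.write("SCALARS pressure float 1\nLOOKUP_TABLE default\n")
        np.savetxt(f, state.p.transpose(2, 1, 0).reshape(-1, 1), fmt="%.6g")
        f.write("SCALARS concentration float 1\nLOOKUP_TABLE default\n")
        np.savetxt(f, state.C.transpose(2, 1, 0).reshape(-1, 1), fmt="%.6g")
        f.write("SCALARS mask int 1\nLOOKUP_TABLE default\n")
        np.savetxt(f, mask.transpose(2, 1, 0).reshape(-1, 1), fmt="%d")


# ----------------------------------------------------------------------
# HDF5 checkpoints
# ----------------------------------------------------------------------

def save_checkpoint(path, state: FlowState, extra: dict | None = None,
                    aux_fields: dict | None = None) -> None:
    """Exact-restart checkpoint (velocities, pressure, scalar, time).

    ``extra`` holds scalar metadata (JSON attribute); ``aux_fields`` holds
    additional arrays required for bit-exact continuation (e.g. iterative-
    solver warm starts).
    """
    with h5py.File(path, "w") as f:
        for name in ("u", "v", "w", "p", "C"):
            f.create_dataset(name, data=getattr(state, name))
        f.attrs["t"] = state.t
        g = state.grid
        f.attrs["lo"] = g.lo
        f.attrs["hi"] = g.hi
        f.attrs["n"] = (g.nx, g.ny, g.nz)
        f.attrs["z_mode"] = g.z_mode
        if extra:
            f.attrs["extra"] = json.dumps(extra)
        for name, arr in (aux_fields or {}).items():
            f.create_dataset(f"aux/{name}", data=np.asarray(arr))


def load_checkpoint(path) -> tuple[FlowState, dict, dict]:
    with h5py.File(path, "r") as f:
        n = f.attrs["n"]
        grid = StaggeredGrid(np.array(f.attrs["lo"]), np.array(f.attrs["hi"]),
                             int(n[0]), int(n[1]), int(n[2]),
                             str(f.attrs["z_mode"]))
        state = FlowState(grid, f["u"][...], f["v"][...], f["w"][...],
                          f["p"][...], f["C"][...], t=float(f.attrs["t"]))
        extra = json.loads(f.attrs.get("extra", "{}"))
        aux = {}
        if "aux" in f:
            aux = {k: f["aux"][k][...] for k in f["aux"]}
    return state, extra, aux
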