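"""Structured parametric surfaces and surface quadrature.

Every wall in the model -- the ventricular endocardium, the valve leaflets,
the basal plate and the atrium/aorta tube surrogates -- is a surface sampled
on parametric coordinates (theta, s): theta runs along the circumference and
s from one end of the patch to the other (base to apex for the ventricle,
annulus to trailing edge for a leaflet).  Positions are stored in cm and node
velocities in cm/s on the same grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import OpenSurfaceError

_SEAM_TOL = 1e-9


@dataclass
class StructuredSurface:
    """A surface sampled on a structured (theta, s) grid.

    Parameters
    ----------
    positions : ndarray, shape (nt, ns, 3)
        Node positions in cm.  If ``closed_theta`` the first and last theta
        rows duplicate each other (the seam) within 1e-9 cm.
    velocities : ndarray, shape (nt, ns, 3)
        Node velocities in cm/s (zero for static surfaces).
    closed_theta : bool
        Whether the grid wraps around in theta.
    facet_mask : ndarray of bool, shape (nt-1, ns-1), optional
        Facets flagged False are holes (used to cut orifices out of plates);
        they are skipped by quadrature and immersed-boundary tagging.
    """

    positions: np.ndarray
    velocities: np.ndarray | None = None
    closed_theta: bool = False
    facet_mask: np.ndarray | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (nt, ns, 3)")
        nt, ns, _ = self.positions.shape
        if nt < 4 or ns < 4:
            raise ValueError("grid must be at least 4 x 4")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.velocities is None:
            self.velocities = np.zeros_like(self.positions)
        else:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.positions.shape:
                raise ValueError("velocities must match positions shape")
        if self.closed_theta:
            seam = np.abs(self.positions[0] - self.positions[-1]).max()
            if seam > _SEAM_TOL:
                raise ValueError(f"closed surface seam mismatch {seam:g} cm")

    # -- basic geometry ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.positions.shape[:2]

    def facet_corners(self) -> tuple[np.ndarray, ...]:
        """Corner arrays (p00, p10, p01, p11), each (nt-1, ns-1, 3)."""
        p = self.positions
        return p[:-1, :-1], p[1:, :-1], p[:-1, 1:], p[1:, 1:]

    def facet_centroids(self) -> np.ndarray:
        p00, p10, p01, p11 = self.facet_corners()
        return 0.25 * (p00 + p10 + p01 + p11)

    def facet_normals_areas(self) -> tuple[np.ndarray, np.ndarray]:
        """Area vectors split into unit normals and scalar areas per facet.

        The facet area vector is half the cross product of the diagonals,
        exact for planar quads and second-order otherwise.
        """
        p00, p10, p01, p11 = self.facet_corners()
        av = 0.5 * np.cross(p11 - p00, p01 - p10)
        area = np.linalg.norm(av, axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            n = np.where(area[..., None] > 0, av / np.maximum(area, 1e-300)[..., None], 0.0)
        if self.facet_mask is not None:
            area = np.where(self.facet_mask, area, 0.0)
        return n, area

    def area(self) -> float:
        """Total surface area (cm^2), holes excluded."""
        _, a = self.facet_normals_areas()
        return float(a.sum())

    def node_normals(self) -> np.ndarray:
        """Unit normals at nodes from central-difference tangents."""
        p = self.positions
        if self.closed_theta:
            # drop duplicated seam before wrapping the difference
            core = p[:-1]
            tt = (np.roll(core, -1, axis=0) - np.roll(core, 1, axis=0)) * 0.5
            tt = np.concatenate([tt, tt[:1]], axis=0)
        else:
            tt = np.gradient(p, axis=0)
        ts = np.gradient(p, axis=1)
        n = np.cross(tt, ts)
        norm = np.linalg.norm(n, axis=-1, keepdims=True)
        ok = norm[..., 0] > 1e-12
        n[ok] /= norm[ok]
        if not ok.all():
            # degenerate rows (e.g. an apex collapsed to a point): copy the
            # nearest valid neighbour along s
            for j in range(p.shape[1]):
                bad = ~ok[:, j]
                if bad.any():
                    src = j + 1 if j + 1 < p.shape[1] else j - 1
                    n[bad, j] = n[bad, src]
        norm = np.linalg.norm(n, axis=-1, keepdims=True)
        n /= np.maximum(norm, 1e-300)
        return n

    def triangles(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Triangle soup (v0, v1, v2), two triangles per unmasked facet."""
        p00, p10, p01, p11 = self.facet_corners()
        if self.facet_mask is not None:
            keep = self.facet_mask
            p00, p10, p01, p11 = (q[keep] for q in (p00, p10, p01, p11))
        else:
            p00, p10, p01, p11 = (q.reshape(-1, 3) for q in (p00, p10, p01, p11))
        v0 = np.concatenate([p00, p00])
        v1 = np.concatenate([p10, p11])
        v2 = np.concatenate([p11, p01])
        return v0, v1, v2

    def translated(self, offset: np.ndarray) -> "StructuredSurface":
        return StructuredSurface(self.positions + np.asarray(offset, float),
                                 self.velocities.copy(), self.closed_theta,
                                 None if self.facet_mask is None else self.facet_mask.copy(),
                                 self.name)


def _row_is_point(row: np.ndarray, tol: float = 1e-7) -> bool:
    return bool(np.abs(row - row.mean(axis=0)).max() < tol)


def _signed_volume(v0: np.ndarray, v1: np.ndarray, v2: np.ndarray) -> float:
    return float(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum() / 6.0)


def _volume_second_order(surface: StructuredSurface,
                         cap_plane: tuple | None = None) -> float:
    if not surface.closed_theta:
        raise OpenSurfaceError("surface is not closed in theta")
    p = surface.positions
    diam = float(np.ptp(p.reshape(-1, 3), axis=0).max())
    tris = [surface.triangles()]
    for j, orient in ((0, -1), (p.shape[1] - 1, +1)):
        ring = p[:-1, j]  # seam row dropped
        if _row_is_point(ring, tol=1e-7 * max(diam, 1.0)):
            continue
        if cap_plane is not None:
            pt = np.asarray(cap_plane[0], float)
            nrm = np.asarray(cap_plane[1], float)
            nrm = nrm / np.linalg.norm(nrm)
            dev = np.abs((ring - pt) @ nrm).max()
            if dev > 1e-6 * max(diam, 1.0):
                raise OpenSurfaceError(
                    f"boundary ring deviates {dev:g} cm from the cap plane")
        c = ring.mean(axis=0)
        r0 = ring
        r1 = np.roll(ring, -1, axis=0)
        cc = np.broadcast_to(c, r0.shape)
        if orient > 0:
            tris.append((r0, r1, cc))
        else:
            tris.append((r1, r0, cc))
    v0 = np.concatenate([t[0] for t in tris])
    v1 = np.concatenate([t[1] for t in tris])
    v2 = np.concatenate([t[2] for t in tris])
    return abs(_signed_volume(v0, v1, v2))


def lv_volume(surface: StructuredSurface, cap_plane: tuple | None = None) -> float:
    """Enclosed volume (cm^3) of a surface, closing open end rows with caps.

    The volume is the divergence-theorem surface quadrature
    ``V = (1/3) oint x . n dA`` on the facet triangulation, with Richardson
    extrapolation over every-other-node subsampling in each parametric
    direction whose interval count is even (raising the order from two to
    four on smooth surfaces).  End rows collapsed to a point (an apex) close
    themselves; a non-degenerate end row is capped by a triangle fan to its
    centroid.

    Parameters
    ----------
    cap_plane : (point, normal), optional
        If given, every capped ring must lie in this plane within
        1e-6 of the surface diameter, otherwise the surface is considered
        open and :class:`OpenSurfaceError` is raised.
    """
    if surface.facet_mask is not None:
        return _volume_second_order(surface, cap_plane)

    def can_halve(n: int) -> bool:
        return (n - 1) % 2 == 0 and (n - 1) // 2 >= 3

    def vol_theta(pos: np.ndarray) -> float:
        """Second-order volume, theta-extrapolated when the grid allows."""
        s = StructuredSurface(pos, closed_theta=surface.closed_theta)
        v = _volume_second_order(s, cap_plane)
        if can_halve(pos.shape[0]):
            c = StructuredSurface(pos[::2], closed_theta=surface.closed_theta)
            v = v + (v - _volume_second_order(c, cap_plane)) / 3.0
        return v

    pos = surface.positions
    v = vol_theta(pos)
    if can_halve(pos.shape[1]):
        v = v + (v - vol_theta(pos[:, ::2])) / 3.0
    return v
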