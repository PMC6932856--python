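"""Synthetic cardiac geometry: ventricle, mitral valve family, domain assembly.

The left ventricle (LV) is a truncated prolate spheroid whose cavity volume
follows a prescribed physiological waveform; the mitral valve (MV) is a pair
of independent leaflets spanning a circular annulus, described by a
two-parameter family of configurations between a fully closed and a fully
open state.  A coaptation defect of adjustable location and severity turns
the closed state into a regurgitant (prolapsed) valve.

Units are cm, s, cm^3 throughout (1 ml = 1 cm^3).  The long axis is z with
the base at high z and the apex at low z; theta is measured from the
direction of the aortic orifice (+x).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

from .errors import GeometryInfeasibleError, LayoutError
from .surfaces import StructuredSurface, lv_volume

HALF_PI = 0.5 * np.pi


# ----------------------------------------------------------------------
# volume waveform
# ----------------------------------------------------------------------

@dataclass
class VolumeWaveform:
    """Cavity volume over one heartbeat.

    Systole is a single raised-cosine ejection of duration ``t_sys``;
    diastole consists of an early (E-wave) and an atrial (A-wave) filling
    phase, also raised cosines, sharing the stroke volume 2:1.  t = 0 is end
    diastole (onset of systole).
    """

    edv: float
    esv: float
    period: float = 1.0
    t_sys: float = 0.35
    e_frac: float = 2.0 / 3.0  # E-wave share of the stroke volume
    t_e: float = 0.25          # E-wave duration (s)
    t_a: float = 0.15          # A-wave duration (s), ends at t = period

    def __post_init__(self) -> None:
        if not (self.edv > self.esv > 0):
            raise ValueError("need EDV > ESV > 0")
        if self.t_sys + self.t_e + self.t_a > self.period + 1e-12:
            raise ValueError("phase durations exceed the period")

    @property
    def sv(self) -> float:
        return self.edv - self.esv

    @property
    def ef(self) -> float:
        return self.sv / self.edv

    @staticmethod
    def _ramp(x: np.ndarray) -> np.ndarray:
        """Raised-cosine smoothstep on [0, 1], clipped outside."""
        x = np.clip(x, 0.0, 1.0)
        return 0.5 * (1.0 - np.cos(np.pi * x))

    def volume(self, t):
        """V(t) in cm^3; periodic in ``period``."""
        t = np.mod(np.asarray(t, dtype=float), self.period)
        sv = self.sv
        ej = self._ramp(t / self.t_sys)                      # systolic ejection
        e0 = self.t_sys
        ew = self._ramp((t - e0) / self.t_e)                 # E-wave
        a0 = self.period - self.t_a
        aw = self._ramp((t - a0) / self.t_a)                 # A-wave
        return self.edv - sv * ej + sv * (self.e_frac * ew + (1 - self.e_frac) * aw)

    def dvolume_dt(self, t):
        t = np.mod(np.asarray(t, dtype=float), self.period)
        sv = self.sv

        def dramp(x, dur):
            inside = (x >= 0) & (x <= 1)
            return np.where(inside, 0.5 * np.pi * np.sin(np.pi * np.clip(x, 0, 1)) / dur, 0.0)

        out = -sv * dramp(t / self.t_sys, self.t_sys)
        out = out + sv * self.e_frac * dramp((t - self.t_sys) / self.t_e, self.t_e)
        out = out + sv * (1 - self.e_frac) * dramp((t - (self.period - self.t_a)) / self.t_a,
                                                   self.t_a)
        return out

    def in_systole(self, t) -> np.ndarray:
        """Phase flag: systole is the contiguous window where dV/dt < 0."""
        t = np.mod(np.asarray(t, dtype=float), self.period)
        return t < self.t_sys


def healthy_waveform(period: float = 1.0) -> VolumeWaveform:
    """Normal LV: EDV 113.47, ESV 46.52 cm^3 (EF 59 %)."""
    return VolumeWaveform(edv=113.47, esv=46.52, period=period)


def dilated_waveform(period: float = 1.0) -> VolumeWaveform:
    """Dilated cardiomyopathy LV: EDV 199.31, ESV 142.50 cm^3 (EF 29 %)."""
    return VolumeWaveform(edv=199.31, esv=142.50, period=period)


# ----------------------------------------------------------------------
# left ventricle
# ----------------------------------------------------------------------

@dataclass
class LVShapeParams:
    """Truncated-prolate-spheroid shape at the reference (EDV) state."""

    long_axis: float = 4.6     # semi-axis c (cm)
    trunc: float = 0.35        # base plane at z = trunc * long_axis
    long_axis_gain: float = 0.10  # share of contraction taken by long-axis shortening

    @property
    def base_z(self) -> float:
        return self.trunc * self.long_axis

    def equatorial_axis_for(self, volume: float) -> float:
        """Semi-axis a that gives the requested truncated-spheroid volume."""
        b = self.trunc
        f = self.long_axis * (b - b ** 3 / 3.0 + 2.0 / 3.0)
        if f <= 0:
            raise GeometryInfeasibleError("degenerate truncation")
        return float(np.sqrt(volume / (np.pi * f)))


HEALTHY_LV = LVShapeParams(long_axis=4.6, trunc=0.35)
DILATED_LV = LVShapeParams(long_axis=5.4, trunc=0.35)


class TimeVaryingLV:
    """LV endocardial surface whose cavity volume tracks a waveform.

    The reference surface (at EDV) is deformed by a single amplitude
    ``alpha(t)``: the short semi-axes scale with an s-weight that vanishes at
    the base (the annulus ring is exactly stationary) and the long axis
    shortens with a fixed small gain, mimicking real contraction patterns.
    ``alpha`` is calibrated per waveform sample by a root find on the
    discrete cavity volume, then interpolated by a periodic cubic spline, so
    node velocities are the analytic derivative d X/d alpha * alpha'(t).
    """

    def __init__(self, shape: LVShapeParams, waveform: VolumeWaveform,
                 n_theta: int = 48, n_s: int = 40, n_calib: int = 128):
        if n_theta < 8 or n_s < 8:
            raise ValueError("need n_theta, n_s >= 8")
        self.shape = shape
        self.waveform = waveform
        self.n_theta = n_theta
        self.n_s = n_s
        a0 = shape.equatorial_axis_for(waveform.edv)
        c = shape.long_axis
        self.a0, self.c = a0, c
        zb = shape.base_z
        theta = np.linspace(0.0, 2 * np.pi, n_theta + 1)
        s = np.linspace(0.0, 1.0, n_s)
        psi0 = np.arccos(shape.trunc)
        psi = psi0 + s * (np.pi - psi0)        # base -> apex
        self._rad0 = a0 * np.sin(psi)          # (ns,)
        self._z0 = c * np.cos(psi)             # (ns,)
        self._cos = np.cos(theta)[:, None]
        self._sin = np.sin(theta)[:, None]
        # radial contraction weight: zero on the (fixed) annulus ring and
        # near-uniform over the rest of the wall, so the cavity can reach a
        # normal end-systolic volume while the base stays put
        self._wr = np.tanh(3.0 * s)
        self._zb = zb
        # calibrate alpha(t) against the discrete volume
        tt = np.linspace(0.0, waveform.period, n_calib + 1)
        targets = waveform.volume(tt)
        if targets.min() <= 0:
            raise GeometryInfeasibleError("waveform volume is not positive")
        alphas = np.empty_like(tt)
        for i, v in enumerate(targets):
            alphas[i] = self._solve_alpha(float(v))
        alphas[-1] = alphas[0]
        self._alpha = CubicSpline(tt, alphas, bc_type="periodic")

    # geometry for a given amplitude -----------------------------------

    def _positions(self, alpha: float) -> np.ndarray:
        rad = self._rad0[None, :] * (1.0 + (alpha - 1.0) * self._wr[None, :])
        zz = self._zb + (self._z0 - self._zb)[None, :] * (1.0 + (alpha - 1.0)
                                                          * self.shape.long_axis_gain)
        p = np.empty((self.n_theta + 1, self.n_s, 3))
        p[..., 0] = rad * self._cos
        p[..., 1] = rad * self._sin
        p[..., 2] = zz
        return p

    def _dpositions_dalpha(self) -> np.ndarray:
        rad = self._rad0[None, :] * self._wr[None, :]
        d = np.empty((self.n_theta + 1, self.n_s, 3))
        d[..., 0] = rad * self._cos
        d[..., 1] = rad * self._sin
        d[..., 2] = np.broadcast_to(((self._z0 - self._zb)
                                     * self.shape.long_axis_gain)[None, :],
                                    (self.n_theta + 1, self.n_s))
        return d

    def _volume_of(self, alpha: float) -> float:
        surf = StructuredSurface(self._positions(alpha), closed_theta=True)
        return lv_volume(surf, cap_plane=((0, 0, self._zb), (0, 0, 1)))

    def _solve_alpha(self, target: float) -> float:
        try:
            return brentq(lambda a: self._volume_of(a) - target, 0.05, 2.5,
                          xtol=1e-12, rtol=1e-14)
        except ValueError as exc:  # no sign change in bracket
            raise GeometryInfeasibleError(
                f"cannot reach volume {target:g} cm^3 with this shape") from exc

    # public API --------------------------------------------------------

    @property
    def base_z(self) -> float:
        return self._zb

    @property
    def base_radius(self) -> float:
        """Radius of the (stationary) LV annulus ring."""
        return float(self._rad0[0])

    def at(self, t: float) -> StructuredSurface:
        """Surface with analytic node velocities at time t."""
        a = float(self._alpha(np.mod(t, self.waveform.period)))
        da = float(self._alpha(np.mod(t, self.waveform.period), 1))
        pos = self._positions(a)
        vel = self._dpositions_dalpha() * da
        return StructuredSurface(pos, vel, closed_theta=True, name="lv_wall")

    def volume_at(self, t: float) -> float:
        a = float(self._alpha(np.mod(t, self.waveform.period)))
        return self._volume_of(a)


def make_lv_surface(shape_params: LVShapeParams, waveform: VolumeWaveform,
                    n_theta: int = 48, n_s: int = 40) -> TimeVaryingLV:
    """Build the time-varying synthetic LV surface."""
    return TimeVaryingLV(shape_params, waveform, n_theta, n_s)


# ----------------------------------------------------------------------
# mitral valve family
# ----------------------------------------------------------------------

def _rotation_about_axis(axis: np.ndarray, angles: np.ndarray,
                         vectors: np.ndarray) -> np.ndarray:
    """Rodrigues rotation of ``vectors`` (..., 3) by per-element ``angles``."""
    k = np.asarray(axis, float)
    k = k / np.linalg.norm(k)
    c = np.cos(angles)[..., None]
    s = np.sin(angles)[..., None]
    kxv = np.cross(np.broadcast_to(k, vectors.shape), vectors)
    kdv = (vectors @ k)[..., None]
    return vectors * c + kxv * s + k * (kdv * (1 - c))


@dataclass
class Leaflet:
    """One leaflet's closed/open configurations and its hinge."""

    closed: StructuredSurface
    open: StructuredSurface
    hinge_point: np.ndarray
    hinge_axis: np.ndarray
    rotation_sign: float
    s_values: np.ndarray  # (ns,)


@dataclass
class ValveFamily:
    """Two-leaflet mitral valve: configurations Xv(theta, s, phi1, phi2).

    phi = 0 is fully closed, phi = pi/2 fully open; leaflet 1 is anterior
    (aortic side), leaflet 2 posterior.
    """

    leaflets: tuple[Leaflet, Leaflet]
    annulus_center: np.ndarray
    annulus_radius: float
    mva: float
    preset: str = "healthy"
    severity: float = 0.0

    @property
    def annulus_curve(self) -> np.ndarray:
        th = np.linspace(0, 2 * np.pi, 129)
        c = self.annulus_center
        r = self.annulus_radius
        return np.stack([c[0] + r * np.cos(th), c[1] + r * np.sin(th),
                         np.full_like(th, c[2])], axis=-1)


def _leaflet_grid(theta: np.ndarray, annulus_pts: np.ndarray,
                  edge_pts: np.ndarray, s: np.ndarray,
                  belly: float) -> np.ndarray:
    """Ruled surface annulus -> edge with a small -z belly sag."""
    w = s[None, :, None]
    p = annulus_pts[:, None, :] * (1 - w) + edge_pts[:, None, :] * w
    sag = belly * (s * (1 - s) * 4.0)[None, :, None]
    p = p - sag * np.array([0.0, 0.0, 1.0])
    return p


def make_mv_family(preset: str = "healthy", severity: float = 0.0,
                   n_theta: int = 33, n_s: int = 13,
                   center: np.ndarray | None = None,
                   base_z: float = 0.0) -> ValveFamily:
    """Build the synthetic two-leaflet mitral valve.

    Parameters
    ----------
    preset : {"healthy", "P3like", "P2like"}
        Where the coaptation defect sits on the posterior leaflet: nowhere
        (healthy annulus, 6.20 cm^2), on the posteromedial scallop (P3like,
        4.83 cm^2) or on the central scallop (P2like, 4.26 cm^2).  Annulus
        areas follow the three valves the model emulates.
    severity : float in [0, 1]
        Amplitude of the defect; 0 reproduces a fully coapting closed valve,
        and the closed-state orifice area grows continuously (linearly) with
        severity.
    """
    if preset not in ("healthy", "P3like", "P2like"):
        raise ValueError(f"unknown MV preset {preset!r}")
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must lie in [0, 1]")
    mva = {"healthy": 6.20, "P3like": 4.83, "P2like": 4.26}[preset]
    radius = float(np.sqrt(mva / np.pi))
    if center is None:
        center = np.array([-1.15, 0.0, base_z])
    center = np.asarray(center, float)
    depth = 0.55          # coaptation-line sag below the annulus (cm)
    belly = 0.18          # leaflet belly sag (cm)
    s = np.linspace(0.0, 1.0, n_s)

    def build_leaflet(theta: np.ndarray, is_anterior: bool) -> Leaflet:
        ann = np.stack([center[0] + radius * np.cos(theta),
                        center[1] + radius * np.sin(theta),
                        np.full_like(theta, center[2])], axis=-1)
        # closed edge: both leaflets meet on the commissure-to-commissure
        # curve x = cx, dipping below the annulus plane
        edge = np.stack([np.full_like(theta, center[0]),
                         center[1] + radius * np.sin(theta),
                         center[2] - depth * np.abs(np.cos(theta))], axis=-1)
        if not is_anterior and severity > 0:
            edge = edge + severity * _defect_offset(preset, theta, ann, edge)
        closed = _leaflet_grid(theta, ann, edge, s, belly)
        # open: leaflet swung toward the ventricle, tilted slightly outward
        length = np.linalg.norm(edge - ann, axis=-1)
        outward = ann - center
        outward[:, 2] = 0.0
        outward /= np.maximum(np.linalg.norm(outward, axis=-1, keepdims=True), 1e-12)
        direc = -np.array([0.0, 0.0, 1.0]) + 0.30 * outward
        direc /= np.linalg.norm(direc, axis=-1, keepdims=True)
        open_pos = ann[:, None, :] + (length[:, None] * s[None, :])[..., None] \
            * direc[:, None, :]
        hinge_axis = np.array([0.0, 1.0, 0.0])
        hinge_point = center.copy()
        closed_s = StructuredSurface(closed, name="mv_closed")
        open_s = StructuredSurface(open_pos, name="mv_open")
        # rotation sense: pick the sign whose half-turn about the hinge moves
        # the closed trailing edge closer to the open trailing edge
        mid = len(theta) // 2
        pc = closed[mid, -1] - hinge_point
        po = open_pos[mid, -1] - hinge_point
        best = min((+1.0, -1.0), key=lambda sg: np.linalg.norm(
            _rotation_about_axis(hinge_axis, np.array(sg * HALF_PI), pc[None])[0] - po))
        return Leaflet(closed_s, open_s, hinge_point, hinge_axis, best, s)

    th_ant = np.linspace(-HALF_PI, HALF_PI, n_theta)
    th_post = np.linspace(HALF_PI, 1.5 * np.pi, n_theta)
    ant = build_leaflet(th_ant, True)
    post = build_leaflet(th_post, False)
    return ValveFamily((ant, post), center, radius, mva, preset, severity)


def _defect_offset(preset: str, theta: np.ndarray, ann: np.ndarray,
                   edge: np.ndarray) -> np.ndarray:
    """Unit-severity displacement of the posterior free edge.

    The edge retracts toward its own annulus (opening a gap) and lifts
    toward the atrium (prolapse); a raised-cosine bump localizes the defect
    to one scallop.
    """
    # (center, half-width, horizontal retraction, atrial lift): the focal
    # prolapses use a compact, wide-open gap (a flail-segment morphology)
    # rather than a long hairline slit, so the orifice stays resolvable on
    # coarse flow grids at matched area
    if preset == "P2like":
        th0, half, ah, az = np.pi, np.pi / 4.5, 0.85, 0.45   # central scallop
    elif preset == "P3like":
        th0, half, ah, az = np.pi + np.pi / 3.2, np.pi / 4.4, 0.88, 0.5
    else:
        # "healthy": a broad shallow central slit; physiologic valves close
        # with a tiny residual orifice (~1 % of the valve area) at small
        # severity rather than a focal prolapse
        th0, half, ah, az = np.pi, np.pi / 2.2, 0.55, 0.35
    d = np.abs(np.angle(np.exp(1j * (theta - th0))))
    bump = np.where(d < half, 0.5 * (1 + np.cos(np.pi * d / half)), 0.0)
    toward_annulus = ann - edge
    toward_annulus[:, 2] = 0.0
    off = ah * toward_annulus * bump[:, None]
    off[:, 2] = az * bump
    return off


def severity_for_eoa(preset: str, target_eoa: float, **kwargs) -> float:
    """Severity whose closed-state orifice area equals ``target_eoa`` (cm^2)."""
    from .metrics import extract_orifice, mvo_area

    def eoa_of(sev: float) -> float:
        fam = make_mv_family(preset, sev, **kwargs)
        surfs = interpolate_valve(fam, 0.0, 0.0)
        return mvo_area(extract_orifice(surfs))

    hi = eoa_of(1.0)
    if not 0.0 <= target_eoa <= hi:
        raise ValueError(f"target EOA {target_eoa:g} outside reachable [0, {hi:g}]")
    return brentq(lambda sv: eoa_of(sv) - target_eoa, 0.0, 1.0, xtol=1e-10)


# ----------------------------------------------------------------------
# valve interpolation
# ----------------------------------------------------------------------

def _interp_leaflet(lf: Leaflet, phi: float, rates: float = 0.0
                    ) -> StructuredSurface:
    """Rotation-dominated path from closed (phi=0) to open (phi=pi/2).

    Each node rotates about the hinge through an angle proportional to its
    own s-coordinate (the annulus row never moves), and the residual
    mismatch with the stored open configuration is blended in linearly, so
    both endpoints are reproduced exactly.
    """
    f = phi / HALF_PI
    s = lf.s_values
    ang_full = lf.rotation_sign * HALF_PI * s            # (ns,)
    pc = lf.closed.positions - lf.hinge_point
    rot_f = _rotation_about_axis(lf.hinge_axis, f * ang_full[None, :], pc)
    rot_1 = _rotation_about_axis(lf.hinge_axis, ang_full[None, :], pc)
    residual = lf.open.positions - (rot_1 + lf.hinge_point)
    pos = rot_f + lf.hinge_point + f * residual
    vel = _dinterp_dphi(lf, phi) * rates
    return StructuredSurface(pos, vel, name=lf.closed.name)


def _dinterp_dphi(lf: Leaflet, phi: float) -> np.ndarray:
    """Analytic d X / d phi for one leaflet (used for node velocities)."""
    f = phi / HALF_PI
    s = lf.s_values
    ang_full = lf.rotation_sign * HALF_PI * s
    pc = lf.closed.positions - lf.hinge_point
    # d/d f of Rot(f*ang) = ang * (k x Rot(f*ang) p) for rotation about unit k
    rot_f = _rotation_about_axis(lf.hinge_axis, f * ang_full[None, :], pc)
    k = lf.hinge_axis / np.linalg.norm(lf.hinge_axis)
    drot = ang_full[None, :, None] * np.cross(np.broadcast_to(k, rot_f.shape), rot_f)
    rot_1 = _rotation_about_axis(lf.hinge_axis, ang_full[None, :], pc)
    residual = lf.open.positions - (rot_1 + lf.hinge_point)
    return (drot + residual) / HALF_PI


def interpolate_valve(family: ValveFamily, phi1: float, phi2: float,
                      rates: tuple[float, float] = (0.0, 0.0)
                      ) -> tuple[StructuredSurface, StructuredSurface]:
    """Leaflet surfaces at opening angles (phi1, phi2), each in [0, pi/2].

    Node velocities are ``dX/dphi_i * rates[i]``.
    """
    for phi in (phi1, phi2):
        if not -1e-12 <= phi <= HALF_PI + 1e-12:
            raise ValueError(f"angle {phi:g} outside [0, pi/2]")
    ant = _interp_leaflet(family.leaflets[0], float(np.clip(phi1, 0, HALF_PI)),
                          rates[0])
    post = _interp_leaflet(family.leaflets[1], float(np.clip(phi2, 0, HALF_PI)),
                           rates[1])
    return ant, post


def valve_config_derivative(family: ValveFamily, phi1: float, phi2: float,
                            leaflet: int, wrt: int | None = None,
                            h: float = 1e-3) -> np.ndarray:
    """Field dXv/dphi_wrt over leaflet ``leaflet`` (0 anterior, 1 posterior).

    Central finite difference of :func:`interpolate_valve` with step ``h``
    (rad); identically zero when the differentiated angle belongs to the
    other leaflet, since the two leaflets are independent.
    """
    if wrt is None:
        wrt = leaflet
    if wrt != leaflet:
        return np.zeros_like(family.leaflets[leaflet].closed.positions)
    phi = (phi1, phi2)[leaflet]
    lo = max(0.0, phi - h)
    hi = min(HALF_PI, phi + h)
    sl = _interp_leaflet(family.leaflets[leaflet], lo)
    sh = _interp_leaflet(family.leaflets[leaflet], hi)
    return (sh.positions - sl.positions) / (hi - lo)


# ----------------------------------------------------------------------
# domain assembly
# ----------------------------------------------------------------------

@dataclass
class AorticOrifice:
    center: np.ndarray
    radius: float
    normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    @property
    def area(self) -> float:
        return np.pi * self.radius ** 2


def _tube(center: np.ndarray, radius: float, z0: float, z1: float,
          n_theta: int = 49, n_z: int = 17, name: str = "tube") -> StructuredSurface:
    th = np.linspace(0, 2 * np.pi, n_theta)
    zz = np.linspace(z0, z1, n_z)
    p = np.empty((n_theta, n_z, 3))
    p[..., 0] = center[0] + radius * np.cos(th)[:, None]
    p[..., 1] = center[1] + radius * np.sin(th)[:, None]
    p[..., 2] = zz[None, :]
    return StructuredSurface(p, closed_theta=True, name=name)


def _basal_plate(lv_radius: float, base_z: float, holes: list[tuple[np.ndarray, float]],
                 n_theta: int = 97, n_r: int = 49) -> StructuredSurface:
    """Polar-grid disk spanning the LV annulus, with orifice holes cut out."""
    th = np.linspace(0, 2 * np.pi, n_theta)
    rr = np.linspace(0.0, lv_radius, n_r)
    p = np.empty((n_theta, n_r, 3))
    p[..., 0] = rr[None, :] * np.cos(th)[:, None]
    p[..., 1] = rr[None, :] * np.sin(th)[:, None]
    p[..., 2] = base_z
    surf = StructuredSurface(p, closed_theta=True, name="basal_plate")
    cen = surf.facet_centroids()
    mask = np.ones(cen.shape[:2], dtype=bool)
    for hc, hr in holes:
        d2 = (cen[..., 0] - hc[0]) ** 2 + (cen[..., 1] - hc[1]) ** 2
        mask &= d2 > hr ** 2
    surf.facet_mask = mask
    return surf


def _disk(center: np.ndarray, radius: float, z: float,
          n_theta: int = 49, n_r: int = 9, name: str = "disk") -> StructuredSurface:
    th = np.linspace(0, 2 * np.pi, n_theta)
    rr = np.linspace(0.0, radius, n_r)
    p = np.empty((n_theta, n_r, 3))
    p[..., 0] = center[0] + rr[None, :] * np.cos(th)[:, None]
    p[..., 1] = center[1] + rr[None, :] * np.sin(th)[:, None]
    p[..., 2] = z
    return StructuredSurface(p, closed_theta=True, name=name)


@dataclass
class DomainAssembly:
    """The composed closed computational geometry.

    LV wall + basal plate (annulus minus both orifices) + mitral valve +
    aortic orifice, with straight tube surrogates of the atrium and the
    aorta extending both orifices to the top of the computational box.
    """

    lv: TimeVaryingLV
    mv: ValveFamily
    aortic: AorticOrifice
    basal_surface: StructuredSurface
    atrium_tube: StructuredSurface
    aorta_tube: StructuredSurface
    av_plate: StructuredSurface
    box_lo: np.ndarray
    box_hi: np.ndarray
    amva: float  # MV annulus area (cm^2)
    alva: float  # LV annulus area (cm^2)

    @property
    def base_z(self) -> float:
        return self.lv.base_z

    def static_surfaces(self, av_open: bool) -> list[StructuredSurface]:
        out = [self.basal_surface, self.atrium_tube, self.aorta_tube]
        if not av_open:
            out.append(self.av_plate)
        return out


def compose_domain(lv: TimeVaryingLV, family: ValveFamily,
                   aortic_params: AorticOrifice | None = None,
                   box: tuple | None = None,
                   pad_xy: float = 0.45, pad_bottom: float = 0.6,
                   tube_height: float = 1.4) -> DomainAssembly:
    """Assemble the closed flow geometry around the LV.

    The basal plate spans the LV annulus minus the mitral annulus and the
    aortic orifice; straight tubes extend both orifices to the top box face.
    Raises :class:`LayoutError` if the orifices overlap each other or leave
    the LV annulus disk.
    """
    zb = lv.base_z
    rb = lv.base_radius
    if aortic_params is None:
        # typical adult aortic valve area ~3.5 cm^2, placed opposite the MV
        # just inside the LV annulus rim
        r_ao = 1.05
        aortic_params = AorticOrifice(np.array([rb - r_ao - 0.2, 0.0, zb]), r_ao)
    mc = family.annulus_center
    ac = aortic_params.center
    gap = np.hypot(*(mc[:2] - ac[:2])) - family.annulus_radius - aortic_params.radius
    if gap <= 0:
        raise LayoutError("mitral annulus and aortic orifice overlap")
    for c, r in ((mc, family.annulus_radius), (ac, aortic_params.radius)):
        if np.hypot(c[0], c[1]) + r >= rb:
            raise LayoutError("orifice extends beyond the LV annulus")
    if box is None:
        half = rb + pad_xy
        box_lo = np.array([-half, -half, -lv.c - pad_bottom])
        box_hi = np.array([half, half, zb + tube_height])
    else:
        box_lo = np.asarray(box[0], float)
        box_hi = np.asarray(box[1], float)
    top = box_hi[2]
    basal = _basal_plate(rb, zb, [(mc, family.annulus_radius),
                                  (ac, aortic_params.radius)])
    atrium = _tube(mc, family.annulus_radius, zb, top, name="atrium_tube")
    aorta = _tube(ac, aortic_params.radius, zb, top, name="aorta_tube")
    av_plate = _disk(ac, aortic_params.radius, zb, name="av_plate")
    amva = np.pi * family.annulus_radius ** 2
    alva = np.pi * rb ** 2
    return DomainAssembly(lv, family, aortic_params, basal, atrium, aorta,
                          av_plate, box_lo, box_hi, amva, alva)
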