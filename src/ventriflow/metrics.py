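"""Regurgitation and blood-transit quantification.

Implements the full measurement suite: the instantaneous mitral orifice
area MVO(t) from the gap between the leaflet trailing edges, the effective
orifice area EOA (MVO of the closed valve), the orifice flow rate QMV, the
annulus flow rates QMVa and QLV, the old-blood rate QMVold, their phase
integrals (Vreg, VregMVa, VLVa, Vregold), the false regurgitation
Vregfalse = VregMVa - Vreg, the residual volume, and the normalized columns
reported per case, including the proportionality check
Vreg/SV ~ EOA/MVA.

Sign conventions: flow toward the atrium (regurgitant, +z) is positive in
QMV/QMVa; QLV is positive into the ventricle so its diastolic integral is
the filling volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import PhaseError

Z = np.array([0.0, 0.0, 1.0])


# ----------------------------------------------------------------------
# orifice geometry
# ----------------------------------------------------------------------

@dataclass
class OrificeGeometry:
    """Paired trailing edges, midline and per-station gap of the MV orifice."""

    ant: np.ndarray          # (M, 3) anterior edge stations
    post: np.ndarray         # (M, 3) posterior edge stations
    ant_vel: np.ndarray
    post_vel: np.ndarray
    midline: np.ndarray      # (M, 3)
    gap: np.ndarray          # (M,) |ant - post|, cm
    normal: np.ndarray       # (M, 3) unit, perpendicular to tangent and gap
    arclength: np.ndarray    # (M,) cumulative midline arclength

    @property
    def length(self) -> float:
        return float(self.arclength[-1])


def _edge_resample(pts: np.ndarray, vel: np.ndarray, frac: np.ndarray):
    """Resample a polyline at normalized parametric (index) fractions.

    Index-proportional pairing keeps stations registered across the two
    edges even when a prolapse locally stretches one of them (arclength
    pairing would smear the defect gap into the coapting sections).
    """
    sn = np.linspace(0.0, 1.0, len(pts))
    out_p = np.stack([np.interp(frac, sn, pts[:, c]) for c in range(3)], axis=-1)
    out_v = np.stack([np.interp(frac, sn, vel[:, c]) for c in range(3)], axis=-1)
    return out_p, out_v


def extract_orifice(valve_surfaces, n_stations: int | None = None) -> OrificeGeometry:
    """Pair the two trailing edges station-by-station and build the midline.

    ``valve_surfaces`` is the (anterior, posterior) pair from
    :func:`ventriflow.geometry.interpolate_valve`; the trailing edge is the
    last s-row of each leaflet.  Stations are paired by normalized
    parametric fraction (see :func:`_edge_resample`), the midline is the
    pointwise average, and each station carries the gap width and a unit
    normal perpendicular to the midline tangent and the gap vector,
    oriented toward the atrium.
    """
    ant_s, post_s = valve_surfaces
    ea, va = ant_s.positions[:, -1], ant_s.velocities[:, -1]
    ep, vp = post_s.positions[:, -1], post_s.velocities[:, -1]
    la = np.linalg.norm(np.diff(ea, axis=0), axis=-1).sum()
    lp = np.linalg.norm(np.diff(ep, axis=0), axis=-1).sum()
    if min(la, lp) > 0 and max(la, lp) / min(la, lp) > 3.0:
        raise PhaseError("trailing edges have grossly different lengths")
    # orient the posterior edge to run parallel to the anterior edge
    if np.linalg.norm(ea[0] - ep[0]) > np.linalg.norm(ea[0] - ep[-1]):
        ep, vp = ep[::-1], vp[::-1]
    m = n_stations or 2 * max(len(ea), len(ep))
    frac = np.linspace(0.0, 1.0, m)
    pa, va = _edge_resample(ea, va, frac)
    pp, vp = _edge_resample(ep, vp, frac)
    mid = 0.5 * (pa + pp)
    gapv = pa - pp
    gap = np.linalg.norm(gapv, axis=-1)
    tang = np.gradient(mid, axis=0)
    tang /= np.maximum(np.linalg.norm(tang, axis=-1, keepdims=True), 1e-12)
    with np.errstate(invalid="ignore"):
        ghat = np.where(gap[:, None] > 1e-9, gapv / np.maximum(gap, 1e-300)[:, None], Z)
    n = np.cross(tang, ghat)
    nn = np.linalg.norm(n, axis=-1, keepdims=True)
    n = np.where(nn > 1e-9, n / np.maximum(nn, 1e-300), Z)
    # orient toward the atrium (+z); degenerate stations default to +z
    flip = (n @ Z) < 0
    n[flip] *= -1.0
    seg = np.linalg.norm(np.diff(mid, axis=0), axis=-1)
    arcl = np.concatenate([[0.0], np.cumsum(seg)])
    return OrificeGeometry(pa, pp, va, vp, mid, gap, n, arcl)


def mvo_area(orifice: OrificeGeometry) -> float:
    """MVO(t) = integral of the edge gap along the midline (cm^2)."""
    return float(np.trapezoid(orifice.gap, orifice.arclength))


def _gauss01(n: int):
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (x + 1.0), 0.5 * w


def orifice_flow(fluid_sampler, orifice: OrificeGeometry,
                 n_gauss: int = 5, edge_velocity: str = "mean",
                 weight_sampler=None) -> float:
    """QMV (cm^3/s): gap-weighted relative normal velocity along the midline.

    The fluid velocity is averaged over ``n_gauss`` Gauss points spanning
    the gap segment at each station; the edge velocity uses the mean of the
    two edges (``edge_velocity="mean"``) or the literal half-difference rate
    (``"half-difference"``).  ``weight_sampler`` optionally weights the
    integrand pointwise (used for the old-blood flow).
    """
    xi, wq = _gauss01(n_gauss)
    pts = orifice.post[None, :, :] + xi[:, None, None] * (
        orifice.ant - orifice.post)[None, :, :]          # (G, M, 3)
    flat = pts.reshape(-1, 3)
    vel = np.asarray(fluid_sampler(flat), dtype=float).reshape(*pts.shape[:2], 3)
    if weight_sampler is not None:
        wgt = np.asarray(weight_sampler(flat), dtype=float).reshape(pts.shape[:2])
    else:
        wgt = np.ones(pts.shape[:2])
    vbar = np.einsum("g,gmc->mc", wq, vel * wgt[..., None])
    cbar = np.einsum("g,gm->m", wq, wgt)
    if edge_velocity == "mean":
        ve = 0.5 * (orifice.ant_vel + orifice.post_vel)
    elif edge_velocity == "half-difference":
        ve = 0.5 * (orifice.ant_vel - orifice.post_vel)
    else:
        raise ValueError("edge_velocity must be 'mean' or 'half-difference'")
    vrel = vbar - cbar[:, None] * ve
    integrand = np.einsum("mc,mc->m", vrel, orifice.normal) * orifice.gap
    return float(np.trapezoid(integrand, orifice.arclength))


def old_blood_flow(fluid_sampler, concentration_sampler,
                   orifice: OrificeGeometry, n_gauss: int = 5,
                   edge_velocity: str = "mean") -> float:
    """QMVold (cm^3/s): the orifice flow weighted by the concentration C."""
    return orifice_flow(fluid_sampler, orifice, n_gauss, edge_velocity,
                        weight_sampler=concentration_sampler)


def annulus_flow(fluid_sampler, center, radius: float, z: float,
                 normal=Z, annulus_velocity=None,
                 n_r: int = 24, n_theta: int = 48) -> float:
    """Flux of the relative velocity through a circular annulus patch.

    Q = iint (v - v_annulus) . n dA over the disk of given center/radius in
    the plane z; midpoint quadrature on a polar grid.  Used for both the
    mitral annulus (QMVa, n toward the atrium) and the LV annulus (QLV).
    """
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    rr = (np.arange(n_r) + 0.5) * (radius / n_r)
    th = (np.arange(n_theta) + 0.5) * (2 * np.pi / n_theta)
    R, T = np.meshgrid(rr, th, indexing="ij")
    pts = np.stack([center[0] + R * np.cos(T), center[1] + R * np.sin(T),
                    np.full_like(R, z)], axis=-1).reshape(-1, 3)
    dA = (radius / n_r) * (2 * np.pi / n_theta) * R.reshape(-1)
    v = np.asarray(fluid_sampler(pts), dtype=float)
    if annulus_velocity is not None:
        v = v - np.asarray(annulus_velocity, float)
    return float(np.sum((v @ normal) * dA))


# ----------------------------------------------------------------------
# time series and phase integrals
# ----------------------------------------------------------------------

SERIES_COLUMNS = ("t", "mvo", "qmv", "qmva", "qlv", "qmv_old", "dvdt",
                  "phi1", "phi2", "dphi1", "dphi2", "av_open", "systole",
                  "c_min", "c_max")


def new_series() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=float) for c in SERIES_COLUMNS})


def integrate_phase(series: pd.DataFrame, phase: str, flux: str,
                    t_window: tuple[float, float] | None = None) -> float:
    """Trapezoidal time integral of one flux column over a phase window.

    ``phase`` is "systole" or "diastole" (from the series' phase flag);
    ``t_window`` optionally restricts to an absolute time interval first.
    """
    if phase not in ("systole", "diastole"):
        raise ValueError("phase must be 'systole' or 'diastole'")
    df = series
    if t_window is not None:
        df = df[(df["t"] >= t_window[0] - 1e-12) & (df["t"] <= t_window[1] + 1e-12)]
    sel = df["systole"].astype(bool) if phase == "systole" \
        else ~df["systole"].astype(bool)
    df = df[sel]
    if len(df) < 2:
        raise PhaseError(f"phase window '{phase}' is empty")
    return float(np.trapezoid(df[flux].to_numpy(), df["t"].to_numpy()))


# ----------------------------------------------------------------------
# report
# ----------------------------------------------------------------------

@dataclass
class MetricReport:
    """Cycle-integrated regurgitation/transit quantities for one case.

    Volumes in cm^3, areas in cm^2, normalized columns in percent.
    ``eq1_residual`` is |Vreg/SV - EOA/MVA| (both in %), the deviation from
    the direct proportionality between functional and structural severity.
    """

    mva: float
    eoa: float
    sv: float
    vreg_mva: float
    vreg: float
    vreg_old: float = float("nan")
    vlva: float = float("nan")
    vresidual_pct: float = float("nan")
    eoa_mva_pct: float = field(init=False)
    vreg_false: float = field(init=False)
    vreg_sv_pct: float = field(init=False)
    vregold_vreg_pct: float = field(init=False)
    eq1_residual: float = field(init=False)

    def __post_init__(self) -> None:
        self.eoa_mva_pct = 100.0 * self.eoa / self.mva
        self.vreg_false = self.vreg_mva - self.vreg
        self.vreg_sv_pct = 100.0 * self.vreg / self.sv
        self.vregold_vreg_pct = (100.0 * self.vreg_old / self.vreg
                                 if self.vreg > 0 else float("nan"))
        self.eq1_residual = abs(self.vreg_sv_pct - self.eoa_mva_pct)

    def to_dict(self) -> dict:
        return asdict(self)


def build_report(series: pd.DataFrame, *, mva: float, eoa: float, sv: float,
                 vresidual: float | None = None,
                 sys_window: tuple[float, float] | None = None,
                 dia_window: tuple[float, float] | None = None) -> MetricReport:
    """Assemble the per-case report from a metric time series.

    ``vresidual`` is the residual-volume fraction (0..1) measured at end
    systole one cycle after marking; windows select which systole/diastole
    of a multi-cycle series to integrate.
    """
    vreg = integrate_phase(series, "systole", "qmv", sys_window)
    vreg_mva = integrate_phase(series, "systole", "qmva", sys_window)
    vreg_old = integrate_phase(series, "systole", "qmv_old", sys_window)
    try:
        vlva = integrate_phase(series, "diastole", "qlv", dia_window)
    except PhaseError:
        vlva = float("nan")
    return MetricReport(mva=mva, eoa=eoa, sv=sv, vreg_mva=vreg_mva, vreg=vreg,
                        vreg_old=vreg_old, vlva=vlva,
                        vresidual_pct=float("nan") if vresidual is None
                        else 100.0 * vresidual)
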