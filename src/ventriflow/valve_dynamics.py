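"""Asymptotic two-degree-of-freedom mitral-valve dynamics.

The leaflets carry no elastic forces: at every instant the opening-angle
rates minimize, in the least-squares sense over the valvular surface, the
mismatch between the fluid velocity and the valve velocity component normal
to the leaflets.  This yields a 2x2 linear system

    M_ij = iint (dXv/dphi_i . n)(dXv/dphi_j . n) dA,
    b_i  = iint (v . n)(dXv/dphi_i . n) dA,      M r = b

for the two rates.  The chordae tendineae are replaced by the kinematic
constraint that the valve cannot open toward the atrium (angles clamped to
[0, pi/2]).  The aortic valve is a simple orifice that opens when the mitral
valve is closed and the mean normal velocity at the orifice points toward
the aorta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import HALF_PI, ValveFamily, _dinterp_dphi, _interp_leaflet

#: diagonal entries of M below this (cm^4) freeze the corresponding leaflet
EPS_M = 1e-10
#: both angles below this (rad) count as "MV closed" for the aortic valve
PHI_CLOSED_TOL = 0.02


@dataclass
class ValveState:
    """Opening angles (rad, in [0, pi/2]) and their rates (rad/s)."""

    phi1: float = 0.0
    phi2: float = 0.0
    dphi1: float = 0.0
    dphi2: float = 0.0

    def clamped(self) -> "ValveState":
        return ValveState(float(np.clip(self.phi1, 0.0, HALF_PI)),
                          float(np.clip(self.phi2, 0.0, HALF_PI)),
                          self.dphi1, self.dphi2)

    @property
    def angles(self) -> np.ndarray:
        return np.array([self.phi1, self.phi2])

    def is_closed(self, tol: float = PHI_CLOSED_TOL) -> bool:
        return self.phi1 < tol and self.phi2 < tol


@dataclass
class ValveSystem:
    """The assembled least-squares system M r = b."""

    M: np.ndarray  # (2, 2), cm^4
    b: np.ndarray  # (2,), cm^4/s


@dataclass
class AorticValveState:
    open: bool = False


def _leaflet_quadrature(family: ValveFamily, phis, leaflet: int):
    """Facet centroids, normals*area and dX/dphi at centroids."""
    lf = family.leaflets[leaflet]
    surf = _interp_leaflet(lf, float(phis[leaflet]))
    cen = surf.facet_centroids()
    n, area = surf.facet_normals_areas()
    dX = _dinterp_dphi(lf, float(phis[leaflet]))
    p00, p10, p01, p11 = (dX[:-1, :-1], dX[1:, :-1], dX[:-1, 1:], dX[1:, 1:])
    dXc = 0.25 * (p00 + p10 + p01 + p11)
    return cen.reshape(-1, 3), (n * area[..., None]).reshape(-1, 3), dXc.reshape(-1, 3)


def assemble_system(family: ValveFamily, state: ValveState,
                    fluid_sampler) -> ValveSystem:
    """Build M and b by one-point (centroid) quadrature over both leaflets.

    The off-diagonal entries are integrated explicitly even though the two
    derivative fields have disjoint support (one leaflet each), so they
    vanish here but would not for a single shared surface.
    """
    phis = (state.phi1, state.phi2)
    M = np.zeros((2, 2))
    b = np.zeros(2)
    for leaflet in range(2):
        cen, ndA, dXc = _leaflet_quadrature(family, phis, leaflet)
        nda_mag = np.linalg.norm(ndA, axis=-1)
        # g_i = (dXv/dphi_i . n) dA on this leaflet; the other g is zero here
        g = np.einsum("pc,pc->p", dXc, ndA)
        M[leaflet, leaflet] += float(np.sum(g * g / np.maximum(nda_mag, 1e-300)))
        try:
            v = fluid_sampler(cen, state=state, leaflet=leaflet)
        except TypeError:
            v = fluid_sampler(cen)
        v = np.asarray(v, dtype=float)
        b[leaflet] += float(np.sum(np.einsum("pc,pc->p", v, ndA) * g
                                   / np.maximum(nda_mag, 1e-300)))
        # off-diagonal: integrand of g1 * g2 / dA; identically zero because
        # dX/dphi_other vanishes on this leaflet
    return ValveSystem(M, b)


def solve_rates(system: ValveSystem, eps: float = EPS_M) -> tuple[float, float]:
    """Solve M r = b; a leaflet with a degenerate diagonal entry is frozen."""
    M = system.M.copy()
    b = system.b.copy()
    active = np.diag(M) > eps
    r = np.zeros(2)
    if active.all():
        r = np.linalg.solve(M, b)
    elif active.any():
        i = int(np.flatnonzero(active)[0])
        r[i] = b[i] / M[i, i]
    return float(r[0]), float(r[1])


def valve_rates(family: ValveFamily, state: ValveState, fluid_sampler,
                rate_max: float | None = None) -> tuple[float, float]:
    r1, r2 = solve_rates(assemble_system(family, state, fluid_sampler))
    if rate_max is not None:
        r1 = float(np.clip(r1, -rate_max, rate_max))
        r2 = float(np.clip(r2, -rate_max, rate_max))
    return r1, r2


def offset_normal_sampler(family: ValveFamily, base_sampler, offset: float):
    """Sample the fluid on both sides of a leaflet, offset along its normal.

    In the coupled solver the cells cut by a leaflet carry the leaflet's own
    prescribed velocity, so sampling exactly on the surface feeds the valve
    model its previous rates back (a runaway).  Averaging samples displaced
    by ``offset`` on the two sides returns the evolved fluid velocity
    instead.  Requires the state/leaflet context from
    :func:`assemble_system`.
    """

    def sampler(points, state=None, leaflet=None):
        if state is None or leaflet is None:
            return base_sampler(points)
        _, ndA, _ = _leaflet_quadrature(family, (state.phi1, state.phi2),
                                        leaflet)
        mag = np.linalg.norm(ndA, axis=-1, keepdims=True)
        n = ndA / np.maximum(mag, 1e-300)
        vp = np.asarray(base_sampler(points + offset * n), float)
        vm = np.asarray(base_sampler(points - offset * n), float)
        return 0.5 * (vp + vm)

    return sampler


def step_valve(family: ValveFamily, state: ValveState, fluid_sampler,
               dt: float, phase=None, t: float = 0.0) -> ValveState:
    """Advance the angles one SSP-RK3 step, clamping to [0, pi/2].

    Clamping at zero is the discrete form of the no-opening-toward-the-atrium
    constraint; the same Runge-Kutta combinations as the flow solver are
    used so the coupled advancement stays third-order.  If the sampler
    accepts a ``t`` keyword it receives each stage's time (needed for
    time-dependent manufactured fields).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    y0 = state.angles

    def rates_at(y, stage_t):
        st = ValveState(float(y[0]), float(y[1])).clamped()

        def sampler(points, **kw):
            try:
                return fluid_sampler(points, t=stage_t, **kw)
            except TypeError:
                return fluid_sampler(points, **kw)

        return np.array(valve_rates(family, st, sampler))

    r0 = rates_at(y0, t)
    y1 = np.clip(y0 + dt * r0, 0.0, HALF_PI)
    r1 = rates_at(y1, t + dt)
    y2 = np.clip(0.75 * y0 + 0.25 * (y1 + dt * r1), 0.0, HALF_PI)
    r2 = rates_at(y2, t + 0.5 * dt)
    y3 = np.clip(y0 / 3.0 + 2.0 / 3.0 * (y2 + dt * r2), 0.0, HALF_PI)
    return ValveState(float(y3[0]), float(y3[1]), float(r2[0]), float(r2[1]))


def leaflet_centroid_velocity(family: ValveFamily, state: ValveState,
                              leaflet: int, rate: float) -> np.ndarray:
    """Valve surface velocity dXv/dphi * rate at facet centroids.

    Verification utility: a fluid sampler built from this field makes the
    least-squares model recover the prescribed rates exactly.
    """
    _, _, dXc = _leaflet_quadrature(family, (state.phi1, state.phi2), leaflet)
    return dXc * rate


def prescribed_motion_sampler(family: ValveFamily, rates_fn):
    """Fluid sampler whose field equals the valve's own kinematic velocity.

    ``rates_fn(state)`` returns the prescribed (omega1, omega2); the sampler
    relies on the state/leaflet context passed by :func:`assemble_system`.
    """

    def sampler(points, state=None, leaflet=None, t=None):
        if state is None or leaflet is None:
            raise ValueError("sampler requires state/leaflet context")
        try:
            om = rates_fn(state, t)
        except TypeError:
            om = rates_fn(state)
        return leaflet_centroid_velocity(family, state, leaflet, om[leaflet])

    return sampler


def update_aortic_valve(mv_state: ValveState, mean_outflow_velocity: float,
                        phi_tol: float = PHI_CLOSED_TOL,
                        previous: AorticValveState | None = None
                        ) -> AorticValveState:
    """Aortic valve open/close logic.

    The valve *opens* when the mitral valve is closed and the mean normal
    velocity at the orifice is directed toward the aorta; once open it
    *closes* only when that flow reverses (hysteresis -- closure of the real
    valve is flow-reversal driven, and this keeps a sub-tolerance flutter of
    the mitral angles from sealing the chamber mid-ejection).
    """
    was_open = previous.open if previous is not None else False
    aortward = mean_outflow_velocity > 0.0
    return AorticValveState(
        open=bool(aortward and (was_open or mv_state.is_closed(phi_tol))))
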