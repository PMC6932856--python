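"""Asymptotic valve model: assembly, rates, clamping, aortic valve logic."""

import numpy as np
import pytest

from ventriflow.geometry import HALF_PI, interpolate_valve, make_mv_family
from ventriflow.valve_dynamics import (AorticValveState, ValveState,
                                       ValveSystem, assemble_system,
                                       leaflet_centroid_velocity,
                                       prescribed_motion_sampler, solve_rates,
                                       step_valve, update_aortic_valve,
                                       valve_rates)


@pytest.fixture(scope="module")
def family():
    return make_mv_family("healthy", 0.0)


class TestAssembly:
    def test_quiescent_fluid_gives_zero_rhs(self, family):
        st = ValveState(0.5, 0.9)
        sys = assemble_system(family, st, lambda p: np.zeros_like(p))
        assert np.allclose(sys.b, 0.0)
        assert solve_rates(sys) == (0.0, 0.0)

    def test_matrix_symmetric_psd_and_block_diagonal(self, family, rng):
        for _ in range(25):
            st = ValveState(rng.uniform(0, HALF_PI), rng.uniform(0, HALF_PI))
            sys = assemble_system(family, st, lambda p: np.zeros_like(p))
            assert np.abs(sys.M - sys.M.T).max() < 1e-12 * max(sys.M.max(), 1)
            assert np.linalg.eigvalsh(sys.M).min() >= -1e-12
            # disjoint leaflet support: off-diagonals vanish
            assert sys.M[0, 1] == 0.0

    def test_prescribed_motion_recovered_exactly(self, family, rng):
        for _ in range(5):
            st = ValveState(rng.uniform(0.05, 1.5), rng.uniform(0.05, 1.5))
            om = rng.uniform(-3, 3, size=2)
            sampler = prescribed_motion_sampler(family, lambda s: om)
            r = valve_rates(family, st, sampler)
            assert r[0] == pytest.approx(om[0], rel=1e-6)
            assert r[1] == pytest.approx(om[1], rel=1e-6)

    def test_linearity_flow_reversal_flips_rates(self, family):
        st = ValveState(0.7, 0.4)
        om = np.array([1.1, -0.6])
        fwd = valve_rates(family, st, prescribed_motion_sampler(
            family, lambda s: om))
        rev = valve_rates(family, st, prescribed_motion_sampler(
            family, lambda s: -om))
        assert fwd[0] == pytest.approx(-rev[0], rel=1e-9)
        assert fwd[1] == pytest.approx(-rev[1], rel=1e-9)

    def test_flat_flap_hand_quadrature(self):
        # uniform flow U normal to one flat facet with a uniform angle
        # derivative r: M11 = A r^2, b1 = A U r
        from ventriflow.valve_dynamics import ValveSystem
        A, r, U = 0.6, 0.8, 12.0
        M11 = A * r * r
        b1 = A * U * r
        rate = solve_rates(ValveSystem(np.diag([M11, 0.0]),
                                       np.array([b1, 0.0])))
        assert rate[0] == pytest.approx(U / r)
        assert rate[1] == 0.0


class TestSolveRates:
    def test_identity_system(self):
        assert solve_rates(ValveSystem(np.eye(2), np.array([1.0, 2.0]))) \
            == (1.0, 2.0)

    def test_degenerate_leaflet_frozen(self):
        sys = ValveSystem(np.diag([2.0, 0.0]), np.array([3.0, 4.0]))
        assert solve_rates(sys) == (1.5, 0.0)

    def test_matches_direct_inverse(self, rng):
        for _ in range(20):
            a = rng.standard_normal((2, 2))
            M = a @ a.T + 0.1 * np.eye(2)
            b = rng.standard_normal(2)
            r = solve_rates(ValveSystem(M, b))
            exact = np.linalg.inv(M) @ b
            assert np.abs(np.array(r) - exact).max() < 1e-12 * max(
                1, np.abs(exact).max())


class TestStepValve:
    def test_zero_rates_leave_state(self, family):
        st = ValveState(0.3, 0.8)
        out = step_valve(family, st, lambda p: np.zeros_like(p), 1e-3)
        assert out.phi1 == st.phi1
        assert out.phi2 == st.phi2

    def test_constant_rate_exact(self, family):
        om = (0.5, -0.3)
        st = ValveState(0.6, 0.9)
        out = step_valve(family, st,
                         prescribed_motion_sampler(family, lambda s: om), 1e-2)
        assert out.phi1 == pytest.approx(0.6 + 0.5 * 1e-2, abs=1e-8)
        assert out.phi2 == pytest.approx(0.9 - 0.3 * 1e-2, abs=1e-8)

    def test_clamp_at_closed_position(self, family):
        st = ValveState(0.0, 0.0)
        out = step_valve(family, st,
                         prescribed_motion_sampler(family,
                                                   lambda s: (-2.0, -2.0)),
                         5e-3)
        assert out.phi1 == 0.0
        assert out.phi2 == 0.0

    def test_trajectory_recovery_third_order(self, family, rng):
        """Angles driven by a manufactured velocity field are reproduced
        with RK3 accuracy: halving dt cuts the error by ~8."""
        for _ in range(3):
            a1, a2 = rng.uniform(0.5, 1.5, size=2)
            w1, w2 = rng.uniform(3.0, 7.0, size=2)

            def omega(t):
                return np.array([a1 * np.sin(w1 * t), a2 * np.cos(w2 * t)])

            def exact(t):
                return np.array([0.5 + a1 * (1 - np.cos(w1 * t)) / w1,
                                 0.5 + a2 * np.sin(w2 * t) / w2])

            sampler = prescribed_motion_sampler(family,
                                                lambda s, t: omega(t))
            errs = []
            for nsteps in (8, 16):
                dt = 0.2 / nsteps
                st = ValveState(0.5, 0.5)
                for k in range(nsteps):
                    st = step_valve(family, st, sampler, dt, t=k * dt)
                errs.append(np.abs(st.angles - exact(0.2)).max())
            # third-order scheme: halving dt shrinks the error ~8x
            assert errs[0] / errs[1] > 6.0


class TestAorticValve:
    @pytest.mark.parametrize("phi,vel,was_open,expect", [
        ((1.2, 1.2), 10.0, False, False),   # MV open blocks AV opening
        ((0.0, 0.0), 10.0, False, True),    # MV closed, aortward flow
        ((0.0, 0.0), -1.0, False, False),   # flow toward the ventricle
        ((0.5, 0.0), 5.0, True, True),      # hysteresis: stays open
        ((0.0, 0.0), -0.1, True, False),    # closes on flow reversal
    ])
    def test_logic(self, phi, vel, was_open, expect):
        st = ValveState(*phi)
        out = update_aortic_valve(st, vel,
                                  previous=AorticValveState(was_open))
        assert out.open is expect
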