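"""Regurgitation metrics: orifice geometry, flow rates, phase integrals,
report identities and the printed-table worked examples."""

import numpy as np
import pandas as pd
import pytest

from ventriflow.errors import PhaseError
from ventriflow.geometry import interpolate_valve, make_mv_family
from ventriflow.metrics import (MetricReport, OrificeGeometry, annulus_flow,
                                build_report, extract_orifice, integrate_phase,
                                mvo_area, old_blood_flow, orifice_flow)
from ventriflow.surfaces import StructuredSurface


def parallel_edge_orifice(length=2.0, gap=0.3, n=41):
    """Two straight parallel trailing edges (synthetic leaflet pair)."""
    y = np.linspace(0, length, n)
    ant = np.stack([np.full_like(y, gap / 2), y, np.zeros_like(y)], axis=-1)
    post = np.stack([np.full_like(y, -gap / 2), y, np.zeros_like(y)], axis=-1)

    def leaflet(edge):
        # build a 4-row sheet whose last s-row is the edge
        rows = [edge + np.array([0, 0, -0.3 * (3 - j)]) for j in range(4)]
        return StructuredSurface(np.stack(rows, axis=1))

    return leaflet(ant), leaflet(post)


class TestOrificeGeometry:
    def test_coapting_edges_have_zero_gap(self):
        fam = make_mv_family("healthy", 0.0)
        orif = extract_orifice(interpolate_valve(fam, 0, 0))
        assert orif.gap.max() < 1e-9
        assert mvo_area(orif) < 1e-9

    def test_parallel_edges(self):
        orif = extract_orifice(parallel_edge_orifice())
        assert orif.length == pytest.approx(2.0, rel=1e-6)
        assert np.allclose(orif.gap, 0.3)
        assert mvo_area(orif) == pytest.approx(0.6, rel=1e-6)

    def test_defect_localized_to_scallop(self):
        fam = make_mv_family("P2like", 0.8)
        orif = extract_orifice(interpolate_valve(fam, 0, 0))
        # the gap is localized: a contiguous open sector, closed elsewhere
        open_frac = np.mean(orif.gap > 0.05)
        assert 0.1 < open_frac < 0.7
        peak = np.argmax(orif.gap)
        assert orif.gap[0] < 0.05 and orif.gap[-1] < 0.05
        assert 0.2 < peak / len(orif.gap) < 0.8

    def test_mvo_quadrature_second_order(self):
        # smooth gap profile against refinement
        def area(n):
            y = np.linspace(0, 2, n)
            gapw = 0.2 + 0.1 * np.sin(np.pi * y / 2)
            ant = np.stack([gapw / 2, y, np.zeros_like(y)], -1)
            post = np.stack([-gapw / 2, y, np.zeros_like(y)], -1)

            def lf(e):
                rows = [e + [0, 0, -0.2 * (3 - j)] for j in range(4)]
                return StructuredSurface(np.stack(rows, axis=1))
            return mvo_area(extract_orifice((lf(ant), lf(post)),
                                            n_stations=n))

        exact = 0.2 * 2 + 0.1 * (2 / np.pi) * (1 - np.cos(np.pi))
        e1 = abs(area(21) - exact)
        e2 = abs(area(41) - exact)
        assert e1 / max(e2, 1e-15) > 3.0


class TestOrificeFlow:
    def test_uniform_normal_flow(self):
        orif = extract_orifice(parallel_edge_orifice(length=2.0, gap=0.3))
        U = 7.5
        q = orifice_flow(lambda p: np.tile([0, 0, U], (len(p), 1)), orif)
        assert q == pytest.approx(U * 0.3 * 2.0, rel=1e-6)

    def test_fluid_moving_with_edges_gives_zero(self):
        ant, post = parallel_edge_orifice()
        vel = np.array([0.0, 0.0, 4.0])
        for s in (ant, post):
            s.velocities[:] = vel
        orif = extract_orifice((ant, post))
        q = orifice_flow(lambda p: np.tile(vel, (len(p), 1)), orif)
        assert abs(q) < 1e-9

    def test_smooth_field_against_dense_quadrature(self):
        orif = extract_orifice(parallel_edge_orifice(n=81))

        def field(p):
            return np.stack([np.zeros(len(p)), np.zeros(len(p)),
                             3.0 + np.sin(2.0 * p[:, 1]) + 0.5 * p[:, 0]],
                            axis=-1)

        q5 = orifice_flow(field, orif, n_gauss=5)
        q_dense = orifice_flow(field, orif, n_gauss=24)
        assert q5 == pytest.approx(q_dense, rel=5e-3)

    def test_edge_velocity_conventions(self):
        ant, post = parallel_edge_orifice()
        ant.velocities[:] = [0.0, 0.0, 2.0]
        post.velocities[:] = [0.0, 0.0, -2.0]
        orif = extract_orifice((ant, post))
        still = lambda p: np.zeros((len(p), 3))  # noqa: E731
        q_mean = orifice_flow(still, orif, edge_velocity="mean")
        q_half = orifice_flow(still, orif, edge_velocity="half-difference")
        assert q_mean == pytest.approx(0.0, abs=1e-9)   # edge mean vanishes
        assert q_half == pytest.approx(-2.0 * 0.3 * 2.0, rel=1e-6)


class TestOldBloodFlow:
    @pytest.mark.parametrize("c", [1.0, 0.0, 0.5])
    def test_uniform_concentration_scales_flow(self, c):
        orif = extract_orifice(parallel_edge_orifice())
        field = lambda p: np.tile([0, 0, 5.0], (len(p), 1))  # noqa: E731
        q = orifice_flow(field, orif)
        q_old = old_blood_flow(field, lambda p: np.full(len(p), c), orif)
        assert q_old == pytest.approx(c * q, rel=1e-9)


class TestAnnulusFlow:
    def test_uniform_flux(self):
        q = annulus_flow(lambda p: np.tile([0, 0, 2.0], (len(p), 1)),
                         (0.0, 0.0), radius=1.5, z=0.0)
        assert q == pytest.approx(2.0 * np.pi * 1.5 ** 2, rel=1e-3)

    def test_relative_velocity_cancels(self):
        v = np.array([1.0, -2.0, 3.0])
        q = annulus_flow(lambda p: np.tile(v, (len(p), 1)),
                         (0.0, 0.0), 1.0, 0.0, annulus_velocity=v)
        assert abs(q) < 1e-12


class TestIntegratePhase:
    def make_series(self):
        t = np.linspace(0, 1, 201)
        sys_flag = t < 0.35
        return pd.DataFrame({"t": t, "q": np.where(sys_flag, 10.0, 0.0),
                             "systole": sys_flag.astype(float)})

    def test_constant_flux_over_systole(self):
        df = self.make_series()
        v = integrate_phase(df, "systole", "q")
        assert v == pytest.approx(10.0 * 0.35, rel=0.02)

    def test_antisymmetric_flux_cancels(self):
        t = np.linspace(0, 0.35, 101)
        df = pd.DataFrame({"t": t, "q": np.sin(2 * np.pi * t / 0.35),
                           "systole": np.ones_like(t)})
        assert abs(integrate_phase(df, "systole", "q")) < 1e-12

    def test_empty_phase_raises(self):
        df = self.make_series()
        df["systole"] = 1.0
        with pytest.raises(PhaseError):
            integrate_phase(df, "diastole", "q")

    def test_window_restriction(self):
        df = self.make_series()
        v = integrate_phase(df, "systole", "q", t_window=(0.0, 0.175))
        assert v == pytest.approx(1.75, rel=0.03)


class TestReport:
    def test_false_regurgitation_identity(self):
        # total and orifice regurgitation as printed for the P3 prolapse
        r = MetricReport(mva=4.83, eoa=0.52, sv=66.95, vreg_mva=8.87,
                         vreg=6.29, vreg_old=2.36)
        assert r.vreg_false == pytest.approx(8.87 - 6.29, abs=1e-12)
        assert r.vreg_false == pytest.approx(2.58, abs=1e-9)
        assert r.vreg_sv_pct == pytest.approx(9.40, abs=0.01)
        assert r.eoa_mva_pct == pytest.approx(11.0, abs=0.3)

    def test_normalizations_p2(self):
        r = MetricReport(mva=4.26, eoa=0.87, sv=66.95, vreg_mva=13.42,
                         vreg=12.76, vreg_old=6.42)
        assert r.vreg_sv_pct == pytest.approx(19.07, abs=0.02)
        assert r.vregold_vreg_pct == pytest.approx(50.31, abs=0.01)
        assert r.eoa_mva_pct == pytest.approx(20.4, abs=0.1)

    def test_build_report_from_series(self):
        t = np.linspace(0, 1, 401)
        sys_flag = (t < 0.35).astype(float)
        qmv = np.where(t < 0.35, 6.0, -50.0)
        qmva = np.where(t < 0.35, 8.0, -50.0)
        qold = np.where(t < 0.35, 3.0, 0.0)
        qlv = np.where(t >= 0.35, 66.95 / 0.65, 0.0)
        df = pd.DataFrame({"t": t, "qmv": qmv, "qmva": qmva, "qmv_old": qold,
                           "qlv": qlv, "systole": sys_flag})
        r = build_report(df, mva=6.2, eoa=0.06, sv=66.95, vresidual=0.285)
        assert r.vreg == pytest.approx(6.0 * 0.35, rel=0.02)
        assert r.vreg_false == pytest.approx(2.0 * 0.35, rel=0.05)
        assert r.vresidual_pct == pytest.approx(28.5)
        assert r.vlva == pytest.approx(66.95, rel=0.02)
        assert r.eq1_residual == abs(r.vreg_sv_pct - r.eoa_mva_pct)
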