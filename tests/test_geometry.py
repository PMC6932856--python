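"""Synthetic ventricle, valve family and domain assembly."""

import numpy as np
import pytest

from ventriflow.errors import LayoutError
from ventriflow.geometry import (DILATED_LV, HEALTHY_LV, compose_domain,
                                 dilated_waveform, healthy_waveform,
                                 interpolate_valve, make_lv_surface,
                                 make_mv_family, severity_for_eoa,
                                 valve_config_derivative)
from ventriflow.metrics import extract_orifice, mvo_area
from ventriflow.surfaces import lv_volume

HALF_PI = np.pi / 2


class TestWaveform:
    def test_periodicity_and_extremes(self):
        wf = healthy_waveform()
        assert wf.volume(0.0) == pytest.approx(wf.volume(wf.period), abs=1e-9)
        t = np.linspace(0, wf.period, 2001)
        v = wf.volume(t)
        assert v.max() == pytest.approx(wf.edv, abs=1e-6)
        assert v.min() == pytest.approx(wf.esv, abs=1e-6)
        assert wf.sv == pytest.approx(66.95)
        assert wf.ef == pytest.approx(0.59, abs=0.005)

    def test_systole_is_where_volume_decreases(self):
        wf = dilated_waveform()
        t = np.linspace(0.001, wf.period - 0.001, 999)
        dv = wf.dvolume_dt(t)
        sys_flag = wf.in_systole(t)
        assert (dv[sys_flag] <= 1e-9).all()
        assert (dv[~sys_flag] >= -1e-9).all()

    def test_derivative_consistent_with_volume(self):
        wf = healthy_waveform()
        # compare inside each phase (away from the piecewise joins)
        t = np.linspace(0.02, 0.33, 200)
        h = 1e-6
        fd = (wf.volume(t + h) - wf.volume(t - h)) / (2 * h)
        assert np.abs(fd - wf.dvolume_dt(t)).max() < 1e-3 * np.abs(fd).max()

    def test_invalid_volumes_rejected(self):
        from ventriflow.geometry import VolumeWaveform
        with pytest.raises(ValueError):
            VolumeWaveform(edv=50.0, esv=60.0)


class TestLV:
    def test_volume_tracks_waveform(self, healthy_lv):
        wf = healthy_lv.waveform
        for t in np.linspace(0, 1, 23):
            assert abs(healthy_lv.volume_at(t) - wf.volume(t)) / wf.sv < 5e-3

    @pytest.mark.parametrize("shape,wf_fn,t,expected", [
        (HEALTHY_LV, healthy_waveform, 0.0, 113.47),     # end diastole
        (DILATED_LV, dilated_waveform, 0.35, 142.50),    # end systole
    ])
    def test_preset_volumes(self, shape, wf_fn, t, expected):
        lv = make_lv_surface(shape, wf_fn(), 32, 25)
        assert lv.volume_at(t) == pytest.approx(expected, rel=5e-3)

    def test_velocities_match_position_derivative(self, healthy_lv):
        dt = 1e-5
        s0 = healthy_lv.at(0.2)
        s1 = healthy_lv.at(0.2 + dt)
        fd = (s1.positions - s0.positions) / dt
        scale = np.abs(s0.velocities).max()
        assert np.abs(fd - s0.velocities).max() < 1e-2 * scale

    def test_static_waveform_gives_zero_velocity(self):
        from ventriflow.geometry import VolumeWaveform
        wf = VolumeWaveform(edv=100.0, esv=99.99)  # essentially constant
        lv = make_lv_surface(HEALTHY_LV, wf, 24, 17)
        assert np.abs(lv.at(0.3).velocities).max() < 0.05

    def test_annulus_ring_is_stationary(self, healthy_lv):
        r0 = healthy_lv.at(0.0).positions[:, 0]
        r1 = healthy_lv.at(0.2).positions[:, 0]
        assert np.abs(r0 - r1).max() < 1e-12


class TestValveFamily:
    def test_full_coaptation_at_zero_severity(self, healthy_family):
        surfs = interpolate_valve(healthy_family, 0.0, 0.0)
        assert mvo_area(extract_orifice(surfs)) < 1e-6

    def test_endpoints_exact(self, healthy_family):
        closed = interpolate_valve(healthy_family, 0.0, 0.0)
        opened = interpolate_valve(healthy_family, HALF_PI, HALF_PI)
        for lf, srf in zip(healthy_family.leaflets, closed):
            assert np.abs(srf.positions - lf.closed.positions).max() < 1e-12
        for lf, srf in zip(healthy_family.leaflets, opened):
            assert np.abs(srf.positions - lf.open.positions).max() < 1e-12

    def test_eoa_increases_with_severity(self):
        areas = []
        for sev in (0.25, 0.5, 0.75, 1.0):
            fam = make_mv_family("P2like", sev)
            areas.append(mvo_area(extract_orifice(interpolate_valve(fam, 0, 0))))
        assert np.all(np.diff(areas) > 0)

    def test_annulus_identical_across_severities(self):
        f0 = make_mv_family("P3like", 0.0)
        f1 = make_mv_family("P3like", 0.9)
        for a, b in zip(f0.leaflets, f1.leaflets):
            assert np.abs(a.closed.positions[:, 0]
                          - b.closed.positions[:, 0]).max() < 1e-12

    def test_p3_severity_reaches_reported_normalized_eoa(self):
        # posteromedial prolapse tuned to EOA/MVA = 11 %
        sev = severity_for_eoa("P3like", 0.11 * 4.83)
        fam = make_mv_family("P3like", sev)
        eoa = mvo_area(extract_orifice(interpolate_valve(fam, 0, 0)))
        assert eoa / fam.mva == pytest.approx(0.11, abs=1e-3)

    def test_mva_presets(self):
        assert make_mv_family("healthy").mva == pytest.approx(6.20)
        assert make_mv_family("P3like").mva == pytest.approx(4.83)
        assert make_mv_family("P2like").mva == pytest.approx(4.26)

    def test_angle_out_of_range_raises(self, healthy_family):
        with pytest.raises(ValueError):
            interpolate_valve(healthy_family, -0.2, 0.0)
        with pytest.raises(ValueError):
            interpolate_valve(healthy_family, 0.0, 2.0)

    def test_interpolation_continuity_in_angle(self, healthy_family):
        a = interpolate_valve(healthy_family, 0.7, 0.3)[0].positions
        b = interpolate_valve(healthy_family, 0.7 + 1e-3, 0.3)[0].positions
        leaflet_len = 1.5
        assert np.abs(a - b).max() < 1e-2 * leaflet_len


class TestValveDerivative:
    def test_cross_leaflet_derivative_vanishes(self, healthy_family):
        d = valve_config_derivative(healthy_family, 0.4, 0.4, leaflet=0, wrt=1)
        assert np.abs(d).max() == 0.0

    def test_finite_difference_second_order(self, healthy_family):
        from ventriflow.geometry import _dinterp_dphi
        exact = _dinterp_dphi(healthy_family.leaflets[0], np.pi / 4)
        e1 = np.abs(valve_config_derivative(healthy_family, np.pi / 4, np.pi / 4,
                                            0, h=1e-3) - exact).max()
        e2 = np.abs(valve_config_derivative(healthy_family, np.pi / 4, np.pi / 4,
                                            0, h=2e-3) - exact).max()
        assert e2 / e1 == pytest.approx(4.0, rel=0.2)

    def test_edge_moves_more_than_annulus(self, healthy_family):
        d = valve_config_derivative(healthy_family, np.pi / 4, np.pi / 4, 0)
        edge = np.linalg.norm(d[:, -1], axis=-1).mean()
        annulus = np.linalg.norm(d[:, 0], axis=-1).mean()
        assert edge > 10 * annulus


class TestDomain:
    def test_compose_healthy(self, healthy_lv):
        fam = make_mv_family("healthy", base_z=healthy_lv.base_z)
        dom = compose_domain(healthy_lv, fam)
        assert dom.amva >= fam.mva - 1e-9   # annulus disk covers valve area
        top = dom.box_hi[2]
        assert np.abs(dom.atrium_tube.positions[:, -1, 2] - top).max() < 1e-9
        assert np.abs(dom.aorta_tube.positions[:, -1, 2] - top).max() < 1e-9

    def test_orifice_overlap_raises(self, healthy_lv):
        from ventriflow.geometry import AorticOrifice
        fam = make_mv_family("healthy", base_z=healthy_lv.base_z)
        bad = AorticOrifice(np.array([-0.5, 0.0, healthy_lv.base_z]), 1.2)
        with pytest.raises(LayoutError):
            compose_domain(healthy_lv, fam, aortic_params=bad)

    def test_basal_plate_has_orifice_holes(self, healthy_lv):
        fam = make_mv_family("healthy", base_z=healthy_lv.base_z)
        dom = compose_domain(healthy_lv, fam)
        plate = dom.basal_surface
        assert plate.facet_mask is not None
        # plate area = annulus disk minus the two orifice disks, roughly
        expect = (np.pi * healthy_lv.base_radius ** 2 - dom.amva
                  - dom.aortic.area)
        assert plate.area() == pytest.approx(expect, rel=0.05)
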