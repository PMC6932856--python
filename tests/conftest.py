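import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def unit_sphere_surface():
    from ventriflow.surfaces import StructuredSurface
    th = np.linspace(0, 2 * np.pi, 65)
    ps = np.linspace(0, np.pi, 65)
    T, P = np.meshgrid(th, ps, indexing="ij")
    pos = np.stack([np.sin(P) * np.cos(T), np.sin(P) * np.sin(T), np.cos(P)],
                   axis=-1)
    return StructuredSurface(pos, closed_theta=True)


@pytest.fixture(scope="session")
def healthy_lv():
    from ventriflow.geometry import HEALTHY_LV, healthy_waveform, make_lv_surface
    return make_lv_surface(HEALTHY_LV, healthy_waveform(), 40, 33)


@pytest.fixture(scope="session")
def healthy_family():
    from ventriflow.geometry import make_mv_family
    return make_mv_family("healthy", 0.0)
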