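import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from voidlapse.acquisition import CartesianSchedule, RadialSchedule
from voidlapse.phantom import ImageGrid, Particle, Scene


@pytest.fixture
def small_cartesian():
    return CartesianSchedule(matrix=(64, 64), fov=(12.8, 12.8), tr_ms=50.22, averages=1)


@pytest.fixture
def small_radial():
    """Tiny 3D radial schedule (~Nyquist for 24^3) for fast reconstruction tests."""
    return RadialSchedule(
        n_spokes=1800,
        interleave_factor=20,
        samples_per_spoke=25,
        matrix=(24, 24, 24),
        fov=(12.8, 12.8, 12.8),
        tr_ms=150.0,
        dual_echo=False,
    )


@pytest.fixture
def grid2d():
    return ImageGrid((64, 64), (12.8, 12.8))


@pytest.fixture
def grid3d():
    return ImageGrid((24, 24, 24), (12.8, 12.8, 12.8))


@pytest.fixture
def static_scene_2d():
    return Scene(particles=[Particle(0, np.array([2.0, 1.1]))])


@pytest.fixture
def static_scene_3d():
    return Scene(
        particles=[Particle(0, np.array([2.0, 1.1, 0.6]), void_amplitude=0.5, void_sigma=0.2)],
        cylinder_height=12.8,
    )


@pytest.fixture
def tiny_radial_preset(monkeypatch):
    """Register a scaled-down radial preset so pipeline tests stay fast."""
    from voidlapse.pipeline import SEQUENCE_PRESETS

    preset = dict(
        kind="radial",
        schedule=dict(
            n_spokes=1800,
            interleave_factor=20,
            samples_per_spoke=25,
            matrix=(24, 24, 24),
            fov=(12.8, 12.8, 12.8),
            tr_ms=267.08,
            dual_echo=True,
        ),
        void_amplitude=0.5,
        void_sigma=0.25,
        noise_sigma=0.4,
    )
    monkeypatch.setitem(SEQUENCE_PRESETS, "radial_tiny", preset)
    return "radial_tiny"
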