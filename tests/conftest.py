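import numpy as np
import pytest

from qpimass.config import NoiseConfig, OpticsConfig, RunConfig
from qpimass import phantom


@pytest.fixture(scope="session")
def optics():
    return OpticsConfig()


@pytest.fixture(scope="session")
def quiet_noise():
    return NoiseConfig(sigma_opd_um=0.0, sigma_intensity=0.0)


@pytest.fixture(scope="session")
def static_scene():
    """One motionless 240 pg cell on a 96x96 grid (50 frames)."""
    return phantom.build_scenario("static-cell", 5)[0]


@pytest.fixture(scope="session")
def static_stack(static_scene):
    return phantom.render_stack(static_scene, NoiseConfig(), seed=5)


def single_cell_scene(
    mass_pg=300.0,
    radius_um=7.0,
    size_px=64,
    n_frames=1,
    growth=0.0,
    optics=None,
    **cell_kw,
):
    """Helper: scene with one centred cell on a small grid."""
    from dataclasses import replace

    optics = replace(optics or OpticsConfig(), image_shape=(size_px, size_px))
    half = size_px * optics.pixel_um / 2
    cell = phantom.CellSpec(
        cell_id=1,
        role=phantom.ROLE_TARGET_HEALTHY,
        initial_mass_pg=mass_pg,
        radius_um=radius_um,
        growth_per_4h=growth,
        waypoints=[(0.0, half, half)],
        **cell_kw,
    )
    return phantom.build_scene(phantom.SceneConfig(optics=optics, n_frames=n_frames, cells=[cell]))
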