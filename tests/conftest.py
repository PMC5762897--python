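import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from migchip import chipmodel as cm
from migchip import quantify as q

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_geometry() -> cm.DeviceGeometry:
    """A 20-channel device (10 per side) with room for registration shifts."""
    return cm.DeviceGeometry(n_channels_per_side=10, margin_px=20)


@pytest.fixture(scope="session")
def small_config() -> q.QuantConfig:
    return q.QuantConfig(central_window=10)


@pytest.fixture(scope="session")
def mixed_scene(small_geometry) -> cm.SyntheticScene:
    """Noise-free pixel-aligned scene with live, dead and debris objects."""
    return cm.sample_scene(
        small_geometry,
        n_cells=40,
        distance_dist="uniform",
        dist_params={"low": 50.0, "high": 950.0},
        dead_fraction=0.3,
        debris_count=15,
        noise_sd=0.0,
        seed=11,
        snap_to_grid=True,
    )


@pytest.fixture(scope="session")
def mixed_image(mixed_scene) -> cm.RenderedImage:
    return cm.render(mixed_scene)


def single_cell_scene(
    geometry: cm.DeviceGeometry,
    distance_um: float,
    side: str = "left",
    channel_index: int = 0,
    viability: str = "live",
) -> cm.SyntheticScene:
    """Hand-built scene with exactly one cell at a chosen position."""
    cell = cm.GroundTruthCell(
        channel_index=channel_index,
        side=side,
        distance_um=distance_um,
        viability=viability,
        radius_um=6.0,
        peak_intensity=200,
    )
    return cm.SyntheticScene(
        geometry=geometry, cells=(cell,), debris=(), noise_sd=0.0, seed=0
    )
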