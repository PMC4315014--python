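"""Shared fixtures: a small fast phantom for unit tests and the full-protocol
study (24 phases, 8 mm tags, 160x160 at 1.25 mm) for the acceptance suite."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cardiodose as cd

settings.register_profile(
    "deterministic", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

SMALL_SHAPE = (96, 96)
SMALL_SPACING = 1.25


def small_geometry() -> cd.LVGeometry:
    c = (SMALL_SHAPE[0] - 1) / 2 * SMALL_SPACING
    return cd.LVGeometry(
        center=(c, c), endo_radius=16.0, epi_radius=26.0,
        image_shape=SMALL_SHAPE, pixel_spacing=SMALL_SPACING,
    )


def small_motion(**kwargs) -> cd.MotionModel:
    kwargs.setdefault("phase_count", 8)
    return cd.MotionModel(**kwargs)


@pytest.fixture(scope="session")
def small_study():
    """Noisy, coil-shaded 8-phase study on a 96x96 grid."""
    return cd.make_study(geometry=small_geometry(), motion=small_motion(), seed=11)


@pytest.fixture(scope="session")
def clean_small_study():
    """Noise-free, bias-free version of the small study."""
    return cd.make_study(
        geometry=small_geometry(), motion=small_motion(),
        noise_sd=0.0, bias_strength=0.0, seed=11,
    )


@pytest.fixture(scope="session")
def wedge_small_study():
    """Noise-free small study with a hypokinetic wedge at angle pi."""
    return cd.make_study(
        geometry=small_geometry(),
        motion=small_motion(wedge_center=float(np.pi)),
        noise_sd=0.0, bias_strength=0.0, seed=11,
    )


@pytest.fixture(scope="session")
def default_study():
    """Full-protocol study: 24 phases, 8 mm tags, default noise and shading."""
    return cd.make_study(seed=12)


@pytest.fixture(scope="session")
def clean_default_study():
    return cd.make_study(noise_sd=0.0, bias_strength=0.0, seed=12)


@pytest.fixture(scope="session")
def noisy_default_study():
    """SNR ~10 relative to the myocardial signal level."""
    return cd.make_study(noise_sd=10.0, seed=12)
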