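"""Shared fixtures: small synthetic shapes rendered fast.

Unit tests use small canvases (128-256 px) with the object filter lowered
accordingly; the full-size study conditions (512 px canvas, 50,000 px
filter) are exercised only by the end-to-end tests.
"""

import numpy as np
import pytest

from otolithid import RadialShape, RunConfig, render_image

SMALL_MIN_AREA = 500  # object filter for small rendered test shapes


def circle_shape(radius: float) -> RadialShape:
    return RadialShape(
        base_radius=radius,
        orders=np.array([]),
        amplitudes=np.array([]),
        phases=np.array([]),
    )


def harmonic_shape(radius: float, order: int, amplitude: float, phase: float = 0.0) -> RadialShape:
    return RadialShape(
        base_radius=radius,
        orders=np.array([float(order)]),
        amplitudes=np.array([amplitude]),
        phases=np.array([phase]),
    )


@pytest.fixture
def small_config() -> RunConfig:
    return RunConfig(min_area=SMALL_MIN_AREA)


@pytest.fixture
def disk_image() -> np.ndarray:
    """Disk of radius 40 on a 128x128 canvas, fg 0.2 / bg 0.05."""
    return render_image(circle_shape(40.0), canvas=(128, 128))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
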