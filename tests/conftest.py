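"""Shared fixtures: small phantoms reused across the suite.

Everything is generated at test time; session scope keeps the heavier
renders to one per run.
"""

from __future__ import annotations

import numpy as np
import pytest

from aortamorph import PhantomSpec, PipelineConfig, generate_phantom
from aortamorph.pipeline import run_morphometry


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    return 2.0 * np.sum(a & b) / (np.sum(a) + np.sum(b))


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Desk-scale straight vessel: 16 x 320 x 320, lumen r=60, wall 24."""
    return PhantomSpec(
        n_slices=16,
        slice_shape=(320, 320),
        lumen_radius_px=60.0,
        wall_thickness_px=24.0,
        n_lamellae=4,
        lamella_thickness_px=2.0,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def small_config() -> PipelineConfig:
    return PipelineConfig(central_window_n_slices=12)


@pytest.fixture(scope="session")
def small_run(small_spec, small_config):
    """Morphometry run (no reslicing needed: straight tube) on the small
    phantom; shared by segmentation/morphometry/pipeline tests."""
    return run_morphometry(small_config, spec=small_spec, reslice=False)


@pytest.fixture(scope="session")
def wrinkled_phantom():
    spec = PhantomSpec(
        n_slices=2,
        wrinkle_amplitude_px=5.0,
        wrinkle_frequency=12,
    )
    return spec, generate_phantom(spec)
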