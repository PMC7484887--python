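"""Shared fixtures: small-grid phantoms and the full simulated study.

The "small" grid (128 × 128 in-plane at 1.4 mm, 68 slices of 2.5 mm) still
contains the entire phantom plus the 30° shear excursion but keeps unit
tests fast; the full study fixture runs the packaged six-angle experiment
at its default 256² grid once per session.
"""

import numpy as np
import pytest

import stereoct as sc

SMALL_SHAPE = (68, 128, 128)
SMALL_SPACING = (1.4, 1.4, 2.5)


def small_phantom_spec(amalgam: bool) -> sc.PhantomSpec:
    return sc.PhantomSpec(amalgam=amalgam, spacing=SMALL_SPACING, grid_shape=SMALL_SHAPE)


@pytest.fixture(scope="session")
def small_baseline() -> sc.Volume:
    """Metal-free phantom on the small grid."""
    return sc.build_phantom(small_phantom_spec(amalgam=False), seed=0)


@pytest.fixture(scope="session")
def small_metal_phantom() -> sc.Volume:
    """Amalgam phantom on the small grid."""
    return sc.build_phantom(small_phantom_spec(amalgam=True), seed=0)


@pytest.fixture(scope="session")
def small_study() -> sc.StudyResult:
    """Reduced-angle study on the small grid (with artifacts)."""
    cfg = sc.StudyConfig(
        grid_shape=SMALL_SHAPE, spacing=SMALL_SPACING, angles=(5.0, 15.0, 25.0), seed=0
    )
    return sc.run_study(cfg)


@pytest.fixture(scope="session")
def full_study() -> sc.StudyResult:
    """The packaged six-angle experiment at its default study grid."""
    return sc.run_study(sc.StudyConfig(seed=0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
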