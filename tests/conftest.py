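import numpy as np
import pytest

from fetquant import (
    DEFAULT_SCHEDULE,
    BackgroundEstimate,
    Mask,
    PhantomSpec,
    VolumeGrid,
    make_static_phantom,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def schedule():
    return DEFAULT_SCHEDULE


@pytest.fixture
def noiseless_phantom():
    """Noiseless 48x48x24 phantom: background SUV 1.0, one TBR-2.5 lesion."""
    spec = PhantomSpec(background_sd=0.0)
    volume, lesion, bg_roi = make_static_phantom(spec)
    return spec, volume, lesion, bg_roi


@pytest.fixture
def unit_grid():
    """Helper to build small volumes/masks on an isotropic grid."""

    def build(values, spacing=(2.0, 2.0, 2.0), kind="volume", label="pet_segmentation"):
        values = np.asarray(values)
        affine = np.diag([*spacing, 1.0])
        if kind == "mask":
            return Mask(values.astype(np.uint8), affine, label=label)
        return VolumeGrid(values.astype(float), affine)

    return build
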