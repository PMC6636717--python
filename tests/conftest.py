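import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nucleomorph as nm

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

PIXEL_SIZE = 0.2  # um/px used throughout the suite


@pytest.fixture(scope="session")
def pixel_size():
    return PIXEL_SIZE


@pytest.fixture(scope="session")
def disk_mask():
    """Disk-like generated mask of ~2500 px (100 um^2 at 0.2 um/px)."""
    return nm.generate_shape(nm.ShapeSpec(area_um2=100, seed=1), PIXEL_SIZE)


@pytest.fixture(scope="session")
def textured_nucleus(disk_mask):
    """Bandpass-textured nucleus image on the session disk mask."""
    tex = nm.TextureSpec(length_scale_um=0.8, seed=5)
    return nm.generate_texture(disk_mask, tex, PIXEL_SIZE), disk_mask


@pytest.fixture(scope="session")
def noisy_field():
    """5-nucleus field with shifts, background and noise, plus ground truth."""
    acq = nm.AcquisitionSpec(
        n_frames=8, noise_sd=0.05, max_shift_px=4, background_amplitude=0.2, seed=7
    )
    shapes = [
        nm.ShapeSpec(area_um2=a, aspect_ratio=ar, seed=i)
        for i, (a, ar) in enumerate(
            [(100, 1.2), (150, 1.5), (80, 1.0), (200, 2.0), (120, 1.3)]
        )
    ]
    texs = [nm.TextureSpec(length_scale_um=0.8, seed=10 + i) for i in range(5)]
    stack, gt = nm.generate_field(shapes, texs, acq, field_shape=(300, 300))
    return stack, gt, acq
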