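import numpy as np
import pytest

from hippovol.phantom import PhantomSpec, generate_slice


def rasterize_ellipse(width, height, center, a, b):
    """Brute-force pixel enumeration of the ellipse inequality (test oracle)."""
    cx, cy = center
    count = 0
    for y in range(height):
        for x in range(width):
            if ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 <= 1.0:
                count += 1
    return count


@pytest.fixture(scope="session")
def noiseless_spec():
    return PhantomSpec(noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_phantom(noiseless_spec):
    return generate_slice(noiseless_spec, seed=1)


@pytest.fixture(scope="session")
def noisy_phantom():
    return generate_slice(PhantomSpec(noise_sd=8.0), seed=2)


@pytest.fixture(scope="session")
def small_spec():
    """A 249x249 phantom (half scale) for cheaper property tests."""
    return PhantomSpec(
        width=249,
        height=249,
        hippo_left_center=(88.5, 165.0),
        hippo_right_center=(163.5, 165.0),
        hippo_semi_axes=(10.0, 6.0),
        brain_radius=115.0,
        csf_rim=6.0,
        gm_band=15.0,
        moat_margin=4,
        noise_sd=0.0,
    )
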