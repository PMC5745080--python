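import numpy as np
import pytest

from embryoquant import angular, phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def small_gradient_spec():
    """A compact gradient phantom, noise-free, linear ratio 1 + 2x."""
    return phantom.GradientPhantomSpec(
        image_height=80,
        image_width=160,
        embryo_bbox=(20, 15, 40, 130),
        ratio_function=lambda x: 1 + 2 * x,
        nuclear_level=100.0,
        noise_sigma=0.0,
        seed=0,
    )


@pytest.fixture
def small_insitu_spec():
    """A compact in situ phantom with a quarter-circumference stain."""
    return phantom.InSituPhantomSpec(
        image_height=161,
        image_width=201,
        ellipse=angular.EllipseROI((80.0, 100.0), 90.0, 70.0),
        stain_sector=(90.0, 180.0),
        stain_band_depth=20.0,
        noise_sigma=0.0,
        seed=0,
    )


def brute_force_radial_sums(mask, ellipse, n_points=360, angle_offset_deg=0.0):
    """Independent scalar-loop ray-walk: unit steps, nearest-pixel lookup."""
    row0, col0 = ellipse.center
    rot = np.deg2rad(ellipse.rotation_deg)
    a, b = ellipse.semi_axis_a, ellipse.semi_axis_b
    sums = []
    for k in range(n_points):
        ang = np.deg2rad(angle_offset_deg + k * 360.0 / n_points)
        theta = ang - rot
        t_max = 1.0 / np.sqrt((np.cos(theta) / a) ** 2 + (np.sin(theta) / b) ** 2)
        total = 0
        t = 1
        while t <= int(np.floor(t_max)):
            r = int(np.rint(row0 - t * np.sin(ang)))
            c = int(np.rint(col0 + t * np.cos(ang)))
            total += int(mask[r, c])
            t += 1
        sums.append(total)
    return np.array(sums, dtype=float)
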