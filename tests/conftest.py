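import math

import numpy as np
import pytest

from vesseltort import synthetic_data as sd


@pytest.fixture(scope="session")
def semicircle_arc():
    """Analytic semicircle R=80 placed inside a 400x500 image."""
    return sd.gen_analytic_curve(
        "circular_arc", {"radius": 80, "angle": math.pi, "center": (150, 250), "phase": 0.3}
    )


@pytest.fixture(scope="session")
def semicircle_raster(semicircle_arc):
    """Width-7 rasterized tube of the semicircle with mild noise."""
    return sd.rasterize_vessel(
        semicircle_arc, width_px=7, image_shape=(400, 500), noise_sd=2.0, seed=1
    )


@pytest.fixture(scope="session")
def small_phantom():
    """A compact fundus phantom pair (fast to generate and search)."""
    return sd.gen_fundus_phantom_pair(seed=3, frame_shape=(384, 402), n_vessels=3)


def digital_arc(radius, angle, center=(200.0, 200.0), phase=0.0):
    """8-connected integer-pixel arc as (x, y) points, skeleton-style."""
    ac = sd.gen_analytic_curve(
        "circular_arc",
        {"radius": radius, "angle": angle, "center": center, "phase": phase},
    )
    rc = sd.pixelate_curve(ac.points)
    return np.column_stack([rc[:, 1], rc[:, 0]]).astype(float)
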