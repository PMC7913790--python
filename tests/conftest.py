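"""Shared fixtures: small phantoms and matched-discretization stacks."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from iffmap.synthetic import PhantomSpec, make_phantom, simulate_stack
from iffmap.types import RegionMask

# enhancement pattern with well-spread gradients (no coincident flat rings)
FOUR_BLOBS = [
    (26.0, 26.0, 4.0, 1.0),
    (38.0, 28.0, 5.0, 0.8),
    (28.0, 40.0, 3.5, 0.9),
    (40.0, 40.0, 4.5, 0.7),
]

TRUE_D = 0.2
TRUE_U = (0.4, -0.2)


@pytest.fixture(scope="session")
def uniform_field_and_initial():
    spec = PhantomSpec(
        grid_shape=(64, 64), kind="uniform", diffusion=TRUE_D, velocity=TRUE_U
    )
    return make_phantom(spec)


@pytest.fixture(scope="session")
def matched_stack(uniform_field_and_initial):
    """1 pre + 4 post frames generated by the same FTCS stencil the solver inverts."""
    field, initial = uniform_field_and_initial
    return simulate_stack(
        field,
        initial,
        [0.0, 1.0, 2.0, 3.0, 4.0],
        pre_contrast_count=1,
        scheme="gradient",
        dt_micro=1.0,
    )


@pytest.fixture(scope="session")
def blob_roi():
    yy, xx = np.mgrid[0:64, 0:64]
    return RegionMask(np.hypot(xx - 32, yy - 32) <= 16, label="roi")


def multi_blob_stack(n_post: int, noise_sigma_frac: float, seed: int, **phantom_kw):
    """Matched-discretization stack over the four-blob enhancement pattern."""
    spec = PhantomSpec(
        grid_shape=(64, 64),
        kind="uniform",
        diffusion=phantom_kw.pop("diffusion", TRUE_D),
        velocity=phantom_kw.pop("velocity", TRUE_U),
        blobs=FOUR_BLOBS,
        **phantom_kw,
    )
    field, initial = make_phantom(spec)
    times = [float(t) for t in range(n_post + 1)]
    return simulate_stack(
        field,
        initial,
        times,
        pre_contrast_count=1,
        scheme="gradient",
        dt_micro=1.0,
        noise_sigma=noise_sigma_frac * float(initial.max()),
        seed=seed,
    )
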