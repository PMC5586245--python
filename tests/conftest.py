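"""Shared fixtures: synthetic reference bodies with exact ground truth."""

import logging

import numpy as np
import pytest

from saskit import SyntheticSpec, generate

# the transform warns loudly on deliberately-too-small dmax scans
logging.getLogger("saskit.prtransform").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def sphere_clean():
    """Noise-free uniform sphere, R = 30 A, default grid."""
    return generate(SyntheticSpec(shape="sphere", geometry={"radius": 30.0}))


@pytest.fixture(scope="session")
def sphere_noisy():
    """Sphere with counting noise (1e5 counts at q_min), fixed seed."""
    return generate(SyntheticSpec(shape="sphere", geometry={"radius": 30.0},
                                  counts_at_qmin=1e5, seed=11))


def sphere_intensity_oracle(q, radius):
    """Independent closed-form sphere intensity for oracle comparisons
    (deliberately re-derived here, not imported from the package)."""
    x = np.asarray(q, dtype=float) * radius
    out = np.ones_like(x)
    nz = np.abs(x) > 1e-9
    out[nz] = (3.0 * (np.sin(x[nz]) - x[nz] * np.cos(x[nz])) / x[nz] ** 3) ** 2
    return out
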