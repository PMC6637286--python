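import logging

import numpy as np
import pytest

from bpdph.microct import Volume3D
from bpdph.phantoms import ConditionProfile, generate_vascular_volume

logging.getLogger("bpdph").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def single_tube():
    """One 11 um tube in a 64^3 volume, with its ground truth."""
    profile = ConditionProfile("one_bin", [10.0, 12.0], [1])
    vol, gt = generate_vascular_volume(
        profile, shape=(64, 64, 64), seed=7, poisson_counts=False, noise_sd=0.0
    )
    return vol, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_tube_volume(radius_vox, shape=(48, 48, 48), axis_margin=6, amplitude=200.0, background=20.0):
    """Straight axis-aligned tube rendered with partial volume."""
    from bpdph._geom import render_capsule

    canvas = np.zeros(shape, float)
    c = shape[1] / 2 - 0.5
    p0 = np.array([c, c, float(axis_margin)])
    p1 = np.array([c, c, float(shape[2] - axis_margin)])
    render_capsule(canvas, p0, p1, radius_vox, amplitude=amplitude, supersample=4)
    return Volume3D(background + canvas, voxel_size=6.0), (p0, p1)
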