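"""Shared fixtures: desk-scale phantom cohorts generated at test time."""

import numpy as np
import pytest

from contourqa.phantom import PhantomConfig, generate_case, generate_cohort


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale phantom configuration (48×48×12 voxels)."""
    return PhantomConfig.for_shape((48, 48, 12), seed=5)


@pytest.fixture(scope="session")
def small_case(small_cfg):
    return generate_case(small_cfg, rng_seed=3)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    """8 cases, half with two auto contours (12 contours total)."""
    return generate_cohort(8, 0.5, small_cfg)


@pytest.fixture(scope="session")
def paper_shaped_cohort():
    """60 cases, 1/3 dual-contour → 80 contours, at desk-scale resolution."""
    cfg = PhantomConfig.for_shape((48, 48, 12), seed=7)
    return generate_cohort(60, 1.0 / 3.0, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_mask(rng, shape, p=0.3):
    return rng.random(shape) < p
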