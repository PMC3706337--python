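import logging

import numpy as np
import pytest

from rpl.fixtures import FixtureSpec, generate_suite
from rpl.pipeline import PipelineConfig, fit_models

logging.getLogger("rpl").setLevel(logging.WARNING)

# Standard suite parameters: moderate contrast, touching nuclei, bright
# distractor blobs.  Training and evaluation seeds are disjoint.
STD_SPEC = FixtureSpec(
    image_size=(360, 360),
    n_nuclei=20,
    touching_fraction=0.2,
    n_bright_blobs=3,
    speckle=0.14,
    seed=0,
)
TRAIN_SEED = 1234


@pytest.fixture(scope="session")
def std_spec() -> FixtureSpec:
    return STD_SPEC


@pytest.fixture(scope="session")
def pipeline_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def train_fixtures():
    return generate_suite(4, STD_SPEC, seed=TRAIN_SEED)


@pytest.fixture(scope="session")
def trained_models(train_fixtures, pipeline_config):
    return fit_models(
        [f.image for f in train_fixtures],
        [f.truth for f in train_fixtures],
        pipeline_config,
        seed=0,
    )


@pytest.fixture(scope="session")
def test_fixture():
    """One held-out fixture."""
    return generate_suite(1, STD_SPEC, seed=777)[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def disk_image(shape=(64, 64), bg=20, fg=200, center=(32, 32), radius=12):
    im = np.full(shape, bg, np.uint8)
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    im[(rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2] = fg
    return im
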