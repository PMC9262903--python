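import numpy as np
import pytest

from flowgaze.cohort import CohortDesign, generate_cohort, load_presets


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def presets():
    return load_presets()


@pytest.fixture(scope="session")
def tiny_cohort(presets):
    """Two groups x three participants, with benchmark trials."""
    design = CohortDesign(age_groups=("1y", "adult"), n_per_group=3)
    return generate_cohort(design=design, presets=presets, rng=0)


@pytest.fixture(scope="session")
def full_cohort(presets):
    """The default 13 x 20 study design, seed 0."""
    return generate_cohort(presets=presets, rng=0)


@pytest.fixture(scope="session")
def full_scores(full_cohort):
    return full_cohort.score()
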