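import numpy as np
import pytest

from patchtest import PhantomConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small mixed-grade cohort without bleed, shared across read-only tests."""
    cfg = PhantomConfig(
        n_patients=10,
        chambers_per_area=4,
        image_size=96,
        chamber_size=28,
        grade_probabilities=(0.5, 0.2, 0.2, 0.1),
        bleed_probability=0.0,
        seed=123,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def separable_cohort():
    """High-separation cohort (none vs +++ only): easy for any classifier."""
    cfg = PhantomConfig(
        n_patients=14,
        chambers_per_area=4,
        image_size=96,
        chamber_size=28,
        grade_probabilities=(0.5, 0.0, 0.0, 0.5),
        bleed_probability=0.0,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
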