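import numpy as np
import pytest

from dyskest.features import featurize_dataset
from dyskest.io import assemble_dataset
from dyskest.synth import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_cfg():
    """A 4-subject, 3-round cohort with short trials for fast tests."""
    return CohortConfig(
        n_subjects=4,
        rounds_per_subject=3,
        short_round_subjects=0,
        activity_duration_s=(15.0, 20.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_cfg):
    return generate_cohort(tiny_cfg)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_cohort):
    recordings, annotations = tiny_cohort
    return assemble_dataset(recordings, annotations)


@pytest.fixture(scope="session")
def tiny_sequences(tiny_dataset):
    return featurize_dataset(tiny_dataset)


@pytest.fixture(scope="session")
def default_cohort():
    """The study-structure cohort: 15 subjects, 2 of them with 3 rounds."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(123)
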