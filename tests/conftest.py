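import numpy as np
import pytest

from cineseg.cine_io import split_by_patient
from cineseg.synthetic_cine import generate_cohort
from cineseg.trainer import cohort_from_manifest


@pytest.fixture(scope="session")
def small_cohort():
    """A 10-patient phantom cohort with splits, shared across tests."""
    clips, manifest = generate_cohort(10, seed=42)
    manifest = split_by_patient(manifest, (0.6, 0.2, 0.2), seed=42)
    return cohort_from_manifest(clips, manifest), clips, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
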