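import numpy as np
import pandas as pd
import pytest

from psmavol import (
    CohortSimSpec,
    LesionSpec,
    OrganMaskSet,
    PetVolume,
    default_body_phantom,
    generate_phantom,
    simulate_cohort,
)


@pytest.fixture
def clean_phantom():
    """Noise-free, blur-free torso phantom with three uniform lesions."""
    return generate_phantom(default_body_phantom(seed=7))


@pytest.fixture
def km_fixture():
    """Hand-workable two-group survival fixture.

    Group A: events at 2 and 4, censored at 6 -> product-limit median 4.
    Group B: events at 10, 12, 14 -> median 12.
    """
    return pd.DataFrame(
        {
            "os_months": [2.0, 4.0, 6.0, 10.0, 12.0, 14.0],
            "event": [True, True, False, True, True, True],
            "group": [False, False, False, True, True, True],
        }
    )


@pytest.fixture
def null_cohort():
    """Cohort where survival is independent of every covariate."""
    return simulate_cohort(
        CohortSimSpec(
            n_patients=60, beta_log_tv=0.0, beta_response=0.0,
            beta_low_expression=0.0, frac_low_expression=0.0, seed=11,
        )
    )


def uniform_volume(value=1.0, shape=(10, 10, 10), spacing=(2.0, 2.0, 2.0)):
    return PetVolume(np.full(shape, float(value)), spacing)


def liver_only_masks(volume, liver_value):
    """Whole-grid liver mask set with the PET forced to liver_value inside."""
    labels = np.ones(volume.values.shape, dtype=int)
    return OrganMaskSet(labels, {"liver": 1})
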