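import numpy as np
import pandas as pd
import pytest

from pdsocial.lexicon import load_dictionary
from pdsocial.synth import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def dictionary():
    return load_dictionary()


@pytest.fixture(scope="session")
def small_config():
    """A small but fully featured cohort: duplicates, memories, mojibake."""
    return SynthConfig(
        n_pd=4,
        n_et=1,
        n_ap=1,
        n_cg=2,
        posts_per_participant=(150.0, 60.0),
        rate_pre={"PD": 0.05, "ET": 0.01, "AP": 0.09, "CG": 0.02},
        rate_post={"PD": 0.12, "ET": 0.01, "AP": 0.05, "CG": 0.02},
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture()
def toy_participants():
    return pd.DataFrame(
        {
            "id": ["a", "b", "c"],
            "group": ["PD", "PD", "CG"],
            "gender": ["F", "M", "F"],
            "age_at_interview": [70.0, 65.0, 60.0],
            "interview_date": ["2024-06-15"] * 3,
            "diagnosis_date": ["2020-01-01", "2018-06-01", ""],
        }
    )


def rng(seed=0):
    return np.random.default_rng(seed)
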