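import logging

import numpy as np
import pytest

from mosaicmap import GeneratorConfig, MosaicNormativeScorer, generate_study

# keep expected-degenerate warnings (small cohorts) out of test output
logging.getLogger("mosaicmap").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_config():
    """A fast, fully in-range study: dense normative coverage, tiny matrices."""
    return GeneratorConfig(
        n_normative=240,
        n_patients=30,
        n_patches=120,
        age_range=(55.0, 70.0),
        patient_age_mean=62.0,
        patient_age_sd=2.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)


@pytest.fixture(scope="session")
def fitted_scorer(small_study):
    return MosaicNormativeScorer().fit(
        small_study.normative.thickness, small_study.normative.demographics
    )


@pytest.fixture(scope="session")
def patient_stats(fitted_scorer, small_study):
    return fitted_scorer.score_patients(
        small_study.patient_thickness, small_study.patient_demographics
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
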