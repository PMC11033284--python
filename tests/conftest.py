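import dataclasses

import numpy as np
import pytest

from ricestore.synthetic import (DEFAULT_PROFILES, PesticideProfile,
                                 StorageCondition, StudyDesign,
                                 generate_study_dataset)


@pytest.fixture(scope="session")
def noiseless_design() -> StudyDesign:
    base = StudyDesign()
    return dataclasses.replace(base, pesticides=tuple(
        dataclasses.replace(p, noise_sd=0.0) for p in base.pesticides))


@pytest.fixture(scope="session")
def noiseless_dataset(noiseless_design):
    return generate_study_dataset(noiseless_design, seed=1)


@pytest.fixture()
def simple_profile() -> PesticideProfile:
    return PesticideProfile("test", C0=5.0, fast_fraction=0.8, k_base=0.4,
                            k_slow=0.01, T_opt=38.0, sigma_T=8.0,
                            H_opt=78.0, sigma_H=14.0, noise_sd=0.0)


@pytest.fixture()
def ref_condition() -> StorageCondition:
    return StorageCondition(38.0, 78.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
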