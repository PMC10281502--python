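import numpy as np
import pytest

import bearcomp as bc


@pytest.fixture(scope="session")
def truth():
    return bc.default_truth()


@pytest.fixture(scope="session")
def identity_structural():
    """Unit-coefficient allometries: K_U = K_nU = L**3."""
    return bc.StructuralParams(alpha_lU0=0.0, beta_lU1=3.0, beta_lU2=0.0,
                               sd_lU=0.1, alpha_lKnU0=0.0, beta_lKnU1=3.0,
                               sd_lKnU=0.1)


@pytest.fixture(scope="session")
def dissection_df(truth):
    cfg = bc.GeneratorConfig(seed=7, n_dissection=60)
    return bc.gen_dissection(cfg)


@pytest.fixture(scope="session")
def fast_sampler():
    """Small but adequate MCMC settings for unit tests."""
    return bc.SamplerConfig(chains=2, warmup_iterations=800,
                            sampling_iterations=1500, seed=0)


@pytest.fixture(scope="session")
def single_params():
    return bc.SingleStorageParams(structural_coefficient=20.0,
                                  storage_lipid_fraction=0.55,
                                  storage_protein_fraction=0.10)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
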