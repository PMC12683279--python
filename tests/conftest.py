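import numpy as np
import pandas as pd
import pytest

import viromarker as vm


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_table():
    return vm.AbundanceTable(
        pd.DataFrame([[3, 0], [1, 5]], index=["tA", "tB"], columns=["s1", "s2"])
    )


def noiseless_config(seed=1, **overrides):
    kwargs = dict(
        seed=seed,
        detection_prob=1.0,
        transfer_prob=1.0,
        transient_rate=0.0,
        shared_prevalence=0.0,
        n_shared_species=0,
        n_shared_families=0,
        contamination_rate=0.0,
    )
    kwargs.update(overrides)
    return vm.StudyConfig(**kwargs)


@pytest.fixture(scope="session")
def noiseless_study():
    return vm.generate_study(noiseless_config())


@pytest.fixture(scope="session")
def default_study():
    return vm.generate_study(vm.StudyConfig(seed=7))


def random_presence(rng, n_taxa, n_samples, p=0.4):
    data = (rng.random((n_taxa, n_samples)) < p).astype(int)
    return vm.PresenceMatrix(
        pd.DataFrame(
            data,
            index=[f"t{i}" for i in range(n_taxa)],
            columns=[f"s{j}" for j in range(n_samples)],
        )
    )
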