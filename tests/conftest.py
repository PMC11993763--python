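import numpy as np
import pandas as pd
import pytest

from lineagescape import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study: 12 demes, 2 lineages, 2000 neutral +
    20 adaptive SNPs, 20 individuals per deme."""
    return generate_dataset(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def deme_of_sample(default_dataset):
    return default_dataset.sample_table.set_index("sample")["deme"]


@pytest.fixture(scope="session")
def deme_frequencies(default_dataset, deme_of_sample):
    from lineagescape import allele_frequencies
    freq = allele_frequencies(default_dataset.genotypes, deme_of_sample)
    return freq.reindex(default_dataset.localities["deme"])


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
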