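import numpy as np
import pytest

from chroma3d import contacts as con
from chroma3d import synthetic_data as syn


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic dataset at the default study conditions."""
    return syn.generate(syn.SyntheticConfig(rng_seed=1))


@pytest.fixture(scope="session")
def balanced_matrices(default_dataset):
    return {c: con.ice_balance(m)
            for c, m in default_dataset.contacts.items()}


@pytest.fixture(scope="session")
def dataset_dir(default_dataset, tmp_path_factory):
    out = tmp_path_factory.mktemp("synds")
    syn.write_dataset(default_dataset, out)
    return out


def make_balanced(counts, chrom="chr", bin_size=1):
    """Wrap a dense symmetric array as an already-balanced ContactMatrix
    with unit weights (NaN rows allowed via the mask)."""
    counts = np.asarray(counts, dtype=float)
    mask = ~np.all(np.isnan(counts) | (counts == 0), axis=0)
    m = con.ContactMatrix(chrom, bin_size, np.nan_to_num(counts),
                          valid_mask=mask, weights=np.ones(counts.shape[0]))
    return m
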