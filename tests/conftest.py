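import numpy as np
import pandas as pd
import pytest

from appm.synthetic import SyntheticAlleleSpec, generate_dataset, generate_proteome


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210525)


@pytest.fixture(scope="session")
def small_labeled_table():
    """400 positives / 2,000 negatives from a strongly anchored 9-mer motif."""
    spec = SyntheticAlleleSpec(
        name="A*02:01",
        n_positives=400,
        imbalance_ratio=5,
        length_weights={9: 1.0},
        anchor_rules={2: ("L", 1.0), -1: ("V", 1.0)},
        seed=11,
    )
    table, pfms = generate_dataset(spec)
    return table, pfms


@pytest.fixture(scope="session")
def toy_proteome():
    proteome, hits = generate_proteome(
        n_proteins=8, length_range=(200, 400), seed=5, hits_per_protein=2
    )
    return proteome, hits


def random_peptide(rng, length=None):
    from appm.codec import ALPHABET

    if length is None:
        length = int(rng.integers(8, 12))
    return "".join(rng.choice(list(ALPHABET), size=length))
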