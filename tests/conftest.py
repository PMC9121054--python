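import numpy as np
import pytest

from gradientpop.datatypes import SequenceRecord, SpeciesDataset


def make_dataset(seqs, labels, species="test"):
    recs = [
        SequenceRecord(f"s{i:03d}", s, l)
        for i, (s, l) in enumerate(zip(seqs, labels))
    ]
    return SpeciesDataset(species, recs)


def random_sequences(rng, n, L, n_variable=None, alphabet="ACGT"):
    """Random alignment: shared backbone with variable columns, so
    datasets have realistic shared/segregating structure."""
    backbone = rng.choice(list(alphabet), size=L)
    n_variable = L // 3 if n_variable is None else n_variable
    var_cols = rng.choice(L, size=min(n_variable, L), replace=False)
    seqs = []
    for _ in range(n):
        row = backbone.copy()
        for c in var_cols:
            row[c] = rng.choice(list(alphabet))
        seqs.append("".join(row))
    return seqs


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def toy_two_pop():
    """Small two-population dataset with clear structure."""
    seqs = ["ACGTACGTAC", "ACGTACGTAC", "ACGTACGTAT",
            "TGCATGCATG", "TGCATGCATG", "TGCATGCATA"]
    labels = ["north"] * 3 + ["baltic"] * 3
    return make_dataset(seqs, labels)
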