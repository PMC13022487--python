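import numpy as np
import pytest

from protoseg import PhenotypeTable, ProteinMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, mask=None, prefix_p="S", prefix_q="P"):
    """ProteinMatrix from a 2-D array; mask defaults to all-observed."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if mask is None:
        mask = np.ones((n, p), dtype=bool)
    return ProteinMatrix(
        [f"{prefix_p}{i}" for i in range(n)],
        [f"{prefix_q}{j}" for j in range(p)],
        values,
        np.asarray(mask, dtype=bool),
    )


def make_phenotypes(participant_ids, sick_of=None, age=None, sex=None):
    """PhenotypeTable with one disease code 'D50' for the given sick set."""
    n = len(participant_ids)
    sick_of = sick_of or set()
    codes = {
        p: frozenset({"D50"}) if p in sick_of else frozenset()
        for p in participant_ids
    }
    return PhenotypeTable(
        list(participant_ids),
        np.full(n, 55.0) if age is None else age,
        np.asarray(["F" if i % 2 else "M" for i in range(n)], dtype=object)
        if sex is None
        else sex,
        codes,
    )


@pytest.fixture
def random_masked_matrix(rng):
    values = rng.normal(size=(20, 10))
    mask = rng.random((20, 10)) > 0.1
    return make_matrix(values, mask)
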