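import random

import pytest

from emmernet.io import SeqAlignment, TaxonSet


@pytest.fixture
def rng():
    return random.Random(20260925)


def make_alignment(rng: random.Random, n_taxa: int, n_cols: int,
                   alphabet: str = "ACGT", labels=None) -> SeqAlignment:
    labels = labels or [f"t{i}" for i in range(n_taxa)]
    rows = ["".join(rng.choice(alphabet) for _ in range(n_cols))
            for _ in labels]
    return SeqAlignment(TaxonSet(labels), rows)
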