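from __future__ import annotations

import numpy as np
import pytest

from keystrings.cv import cv_matrix
from keystrings.model import AMINO_ACIDS, Proteome, ProteinRecord
from keystrings.simulate import fixture


def make_random_proteome(
    rng: np.random.Generator,
    species_id: str = "sp",
    n_proteins: int | None = None,
    max_len: int = 50,
    alphabet: str = AMINO_ACIDS,
) -> Proteome:
    n = n_proteins or int(rng.integers(1, 6))
    proteins = []
    for i in range(n):
        L = int(rng.integers(8, max_len + 1))
        seq = "".join(rng.choice(list(alphabet), size=L))
        proteins.append(ProteinRecord(f"g{i}", seq))
    return Proteome(species_id=species_id, proteins=proteins)


@pytest.fixture(scope="session")
def twoclade():
    proteomes, truth = fixture("twoclade-minimal")
    return proteomes, truth


@pytest.fixture(scope="session")
def twoclade_rows(twoclade):
    proteomes, _ = twoclade
    return cv_matrix(proteomes, 5)


@pytest.fixture(scope="session")
def small4x5():
    proteomes, truth = fixture("small4x5")
    return proteomes, truth


@pytest.fixture(scope="session")
def small4x5_rows(small4x5):
    proteomes, _ = small4x5
    return cv_matrix(proteomes, 5)
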