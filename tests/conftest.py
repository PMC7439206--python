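import numpy as np
import pytest

from dewalk import AssociationData, SymptomData, generate_dataset


@pytest.fixture
def toy_assoc() -> AssociationData:
    """4 diseases x 5 microbes, hand-picked so every disease has >=1 partner."""
    A = np.array(
        [
            [1, 1, 0, 0, 0],
            [1, 0, 1, 0, 0],
            [0, 0, 0, 1, 1],
            [0, 0, 0, 1, 0],
        ],
        dtype=float,
    )
    return AssociationData(
        [f"d{i}" for i in range(4)], [f"m{j}" for j in range(5)], A
    )


@pytest.fixture
def toy_symptoms(toy_assoc) -> SymptomData:
    """Symptom counts roughly mirroring the two disease groups of toy_assoc."""
    C = np.array(
        [
            [4, 3, 0, 0],
            [2, 2, 1, 0],
            [0, 0, 5, 4],
            [0, 1, 2, 3],
        ],
        dtype=float,
    )
    return SymptomData(list(toy_assoc.disease_labels), [f"s{k}" for k in range(4)], C)


@pytest.fixture(scope="session")
def synth_dataset():
    """Default planted-cluster dataset shared across tests (read-only)."""
    return generate_dataset()
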