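import numpy as np
import pytest

from lpggnet.montage import (Montage, builtin_montage_22,
                             builtin_scheme_dataset_a)


@pytest.fixture(scope="session")
def montage22():
    return builtin_montage_22()


@pytest.fixture(scope="session")
def scheme_a():
    return builtin_scheme_dataset_a()


@pytest.fixture(scope="session")
def small_montage(montage22):
    """Five central channels, enough for coupling experiments."""
    names = ("C3", "C1", "Cz", "C2", "C4")
    idx = montage22.index_of(names)
    return Montage(names, montage22.coords[idx])


def tiny_montage4():
    """Four-channel montage for miniature model tests."""
    return Montage(("C3", "Cz", "C4", "Pz"),
                   np.array([[-0.6, 0.0, 0.8], [0.0, 0.0, 1.0],
                             [0.6, 0.0, 0.8], [0.0, -0.6, 0.8]]))
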