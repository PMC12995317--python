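import numpy as np
import pytest

import blockspin as bs


@pytest.fixture(scope="session")
def three_party_small():
    """Worked three-party example with the smallest legal sizes."""
    return bs.fixtures.three_party_model((2, 2, 2))


@pytest.fixture(scope="session")
def curie_weiss_pair():
    """M=1, N=2, J=[[1]]: every quantity is computable by hand."""
    return bs.build_model((2,), [[1.0]])


@pytest.fixture(scope="session")
def polarised_low():
    """Identifiable low-temperature two-group model (antagonistic coupling)."""
    return bs.fixtures.polarised_pair_model()


@pytest.fixture(scope="session")
def separated_high():
    """High-temperature M=3 model far from criticality, used for recovery tests.

    Its exact correlations satisfy the window certification
    |E - level/N| <= delta/(8N) at N = 330 (verified by the oracle in the
    tests that use it).
    """

    def make(N: int) -> bs.BlockSpinModel:
        J = np.array([[0.5, 0.1, -0.1], [0.1, 0.3, 0.05], [-0.1, 0.05, 0.15]])
        assert N % 3 == 0
        return bs.build_model((N // 3,) * 3, J)

    return make


def planted_partition(model: bs.BlockSpinModel) -> frozenset:
    return frozenset(
        frozenset(int(i) for i in np.flatnonzero(model.labels == l))
        for l in range(model.M)
    )
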