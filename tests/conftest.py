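import numpy as np
import pytest

from escreg import io, simulate


@pytest.fixture(scope="session")
def default_sim():
    """Default simulated dataset (counts, truth, labels) at seed 1."""
    return simulate.simulate_cells(simulate.SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_lognorm(default_sim):
    counts, truth, labels = default_sim
    return io.log_normalize(counts), truth, labels


@pytest.fixture()
def toy_counts():
    """Small 4-gene x 5-cell counts matrix with a mito gene."""
    values = np.array(
        [
            [5, 0, 2, 1, 3],
            [0, 1, 0, 4, 2],
            [3, 3, 3, 0, 1],
            [1, 0, 9, 2, 0],
        ]
    )
    return io.ExpressionMatrix(
        values, ["GA", "GB", "GC", "MT-1"], [f"C{i}" for i in range(1, 6)], "counts"
    )
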