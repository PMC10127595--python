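import numpy as np
import pytest

import prophagemap as pm


@pytest.fixture(scope="session")
def small_genome():
    """20-kb repeat-free replicon, no planted features."""
    return pm.simulate_genome(20_000, seed=42)


@pytest.fixture(scope="session")
def prophage_genome():
    """200-kb replicon with one planted 44,597-bp prophage."""
    return pm.simulate_genome(
        200_000,
        prophage_specs=[pm.PlantedProphage(100_000, 144_597, core_rate=70_000.0)],
        seed=7,
    )


def coverage_from_truth(genome, readset):
    """Independent per-position coverage recount from read truth coordinates."""
    n = len(genome.replicons[0])
    L = readset.read_length
    starts = np.array(
        [t.start for t in readset.truth if t.replicon_id is not None], dtype=int
    )
    diff = np.zeros(n + 1)
    ends = starts + L
    np.add.at(diff, starts, 1)
    np.add.at(diff, np.minimum(ends, n), -1)
    for e in ends[ends > n]:  # circular wrap
        diff[0] += 1
        diff[e - n] -= 1
    return np.cumsum(diff[:-1])
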