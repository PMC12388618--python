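import numpy as np
import pytest

from amf_assembly.data_io import CommunityTable, PhylogeneticDistances


def make_table(counts, sample_ids=None, otu_ids=None, is_relative=False) -> CommunityTable:
    counts = np.asarray(counts, dtype=float)
    n, m = counts.shape
    return CommunityTable(
        tuple(sample_ids or [f"S{i + 1}" for i in range(n)]),
        tuple(otu_ids or [f"O{j + 1}" for j in range(m)]),
        counts,
        is_relative,
    )


def star_distances(otu_ids, tip_distance=1.0) -> PhylogeneticDistances:
    """All distinct tips at the same pairwise distance (star phylogeny)."""
    n = len(otu_ids)
    m = np.full((n, n), 2 * tip_distance)
    np.fill_diagonal(m, 0.0)
    return PhylogeneticDistances(otu_ids, m)


@pytest.fixture
def balanced_4otu():
    """Tree ((A:1,B:1):1,(C:1,D:1):1); with its hand-derived distances."""
    ids = ("A", "B", "C", "D")
    m = np.array(
        [
            [0, 2, 4, 4],
            [2, 0, 4, 4],
            [4, 4, 0, 2],
            [4, 4, 2, 0],
        ],
        dtype=float,
    )
    return PhylogeneticDistances(ids, m)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
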