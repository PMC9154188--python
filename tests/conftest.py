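import itertools

import numpy as np
import pytest

from netbackbone import BipartiteGraph, WeightedGraph, synth


@pytest.fixture(scope="session")
def toy():
    """The fixed 10-node multi-scale weighted network."""
    return synth.toy_weighted()


@pytest.fixture(scope="session")
def block_bipartite():
    """Planted 3-group bipartite network, 30 agents x 75 artifacts."""
    return synth.bipartite_blocks(seed=11)


def sym_graph(upper: np.ndarray, labels=None) -> WeightedGraph:
    """Build an undirected WeightedGraph from an upper-triangular array."""
    m = np.triu(np.asarray(upper, dtype=float), 1)
    m = m + m.T
    labels = labels or [str(i + 1) for i in range(m.shape[0])]
    return WeightedGraph(labels, m)


def bip(incidence) -> BipartiteGraph:
    inc = np.asarray(incidence, dtype=int)
    r, c = inc.shape
    return BipartiteGraph(
        [f"a{i + 1}" for i in range(r)], [f"p{k + 1}" for k in range(c)], inc
    )


def enumerate_margin_class(d, f):
    """All binary matrices with row sums d and column sums f, by brute
    force over row patterns; oracle for the fixed degree sequence null."""
    d = list(d)
    f = np.asarray(f)
    c = f.size
    row_choices = [
        [np.array([1 if k in cols else 0 for k in range(c)]) for cols in itertools.combinations(range(c), di)]
        for di in d
    ]
    out = []
    for rows in itertools.product(*row_choices):
        m = np.vstack(rows)
        if np.array_equal(m.sum(axis=0), f):
            out.append(m)
    return out
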