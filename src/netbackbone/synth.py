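"""Synthetic networks for demonstrations and tests.

Four generators cover the study conditions used throughout the
package: a fixed 10-node multi-scale weighted toy network, a
block-structured random bipartite network (30 agents, 75 artifacts, 3
groups), a three-community stochastic block model, and a
preferential-attachment graph with hubs.  All are pure functions of
their parameters and seed.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .graph_core import BipartiteGraph, GraphValidationError, WeightedGraph

# Two star clusters joined by one strong bridge: node 1's cluster has
# weak spokes (weight 10) over a weak clique (weight 1); node 6's
# cluster has strong spokes (100) over moderate clique edges (10); the
# 1-6 bridge has weight 75.  Edge weights span two scales, which defeats
# any single global threshold.
_TOY_ROWS = [
    [0, 10, 10, 10, 10, 75, 0, 0, 0, 0],
    [10, 0, 1, 1, 1, 0, 0, 0, 0, 0],
    [10, 1, 0, 1, 1, 0, 0, 0, 0, 0],
    [10, 1, 1, 0, 1, 0, 0, 0, 0, 0],
    [10, 1, 1, 1, 0, 0, 0, 0, 0, 0],
    [75, 0, 0, 0, 0, 0, 100, 100, 100, 100],
    [0, 0, 0, 0, 0, 100, 0, 10, 10, 10],
    [0, 0, 0, 0, 0, 100, 10, 0, 10, 10],
    [0, 0, 0, 0, 0, 100, 10, 10, 0, 10],
    [0, 0, 0, 0, 0, 100, 10, 10, 10, 0],
]


def toy_weighted() -> WeightedGraph:
    """The fixed 10x10 multi-scale weighted toy network (21 edges)."""
    return WeightedGraph([str(i) for i in range(1, 11)], np.array(_TOY_ROWS, dtype=float))


def bipartite_blocks(
    groups: int = 3,
    agents_per: int = 10,
    artifacts_per: int = 25,
    p_in: float = 0.8,
    p_out: float = 0.2,
    seed: int = 0,
) -> BipartiteGraph:
    """Random bipartite network with planted group structure.

    Agents and artifacts are split into ``groups`` aligned groups; a
    cell is 1 with probability ``p_in`` when agent and artifact belong
    to the same group (people mostly attend their own group's events)
    and ``p_out`` otherwise.
    """
    for p in (p_in, p_out):
        if not 0.0 <= p <= 1.0:
            raise GraphValidationError("probabilities must lie in [0, 1]")
    if min(groups, agents_per, artifacts_per) < 1:
        raise GraphValidationError("sizes must be >= 1")
    rng = np.random.default_rng(seed)
    r, c = groups * agents_per, groups * artifacts_per
    probs = np.full((r, c), p_out)
    for g in range(groups):
        probs[
            g * agents_per : (g + 1) * agents_per,
            g * artifacts_per : (g + 1) * artifacts_per,
        ] = p_in
    inc = (rng.random((r, c)) < probs).astype(np.int8)
    agents = [f"a{i + 1}" for i in range(r)]
    artifacts = [f"p{k + 1}" for k in range(c)]
    return BipartiteGraph(agents, artifacts, inc)


def sbm(
    n: int = 60,
    blocks: int = 3,
    p_in: float = 0.75,
    p_out: float = 0.25,
    seed: int = 0,
) -> WeightedGraph:
    """Unweighted stochastic block model: ``blocks`` equal communities
    with within-community edge probability ``p_in`` and
    between-community probability ``p_out``."""
    if n % blocks:
        raise GraphValidationError("n must be divisible by blocks")
    size = n // blocks
    pref = np.full((blocks, blocks), p_out)
    np.fill_diagonal(pref, p_in)
    g = nx.stochastic_block_model(
        [size] * blocks, pref.tolist(), seed=np.random.default_rng(seed)
    )
    wg = WeightedGraph.from_networkx(nx.relabel_nodes(g, {v: str(v + 1) for v in g.nodes()}))
    return wg


def sbm_block_of(node_index: int, n: int = 60, blocks: int = 3) -> int:
    """Community membership of a node index under :func:`sbm` labelling."""
    return node_index // (n // blocks)


def preferential_attachment(n: int = 60, m: int = 3, seed: int = 0) -> WeightedGraph:
    """Unweighted Barabási–Albert graph: each new node attaches to
    ``m`` existing nodes preferentially by degree, producing hubs.

    Growth starts from a connected (m+1)-clique seed, so the graph is
    connected and has n*m - m(m+1)/2 edges.
    """
    g = nx.barabasi_albert_graph(
        n, m, seed=np.random.default_rng(seed), initial_graph=nx.complete_graph(m + 1)
    )
    return WeightedGraph.from_networkx(
        nx.relabel_nodes(g, {v: str(v + 1) for v in g.nodes()})
    )
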