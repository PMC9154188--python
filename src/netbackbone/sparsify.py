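"""Score / normalize / filter / connect sparsification of unweighted
networks.

Unweighted networks carry no edge weights, so each edge is first given
a topological *score* (Jaccard neighborhood overlap, neighbor degree,
triangle count, or a random score), optionally *normalized* by ranking
it among each endpoint's incident edges, then *filtered* by a per-node
budget, a threshold, or a global proportion, and optionally
*connected* by adding the union of maximum-score spanning trees.

Two named presets: L-Spar (Jaccard + rank + degree filter), which
preserves community structure, and Local Degree (neighbor degree +
rank + degree filter), which preserves hubs and hierarchy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .graph_core import GraphValidationError, WeightedGraph
from .inference import Backbone, _reduction_stats

_ESCORES = ("jaccard", "degree", "triangles", "random")
_NORMALIZE = ("none", "rank")
_FILTERS = ("degree", "threshold", "proportion")


@dataclass
class SparsifyPlan:
    """Declarative four-step sparsification recipe.

    filter:
        "degree"      — node of degree d keeps its ceil(d^s) best edges
                        (s in [0, 1]); an edge survives if either
                        endpoint keeps it.
        "threshold"   — keep edges scoring >= t (raw scores) or ranked
                        <= t (rank-normalized).
        "proportion"  — keep the best-scoring fraction p of edges.
    """

    escore: str = "jaccard"
    normalize: str = "rank"
    filter: str = "degree"
    s: float = 0.5
    t: float | None = None
    p: float | None = None
    umst: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.escore not in _ESCORES:
            raise GraphValidationError(f"unknown escore {self.escore!r}; expected {_ESCORES}")
        if self.normalize not in _NORMALIZE:
            raise GraphValidationError(f"unknown normalize {self.normalize!r}; expected {_NORMALIZE}")
        if self.filter not in _FILTERS:
            raise GraphValidationError(f"unknown filter {self.filter!r}; expected {_FILTERS}")
        if self.filter == "degree" and not 0.0 <= self.s <= 1.0:
            raise GraphValidationError("sparsification exponent s must lie in [0, 1]")
        if self.filter == "threshold" and self.t is None:
            raise GraphValidationError("threshold filter requires t")
        if self.filter == "proportion":
            if self.p is None or not 0.0 < self.p <= 1.0:
                raise GraphValidationError("proportion filter requires p in (0, 1]")


def lspar(s: float = 0.5, umst: bool = False) -> SparsifyPlan:
    """L-Spar preset: Jaccard score, rank normalization, degree filter."""
    return SparsifyPlan(escore="jaccard", normalize="rank", filter="degree", s=s, umst=umst)


def localdegree(s: float = 0.5, umst: bool = False) -> SparsifyPlan:
    """Local Degree preset: neighbor-degree score, rank, degree filter."""
    return SparsifyPlan(escore="degree", normalize="rank", filter="degree", s=s, umst=umst)


def _neighbor_sets(G: WeightedGraph) -> list[set]:
    adj = G.matrix > 0
    return [set(np.nonzero(adj[i])[0].tolist()) for i in range(G.n_nodes)]


def score_edges(G: WeightedGraph, escore: str, seed: int = 0) -> dict[tuple[int, int], tuple[float, float]]:
    """Score every edge of an unweighted graph.

    Returns ``{(i, j): (score_from_i, score_from_j)}`` over index pairs
    i < j.  Jaccard, triangle, and random scores are symmetric; the
    degree score is directional — the value from i's perspective is the
    degree of j (edges to hubs score high).  Neighborhoods are open:
    the endpoints themselves are excluded.
    """
    if escore not in _ESCORES:
        raise GraphValidationError(f"unknown escore {escore!r}")
    nbrs = _neighbor_sets(G)
    deg = G.degrees()
    rng = np.random.default_rng(seed)
    scores: dict[tuple[int, int], tuple[float, float]] = {}
    iu, ju = np.nonzero(np.triu(G.matrix, 1))
    for i, j in zip(iu.tolist(), ju.tolist()):
        if escore == "jaccard":
            # open neighborhoods: N(i) excludes i itself but keeps j
            inter = len(nbrs[i] & nbrs[j])
            union = len(nbrs[i] | nbrs[j])
            v = inter / union if union > 0 else 0.0
            scores[(i, j)] = (v, v)
        elif escore == "triangles":
            v = float(len(nbrs[i] & nbrs[j]))
            scores[(i, j)] = (v, v)
        elif escore == "degree":
            scores[(i, j)] = (float(deg[j]), float(deg[i]))
        else:  # random
            v = float(rng.uniform())
            scores[(i, j)] = (v, v)
    return scores


def rank_normalize(
    scores: dict[tuple[int, int], tuple[float, float]], G: WeightedGraph
) -> dict[tuple[int, int], tuple[float, float]]:
    """Competition-rank each node's incident edges by descending score.

    A node's best edge gets rank 1; ties share the best (minimum) rank.
    The rank of edge (i, j) from i's perspective is generally different
    from the rank from j's perspective.
    """
    incident: dict[int, list[tuple[float, tuple[int, int]]]] = {}
    for (i, j), (si, sj) in scores.items():
        incident.setdefault(i, []).append((si, (i, j)))
        incident.setdefault(j, []).append((sj, (i, j)))
    half: dict[tuple[int, tuple[int, int]], float] = {}
    for node, items in incident.items():
        items.sort(key=lambda x: -x[0])
        rank = 0
        prev = None
        for pos, (sc, edge) in enumerate(items, start=1):
            if sc != prev:
                rank = pos
                prev = sc
            half[(node, edge)] = float(rank)
    return {
        (i, j): (half[(i, (i, j))], half[(j, (i, j))]) for (i, j) in scores
    }


def degree_filter(
    ranks: dict[tuple[int, int], tuple[float, float]], G: WeightedGraph, s: float
) -> set[tuple[int, int]]:
    """Per-node budget filter: a node of degree d keeps its edges of
    rank <= ceil(d^s); an edge survives if kept by either endpoint."""
    if not 0.0 <= s <= 1.0:
        raise GraphValidationError("sparsification exponent s must lie in [0, 1]")
    deg = G.degrees()
    budget = {i: math.ceil(deg[i] ** s) if deg[i] > 0 else 0 for i in range(G.n_nodes)}
    kept = set()
    for (i, j), (ri, rj) in ranks.items():
        if ri <= budget[i] or rj <= budget[j]:
            kept.add((i, j))
    return kept


def umst_edges(
    scores: dict[tuple[int, int], tuple[float, float]], G: WeightedGraph
) -> set[tuple[int, int]]:
    """Union of maximum-score spanning trees (one per component).

    An edge belongs to some maximum spanning tree iff, scanning score
    groups in descending order, it joins two distinct components of the
    forest built from all strictly higher-scoring edges (Kruskal with
    tie-group analysis).
    """
    import networkx as nx

    uf = nx.utils.UnionFind(range(G.n_nodes))
    sym = {e: max(v) for e, v in scores.items()}
    groups: dict[float, list[tuple[int, int]]] = {}
    for e, v in sym.items():
        groups.setdefault(v, []).append(e)
    kept = set()
    for v in sorted(groups, reverse=True):
        batch = groups[v]
        # membership test against the forest of strictly better edges
        for i, j in batch:
            if uf[i] != uf[j]:
                kept.add((i, j))
        for i, j in batch:
            uf.union(i, j)
    return kept


def sparsify(G: WeightedGraph, plan: SparsifyPlan) -> Backbone:
    """Run a sparsification plan and return the backbone.

    The node set is preserved; the backbone edge set is always a subset
    of the input's (plus nothing — the union-of-spanning-trees step
    also selects only existing edges).
    """
    scores = score_edges(G, plan.escore, seed=plan.seed)
    values = rank_normalize(scores, G) if plan.normalize == "rank" else scores
    ascending = plan.normalize == "rank"  # rank 1 is best; raw scores: larger is better

    if plan.filter == "degree":
        if plan.normalize != "rank":
            values = rank_normalize(scores, G)
        kept = degree_filter(values, G, plan.s)
    elif plan.filter == "threshold":
        if ascending:
            kept = {e for e, v in values.items() if min(v) <= plan.t}
        else:
            kept = {e for e, v in values.items() if max(v) >= plan.t}
    else:  # proportion
        key = (lambda e: min(values[e])) if ascending else (lambda e: -max(values[e]))
        ordered = sorted(values, key=key)
        n_keep = max(1, math.ceil(plan.p * len(ordered))) if ordered else 0
        kept = set(ordered[:n_keep])

    if plan.umst:
        kept |= umst_edges(scores, G)

    signs = np.zeros((G.n_nodes, G.n_nodes), dtype=np.int8)
    for i, j in kept:
        signs[i, j] = signs[j, i] = 1
    model = (
        "lspar" if (plan.escore, plan.normalize, plan.filter) == ("jaccard", "rank", "degree")
        else "localdegree" if (plan.escore, plan.normalize, plan.filter) == ("degree", "rank", "degree")
        else "sparsify"
    )
    provenance = {
        "model": model,
        "alpha": None,
        "mtc": "none",
        "signed": False,
        "escore": plan.escore,
        "normalize": plan.normalize,
        "filter": plan.filter,
        "umst": plan.umst,
        **({"s": plan.s} if plan.filter == "degree" else {}),
        **({"t": plan.t} if plan.filter == "threshold" else {}),
        **({"p": plan.p} if plan.filter == "proportion" else {}),
        **_reduction_stats(G, signs),
    }
    return Backbone(list(G.nodes), signs, provenance)
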